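"""Macrophage detection and keyhole-model track linking.

Fluorescent macrophages are segmented per frame in 3-D by hysteresis
thresholding (bright seed voxels grown through a lower threshold),
labelled with 26-connectivity, and filtered by a minimum in-plane
surface area (default 80 px²).  Detections are linked over time with a
keyhole gate: a candidate may extend a track when it falls either inside
a disc of radius ρ around the track's last position (slow or reversing
cells) or inside a forward wedge along the predicted direction of motion
(persistent cells).  Assignment within a frame is greedy in ascending
distance with fully deterministic tie-breaking; a global optimal
assignment mode (Hungarian) is provided for cross-checks.

All gating distances are 3-D Euclidean in μm with anisotropic voxel
scaling (lateral_res, lateral_res, z_spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.filters import apply_hysteresis_threshold

from .io import ImagingMetadata, VolumeFrame, TimeLapse, frame_to_mpi

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DetectionParams:
    """Cell segmentation thresholds.

    ``low``/``high`` are the hysteresis pair (raw intensity units);
    ``min_area`` is the minimum single-plane surface area in px² a 3-D
    component must reach in at least one section; ``max_z_gap`` bridges
    components split across that many missing z-sections.
    """

    low: float
    high: float
    min_area: int = 80
    max_z_gap: int = 0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low threshold must not exceed high threshold")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass(frozen=True)
class Detection:
    """One segmented cell in one frame; centroid in μm."""

    frame: int
    x_um: float
    y_um: float
    z_um: float
    area_px: int            # max single-plane area
    volume_vox: int
    mean_intensity: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um])


@dataclass
class KeyholeParams:
    """Geometry of the keyhole gate (all lengths in μm).

    The gate is the union of a disc of radius ``disc_radius`` around the
    last position and a wedge of half-angle ``half_angle`` about the
    predicted direction, reaching ``wedge_factor`` times the last
    displacement.  ``first_radius`` gates a track's second detection,
    before any velocity estimate exists.  Tracks unmatched for more than
    ``max_gap`` consecutive frames are terminated.
    """

    half_angle: float = 30.0
    wedge_factor: float = 3.0
    disc_radius: float = 15.0
    max_gap: int = 1
    first_radius: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.half_angle < 90:
            raise ValueError("half_angle must be in (0, 90) degrees")
        if self.wedge_factor < 1:
            raise ValueError("wedge_factor must be >= 1")
        if self.disc_radius <= 0 or self.first_radius <= 0:
            raise ValueError("radii must be > 0")


@dataclass
class Track:
    """Time-ordered detections of one cell; frame gaps allowed."""

    id: int
    detections: list[tuple[int, Detection]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def append(self, frame: int, det: Detection) -> None:
        if self.detections and frame <= self.detections[-1][0]:
            raise ValueError("frames must be strictly increasing")
        self.detections.append((frame, det))

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.detections]

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.pos for _, d in self.detections])

    @property
    def birth(self) -> int:
        return self.detections[0][0]

    @property
    def death(self) -> int:
        return self.detections[-1][0]

    @property
    def lifespan(self) -> int:
        return self.death - self.birth + 1

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class TrackSet:
    """All tracks of one experiment plus unlinked detections."""

    tracks: list[Track] = field(default_factory=list)
    unassigned: list[tuple[int, Detection]] = field(default_factory=list)
    params: KeyholeParams | None = None

    def n_detections(self) -> int:
        return sum(len(t) for t in self.tracks) + len(self.unassigned)

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)


def _label_components(data: np.ndarray,
                      params: DetectionParams) -> np.ndarray:
    mask = apply_hysteresis_threshold(data.astype(float), params.low,
                                      params.high)
    if not mask.any():
        return np.zeros(data.shape, dtype=np.int32)
    if params.max_z_gap > 0:
        bridged = ndi.binary_dilation(
            mask, structure=np.ones((2 * params.max_z_gap + 1, 1, 1),
                                    dtype=bool))
        labels, _ = ndi.label(bridged, structure=_STRUCT_26)
        labels = np.where(mask, labels, 0)
    else:
        labels, _ = ndi.label(mask, structure=_STRUCT_26)
    return labels


def segment_cells(volume: VolumeFrame | np.ndarray,
                  params: DetectionParams) -> np.ndarray:
    """3-D boolean mask of all voxels in components passing ``min_area``."""
    data = volume.data if isinstance(volume, VolumeFrame) else np.asarray(volume)
    labels = _label_components(data, params)
    out = np.zeros(data.shape, dtype=bool)
    for sl, lab in zip(ndi.find_objects(labels),
                       range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        sub = labels[sl] == lab
        if int(sub.sum(axis=(1, 2)).max()) >= params.min_area:
            out[sl] |= sub
    return out


def detect_cells(
    volume: VolumeFrame | np.ndarray,
    params: DetectionParams,
    metadata: ImagingMetadata,
) -> list[Detection]:
    """Segment cells in one 3-D frame.

    Hysteresis: voxels ≥ high seed regions grown through voxels ≥ low.
    Components are 26-connected; with ``max_z_gap`` > 0 components whose
    xy footprints touch across up to that many empty sections are merged.
    A component survives only if some single z-plane holds ≥ ``min_area``
    member pixels.  Centroids are intensity-weighted and converted to μm.
    """
    data = volume.data if isinstance(volume, VolumeFrame) else np.asarray(volume)
    frame = volume.index if isinstance(volume, VolumeFrame) else 0
    labels = _label_components(data, params)
    if not labels.any():
        return []

    detections: list[Detection] = []
    for sl, lab in zip(ndi.find_objects(labels),
                       range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        sub = labels[sl] == lab
        plane_areas = sub.sum(axis=(1, 2))
        area = int(plane_areas.max())
        if area < params.min_area:
            continue
        vals = data[sl][sub].astype(float)
        w = vals.sum()
        zz, yy, xx = np.nonzero(sub)
        z0, y0, x0 = (s.start for s in sl)
        if w > 0:
            cz = float(((zz + z0) * vals).sum() / w)
            cy = float(((yy + y0) * vals).sum() / w)
            cx = float(((xx + x0) * vals).sum() / w)
        else:
            cz, cy, cx = (float((zz + z0).mean()), float((yy + y0).mean()),
                          float((xx + x0).mean()))
        detections.append(Detection(
            frame=frame,
            x_um=cx * metadata.lateral_res,
            y_um=cy * metadata.lateral_res,
            z_um=cz * metadata.z_spacing,
            area_px=area,
            volume_vox=int(sub.sum()),
            mean_intensity=float(vals.mean()),
        ))
    return detections


def detect_timelapse(lapse: TimeLapse, params: DetectionParams,
                     metadata: ImagingMetadata | None = None
                     ) -> list[list[Detection]]:
    """Per-frame detection lists for a whole (GREEN) time lapse."""
    metadata = metadata or lapse.metadata
    return [detect_cells(fr, params, metadata) for fr in lapse]


def predict_position(track: Track) -> np.ndarray:
    """Constant-velocity extrapolation of the next centroid.

    With ≥ 2 detections: p + (p − p_prev); with one: the position itself.
    """
    if len(track) == 0:
        raise ValueError("track has no detections")
    if len(track) == 1:
        return track.detections[-1][1].pos
    p1 = track.detections[-1][1].pos
    p0 = track.detections[-2][1].pos
    return p1 + (p1 - p0)


def keyhole_gate(prev: np.ndarray, pred: np.ndarray, candidate: np.ndarray,
                 params: KeyholeParams) -> bool:
    """Is a candidate inside the keyhole (disc ∪ forward wedge)?

    The disc of radius ρ around ``prev`` admits slow or reversing cells;
    the wedge with apex ``prev``, axis toward ``pred``, configured
    half-angle and radial extent λ·|pred − prev| admits persistent
    motion.  A zero predicted displacement degrades to the disc alone.
    """
    prev = np.asarray(prev, float)
    d = np.asarray(candidate, float) - prev
    dist = float(np.linalg.norm(d))
    if dist <= params.disc_radius:
        return True
    axis = np.asarray(pred, float) - prev
    step = float(np.linalg.norm(axis))
    if step == 0.0:
        return False
    if dist > params.wedge_factor * step:
        return False
    cos = float(d @ axis) / (dist * step)
    return cos >= np.cos(np.deg2rad(params.half_angle))


def _gated(track: Track, cand: Detection, params: KeyholeParams) -> bool:
    prev = track.detections[-1][1].pos
    if len(track) == 1:
        return float(np.linalg.norm(cand.pos - prev)) <= params.first_radius
    return keyhole_gate(prev, predict_position(track), cand.pos, params)


def link_frames(
    detections_by_frame: Sequence[Sequence[Detection]],
    params: KeyholeParams | None = None,
    mode: str = "greedy",
) -> TrackSet:
    """Link per-frame detections into tracks.

    Greedy mode matches (track, candidate) pairs in ascending distance
    with deterministic tie-breaks (distance, then track id, then
    candidate coordinates); ``mode="global"`` solves each frame's gated
    assignment optimally and exists for oracle cross-checks.  Unmatched
    candidates seed new tracks; every detection ends up in exactly one
    track (singleton tracks rather than an orphan pool, so conservation
    is trivial to audit).
    """
    params = params or KeyholeParams()
    tracks: list[Track] = []
    active: list[Track] = []

    for t, cands in enumerate(detections_by_frame):
        cands = sorted(cands, key=lambda d: (d.x_um, d.y_um, d.z_um))
        active = [tr for tr in active if t - tr.death <= params.max_gap + 1]
        matches: dict[int, Detection] = {}
        if active and cands:
            if mode == "greedy":
                pairs = []
                for tr in active:
                    last = tr.detections[-1][1].pos
                    for ci, cand in enumerate(cands):
                        if _gated(tr, cand, params):
                            dist = float(np.linalg.norm(cand.pos - last))
                            pairs.append((dist, tr.id, ci))
                pairs.sort()
                used_tr: set[int] = set()
                used_c: set[int] = set()
                by_id = {tr.id: tr for tr in active}
                for dist, tid, ci in pairs:
                    if tid in used_tr or ci in used_c:
                        continue
                    matches[ci] = None  # placeholder; assign below
                    by_id[tid].append(t, cands[ci])
                    used_tr.add(tid)
                    used_c.add(ci)
            elif mode == "global":
                BIG = 1e12
                cost = np.full((len(active), len(cands)), BIG)
                for ti, tr in enumerate(active):
                    last = tr.detections[-1][1].pos
                    for ci, cand in enumerate(cands):
                        if _gated(tr, cand, params):
                            cost[ti, ci] = float(np.linalg.norm(cand.pos - last))
                rows, cols = linear_sum_assignment(cost)
                for ti, ci in zip(rows, cols):
                    if cost[ti, ci] < BIG:
                        matches[ci] = None
                        active[ti].append(t, cands[ci])
            else:
                raise ValueError(f"unknown mode {mode!r}")
        for ci, cand in enumerate(cands):
            if ci not in matches:
                tr = Track(id=len(tracks))
                tr.append(t, cand)
                tracks.append(tr)
                active.append(tr)

    return TrackSet(tracks=tracks, unassigned=[], params=params)


def flag_quality(trackset: TrackSet, fusion_radius: float = 10.0) -> TrackSet:
    """Advisory quality flags; nothing is deleted.

    ``artifact``: lifespan-1 tracks (single-frame detections are usually
    debris or noise).  ``collision``: two tracks co-detected in a frame
    with inter-centroid distance below ``fusion_radius`` μm (likely
    touching or fused cells).
    """
    for tr in trackset:
        if tr.lifespan == 1:
            tr.flags.add("artifact")
    index: dict[int, list[tuple[Track, np.ndarray]]] = {}
    for tr in trackset:
        for f, det in tr.detections:
            index.setdefault(f, []).append((tr, det.pos))
    for entries in index.values():
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                ta, pa = entries[i]
                tb, pb = entries[j]
                if float(np.linalg.norm(pa - pb)) < fusion_radius:
                    ta.flags.add("collision")
                    tb.flags.add("collision")
    return trackset


def trackset_to_dataframe(trackset: TrackSet,
                          metadata: ImagingMetadata) -> pd.DataFrame:
    """Long-format table: one row per (track, frame) detection."""
    rows = []
    for tr in trackset:
        flags = ";".join(sorted(tr.flags))
        for f, det in tr.detections:
            rows.append({
                "track_id": tr.id, "frame": f,
                "mpi": frame_to_mpi(f, metadata),
                "x_um": det.x_um, "y_um": det.y_um, "z_um": det.z_um,
                "area_px": det.area_px, "flags": flags,
            })
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "mpi", "x_um", "y_um", "z_um",
                       "area_px", "flags"])


def dataframe_to_trackset(df: pd.DataFrame) -> TrackSet:
    """Inverse of :func:`trackset_to_dataframe` (geometry only)."""
    tracks = []
    for tid, grp in df.groupby("track_id"):
        tr = Track(id=int(tid))
        flags = grp["flags"].iloc[0]
        if isinstance(flags, str) and flags:
            tr.flags = set(flags.split(";"))
        for _, row in grp.sort_values("frame").iterrows():
            tr.append(int(row["frame"]), Detection(
                frame=int(row["frame"]), x_um=float(row["x_um"]),
                y_um=float(row["y_um"]), z_um=float(row["z_um"]),
                area_px=int(row.get("area_px", 0)), volume_vox=0,
                mean_intensity=0.0))
        tracks.append(tr)
    return TrackSet(tracks=tracks)
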