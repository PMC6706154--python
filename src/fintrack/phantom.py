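"""Seeded synthetic 3D+t phantoms with exact ground truth.

A phantom emulates the wounded-larval-fin imaging protocol — 512×512 px
at 1.64 μm/px, 7 z-sections at 10 μm, 90 frames at 1 min starting 25
minutes post injury, 16-bit greyscale, three channels — with everything
the pipeline is supposed to recover known by construction:

* BF renders the fin-tissue silhouette (dark tissue on a bright field);
* RED renders a constant background offset, tissue autofluorescence and
  a wound ROS signal decaying exponentially with distance from a
  V-shaped wound margin;
* GREEN renders macrophages as anisotropic 3-D Gaussian blobs moving on
  a drift-plus-diffusion random walk toward per-cell arrival slots near
  the wound.

Poisson shot noise and Gaussian read noise are applied last.  All
randomness flows from a single seed through spawned child streams, so
identical specs produce bit-identical output and frames can be rendered
independently (streamed) without materialising the full ~1 GB lapse.

The motion model is deliberately simple — it exists to make metric
recovery testable against exact truth, not to model chemotaxis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon2mask

from .io import (DatasetLayout, ImagingMetadata, TimeLapse, VolumeFrame)
from .ros import WoundMargin, BackgroundSet, distance_to_polyline

CHANNELS = ("BF", "RED", "GREEN")


class SpecError(ValueError):
    """Phantom specification is internally inconsistent."""


@dataclass
class WoundSpec:
    """Wound geometry and probe-signal profile.

    ``perimeter_um`` is the total margin length (split across
    ``n_wounds`` V incisions); ``amplitude`` the peak probe intensity at
    the margin (raw 16-bit units); ``decay_um`` the exponential decay
    length of the signal away from the margin; ``growth`` an optional
    linear per-frame amplitude growth factor.
    """

    n_wounds: int = 1
    perimeter_um: float = 320.0
    amplitude: float = 400.0
    decay_um: float = 25.0
    growth: float = 0.0
    arm_angle_deg: float = 55.0

    def __post_init__(self) -> None:
        if self.perimeter_um <= 0:
            raise SpecError("wound perimeter target must be > 0")
        if self.n_wounds not in (1, 2):
            raise SpecError("n_wounds must be 1 or 2")


@dataclass
class CellSpec:
    """Macrophage population and biased-random-walk motion model.

    ``speed_um_min`` is the drift magnitude toward each cell's arrival
    slot near the wound (0 = isotropic walk); ``jitter_um`` the per-step
    Gaussian displacement SD; cells of ``radius_um`` ≈ 8 μm span 2–3
    z-sections, in the 10–20 μm depth range typical of these cells.
    """

    n: int = 10
    radius_um: float = 8.0
    intensity: float = 3000.0
    speed_um_min: float = 3.0
    jitter_um: float = 1.0
    arrive_radius_um: float = 12.0
    dropout: float = 0.0
    mask_threshold: float = 300.0     # defines the ground-truth cell mask
    min_separation_um: float = 35.0   # at spawn
    pairwise_min_um: float = 25.0     # maintained during the walk

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise SpecError("cell radius must be > 0")
        if not 0 <= self.dropout < 1:
            raise SpecError("dropout must be in [0, 1)")


@dataclass
class NoiseSpec:
    """Poisson gain (0 disables shot noise) and Gaussian read-noise SD."""

    poisson_scale: float = 4.0
    read_sd: float = 10.0


@dataclass
class PhantomSpec:
    """Complete parametric description of a synthetic imaging set."""

    metadata: ImagingMetadata = field(default_factory=ImagingMetadata)
    width: int = 512
    height: int = 512
    tissue_polygon: np.ndarray | None = None    # (x, y) px; default fin shape
    wound: WoundSpec = field(default_factory=WoundSpec)
    cells: CellSpec = field(default_factory=CellSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    background: float = 100.0        # camera offset, all channels
    tissue_level: float = 150.0      # RED tissue autofluorescence
    green_tissue_level: float = 30.0
    bf_level: float = 30000.0
    bf_tissue_drop: float = 12000.0
    p3_um: float = 65.0
    seed: int = 42

    def polygon(self) -> np.ndarray:
        if self.tissue_polygon is not None:
            return np.asarray(self.tissue_polygon, dtype=float)
        frac = np.array([(0.12, 0.20), (0.82, 0.12), (0.97, 0.50),
                         (0.82, 0.88), (0.12, 0.80)])
        return frac * np.array([self.width, self.height])


@dataclass
class GroundTruth:
    """Exact masks, tracks and fluorescence of a generated phantom."""

    spec: PhantomSpec
    tissue_mask: np.ndarray                  # 2-D bool
    margins: list[WoundMargin]
    wound_mask: np.ndarray                   # 2-D bool (P3 band ∩ tissue)
    background: float                        # true B
    background_rois: BackgroundSet
    positions_um: np.ndarray                 # (n_frames, n_cells, 3)
    visible: np.ndarray                      # (n_frames, n_cells) bool
    ctf: np.ndarray                          # (n_frames,) analytic CTF
    occupancy: np.ndarray                    # (n_frames,) cells in wound mask
    s_o_um: np.ndarray                       # wound epicenter (x, y) μm
    n_o_um: np.ndarray                       # notochord tip (x, y) μm

    @property
    def area_px(self) -> int:
        return int(self.wound_mask.sum())

    def cell_mask(self, frame: int) -> np.ndarray:
        """Noise-free 3-D macrophage mask at the ground-truth threshold."""
        sig = _render_cells(self.spec, self.positions_um[frame],
                            self.visible[frame])
        return sig >= self.spec.cells.mask_threshold

    def mean_speeds(self) -> np.ndarray:
        """Per-cell mean step speed (μm/min) over visible consecutive frames."""
        dt = self.spec.metadata.sampling
        speeds = []
        for c in range(self.positions_um.shape[1]):
            steps = []
            prev = None
            for t in range(self.positions_um.shape[0]):
                if not self.visible[t, c]:
                    prev = None
                    continue
                if prev is not None:
                    d = np.linalg.norm(self.positions_um[t, c] - prev[1])
                    steps.append(d / ((t - prev[0]) * dt))
                prev = (t, self.positions_um[t, c])
            speeds.append(np.mean(steps) if steps else np.nan)
        return np.asarray(speeds)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _z_profile(n_z: int) -> np.ndarray:
    # symmetric in-focus profile, peak 1 at the middle section
    if n_z == 1:
        return np.ones(1)
    c = (n_z - 1) / 2.0
    return 1.0 - 0.3 * np.abs(np.arange(n_z) - c) / c


def generate_wound_margins(spec: PhantomSpec) -> list[WoundMargin]:
    """V-shaped margin polylines hitting the perimeter target within 1 %.

    A single wound is one V of two equal arms; a double wound is two
    stacked Vs splitting the target.  Apexes point into the fin with the
    arms opening toward the fin edge.
    """
    if spec.wound.perimeter_um <= 0:
        raise SpecError("wound perimeter target must be > 0")
    n = spec.wound.n_wounds
    arm_um = spec.wound.perimeter_um / (2 * n)
    arm_px = arm_um / spec.metadata.lateral_res
    ang = np.deg2rad(spec.wound.arm_angle_deg)
    apex_x = 0.62 * spec.width
    apex_ys = [0.5 * spec.height] if n == 1 else [0.35 * spec.height,
                                                 0.65 * spec.height]
    margins = []
    for ay in apex_ys:
        apex = np.array([apex_x, ay])
        up = apex + arm_px * np.array([np.cos(ang), -np.sin(ang)])
        dn = apex + arm_px * np.array([np.cos(ang), np.sin(ang)])
        for p in (up, dn):
            if not (0 <= p[0] < spec.width and 0 <= p[1] < spec.height):
                raise SpecError(
                    f"wound perimeter {spec.wound.perimeter_um} μm does not "
                    f"fit a {spec.width}×{spec.height} px fin")
        margins.append(WoundMargin(np.array([up, apex, dn])))
    return margins


def generate_wound_margin(spec: PhantomSpec) -> WoundMargin:
    """Single-wound convenience wrapper around :func:`generate_wound_margins`."""
    margins = generate_wound_margins(spec)
    if len(margins) != 1:
        raise SpecError("generate_wound_margin expects n_wounds = 1")
    return margins[0]


def _tissue_mask(spec: PhantomSpec) -> np.ndarray:
    poly_xy = spec.polygon()
    return polygon2mask((spec.height, spec.width), poly_xy[:, ::-1])


def _margin_distance_px(spec: PhantomSpec,
                        margins: Sequence[WoundMargin]) -> np.ndarray:
    return np.minimum.reduce([
        distance_to_polyline((spec.height, spec.width), m.vertices)
        for m in margins])


def _place_background_rois(spec: PhantomSpec, tissue: np.ndarray,
                           n: int = 6, diameter: float = 12.0
                           ) -> BackgroundSet:
    # deterministic grid scan for circles fully outside tissue; shrink the
    # circles if the off-tissue border is narrow (small test images)
    for d in (diameter, 8.0, 6.0, 4.0):
        r = d / 2.0 + 2.0
        circles = []
        step = max(4, int(d) + 2)
        for x in range(int(r) + 1, spec.width - int(r) - 1, step):
            for y in range(int(r) + 1, spec.height - int(r) - 1, step):
                y0, y1 = int(y - r), int(y + r) + 1
                x0, x1 = int(x - r), int(x + r) + 1
                if not tissue[y0:y1, x0:x1].any():
                    circles.append((float(x), float(y), d))
                    if len(circles) == n:
                        return BackgroundSet(circles)
        if circles:
            return BackgroundSet(circles)
    raise SpecError("no room outside tissue for background ROIs")


# ---------------------------------------------------------------------------
# Cell tracks
# ---------------------------------------------------------------------------

def _simulate_tracks(spec: PhantomSpec, tissue: np.ndarray,
                     s_o_px: np.ndarray, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    md = spec.metadata
    n_frames, n_cells = md.n_frames, spec.cells.n
    res = md.lateral_res
    z_max = (md.n_z - 1) * md.z_spacing

    # spawn positions: left half of the fin, mutually separated
    starts = []
    tries = 0
    while len(starts) < n_cells:
        tries += 1
        if tries > 50000:
            raise SpecError("could not place cells inside tissue")
        x = rng.uniform(0.16 * spec.width, 0.48 * spec.width)
        y = rng.uniform(0.22 * spec.height, 0.78 * spec.height)
        if not tissue[int(y), int(x)]:
            continue
        p = np.array([x * res, y * res])
        if all(np.linalg.norm(p - q[:2]) >= spec.cells.min_separation_um
               for q in starts):
            z = rng.uniform(0.25, 0.75) * max(z_max, 1e-9)
            starts.append(np.array([p[0], p[1], z]))

    # arrival slots: a comb of points just inside the wound band
    s_o_um = s_o_px * res
    offsets = (np.arange(n_cells) - (n_cells - 1) / 2.0) * 28.0
    targets = np.stack([
        np.full(n_cells, s_o_um[0] - 25.0),
        s_o_um[1] + offsets,
    ], axis=1)

    pos = np.zeros((n_frames, n_cells, 3))
    pos[0] = np.array(starts)
    drift = spec.cells.speed_um_min * md.sampling
    jit = spec.cells.jitter_um
    h_um, w_um = (spec.height - 1) * res, (spec.width - 1) * res
    sep = spec.cells.pairwise_min_um

    def admissible(q: np.ndarray, c: int, cur: np.ndarray, t: int) -> bool:
        if not tissue[int(round(q[1] / res)), int(round(q[0] / res))]:
            return False
        for k in range(n_cells):
            other = cur[k] if k < c else pos[t - 1, k]
            if k != c and np.linalg.norm(other[:2] - q[:2]) < sep:
                return False
        return True

    for t in range(1, n_frames):
        cur = pos[t - 1].copy()
        for c in range(n_cells):
            p = pos[t - 1, c]
            step = rng.normal(0.0, jit, 3) * np.array([1.0, 1.0, 0.3])
            if drift > 0:
                to = targets[c] - p[:2]
                d = np.linalg.norm(to)
                if d > spec.cells.arrive_radius_um:
                    step[:2] += drift * to / d
                else:
                    step[:2] *= 0.5
            for cand in (step, step * np.array([1.0, -1.0, 1.0]),
                         step * 0.25, np.zeros(3)):
                q = p + cand
                q[0] = np.clip(q[0], 0.0, w_um)
                q[1] = np.clip(q[1], 0.0, h_um)
                q[2] = np.clip(q[2], 0.0, z_max)
                if admissible(q, c, cur, t):
                    break
            else:
                q = p
            cur[c] = q
        pos[t] = cur

    visible = np.ones((n_frames, n_cells), dtype=bool)
    if spec.cells.dropout > 0:
        visible = rng.random((n_frames, n_cells)) >= spec.cells.dropout
    return pos, visible


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_cells(spec: PhantomSpec, pos_um: np.ndarray,
                  visible: np.ndarray) -> np.ndarray:
    """Noise-free GREEN cell signal volume (z, y, x) for one frame."""
    md = spec.metadata
    out = np.zeros((md.n_z, spec.height, spec.width))
    sig_xy = spec.cells.radius_um / 1.8 / md.lateral_res      # px
    sig_z = spec.cells.radius_um / md.z_spacing               # sections
    half = int(np.ceil(4 * sig_xy))
    zs = np.arange(md.n_z)
    for c in range(pos_um.shape[0]):
        if not visible[c]:
            continue
        cx = pos_um[c, 0] / md.lateral_res
        cy = pos_um[c, 1] / md.lateral_res
        cz = pos_um[c, 2] / md.z_spacing
        x0, x1 = max(0, int(cx) - half), min(spec.width, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(spec.height, int(cy) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        g2 = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig_xy ** 2))
        gz = np.exp(-((zs - cz) ** 2) / (2 * max(sig_z, 1e-9) ** 2))
        out[:, y0:y1, x0:x1] += spec.cells.intensity * gz[:, None, None] * g2
    return out


def _apply_noise(img: np.ndarray, spec: PhantomSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    if spec.noise.poisson_scale > 0:
        s = spec.noise.poisson_scale
        out = rng.poisson(out / s).astype(np.float64) * s
    if spec.noise.read_sd > 0:
        out = out + rng.normal(0.0, spec.noise.read_sd, out.shape)
    hi = spec.metadata.intensity_max
    return np.clip(np.rint(out), 0, hi).astype(spec.metadata.dtype)


@dataclass
class _Scene:
    """Static per-phantom render state shared by all frames."""

    tissue: np.ndarray
    margins: list[WoundMargin]
    wound_mask: np.ndarray
    wound_profile: np.ndarray     # unit-amplitude wound signal (2-D)
    zp: np.ndarray
    truth: GroundTruth


def _build_scene(spec: PhantomSpec) -> _Scene:
    md = spec.metadata
    tissue = _tissue_mask(spec)
    margins = generate_wound_margins(spec)
    dist_px = _margin_distance_px(spec, margins)
    band = dist_px <= spec.p3_um / md.lateral_res
    wound_mask = band & tissue
    profile = np.exp(-dist_px * md.lateral_res / spec.wound.decay_um) * tissue

    apex = margins[0].vertices[1]
    if len(margins) == 2:
        apex = (margins[0].vertices[1] + margins[1].vertices[1]) / 2.0
    s_o_px = np.asarray(apex, dtype=float)
    n_o_px = np.array([0.40 * spec.width, 0.50 * spec.height])

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + md.n_frames)
    track_rng = np.random.default_rng(children[0])
    pos, visible = _simulate_tracks(spec, tissue, s_o_px, track_rng)

    bg_rois = _place_background_rois(spec, tissue)

    # analytic CTF: brute-force pixel sum of the noise-free RED projection
    area = int(wound_mask.sum())
    base = spec.tissue_level * tissue.astype(float)
    ctf = np.empty(md.n_frames)
    occupancy = np.zeros(md.n_frames, dtype=int)
    wm = wound_mask
    for t in range(md.n_frames):
        amp = spec.wound.amplitude * (1.0 + spec.wound.growth * t)
        mip = spec.background + base + amp * profile   # z-profile peaks at 1
        # quantize like the 16-bit render so noise-free frames match exactly
        mip_q = np.rint(np.clip(mip, 0, md.intensity_max))
        ctf[t] = float(mip_q[wm].sum()) - area * spec.background
        cols = np.clip(np.round(pos[t, :, 0] / md.lateral_res).astype(int),
                       0, spec.width - 1)
        rows = np.clip(np.round(pos[t, :, 1] / md.lateral_res).astype(int),
                       0, spec.height - 1)
        occupancy[t] = int((visible[t] & wm[rows, cols]).sum())

    truth = GroundTruth(
        spec=spec, tissue_mask=tissue, margins=margins, wound_mask=wound_mask,
        background=spec.background, background_rois=bg_rois,
        positions_um=pos, visible=visible, ctf=ctf, occupancy=occupancy,
        s_o_um=s_o_px * md.lateral_res, n_o_um=n_o_px * md.lateral_res,
    )
    return _Scene(tissue, margins, wound_mask, profile, _z_profile(md.n_z),
                  truth)


def iter_phantom_frames(
    spec: PhantomSpec, scene: _Scene | None = None
) -> Iterator[tuple[int, dict[str, np.ndarray]]]:
    """Stream (frame index, {channel: uint volume}) without storing the lapse."""
    scene = scene or _build_scene(spec)
    md = spec.metadata
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + md.n_frames)
    tissue_f = scene.tissue.astype(float)
    zp = scene.zp
    for t in range(md.n_frames):
        rng = np.random.default_rng(children[2 + t])
        amp = spec.wound.amplitude * (1.0 + spec.wound.growth * t)
        red2d = spec.tissue_level * tissue_f + amp * scene.wound_profile
        red = spec.background + zp[:, None, None] * red2d
        green = (spec.background
                 + zp[:, None, None] * spec.green_tissue_level * tissue_f
                 + _render_cells(spec, scene.truth.positions_um[t],
                                 scene.truth.visible[t]))
        bf = np.broadcast_to(
            spec.bf_level - spec.bf_tissue_drop * tissue_f,
            (md.n_z, spec.height, spec.width)).copy()
        vols = {}
        for channel, img in (("BF", bf), ("RED", red), ("GREEN", green)):
            vols[channel] = _apply_noise(img, spec, rng)
        yield t, vols


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[dict[str, TimeLapse], GroundTruth]:
    """Materialise the full phantom in memory (use streaming for big specs)."""
    scene = _build_scene(spec)
    frames: dict[str, list[VolumeFrame]] = {c: [] for c in CHANNELS}
    for t, vols in iter_phantom_frames(spec, scene):
        for channel, data in vols.items():
            frames[channel].append(VolumeFrame(t, channel, data))
    lapses = {c: TimeLapse(spec.metadata, c, frames[c]) for c in CHANNELS}
    return lapses, scene.truth


def write_phantom(spec: PhantomSpec, root: str | Path,
                  layout: DatasetLayout | None = None,
                  position: str = "P0",
                  write_truth: bool = True) -> tuple[int, GroundTruth]:
    """Render the phantom to the standard TIFF layout; returns (n files, truth).

    Ground truth is written alongside under ``<root>/truth/``: tracks and
    occupancy CSVs, 0/255 mask TIFFs and a truth.yaml of scripted values.
    """
    root = Path(root)
    layout = layout or DatasetLayout()
    scene = _build_scene(spec)
    n = 0
    for t, vols in iter_phantom_frames(spec, scene):
        for channel, data in vols.items():
            for z in range(data.shape[0]):
                path = root / layout.relpath(channel, position, t, z)
                path.parent.mkdir(parents=True, exist_ok=True)
                tifffile.imwrite(path, data[z])
                n += 1
    if write_truth:
        _write_truth(scene.truth, root / "truth")
    return n, scene.truth


def _write_truth(truth: GroundTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    md = truth.spec.metadata
    rows = []
    for t in range(truth.positions_um.shape[0]):
        for c in range(truth.positions_um.shape[1]):
            if truth.visible[t, c]:
                x, y, z = truth.positions_um[t, c]
                rows.append({"cell": c, "frame": t, "x_um": x, "y_um": y,
                             "z_um": z})
    pd.DataFrame(rows).to_csv(outdir / "tracks.csv", index=False)
    pd.DataFrame({
        "frame": np.arange(md.n_frames),
        "occupancy": truth.occupancy,
        "ctf": truth.ctf,
    }).to_csv(outdir / "occupancy.csv", index=False)
    tifffile.imwrite(outdir / "tissue_mask.tif",
                     truth.tissue_mask.astype(np.uint8) * 255)
    tifffile.imwrite(outdir / "wound_mask.tif",
                     truth.wound_mask.astype(np.uint8) * 255)
    meta = {
        "seed": int(truth.spec.seed),
        "background": float(truth.background),
        "area_px": truth.area_px,
        "s_o_um": [float(v) for v in truth.s_o_um],
        "n_o_um": [float(v) for v in truth.n_o_um],
        "wound": {"n_wounds": truth.spec.wound.n_wounds,
                  "perimeter_um": float(truth.spec.wound.perimeter_um),
                  "amplitude": float(truth.spec.wound.amplitude)},
        "cells": {"n": truth.spec.cells.n,
                  "speed_um_min": float(truth.spec.cells.speed_um_min)},
        "margins_px": [m.vertices.tolist() for m in truth.margins],
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: per-condition presets: wound signal and macrophage drift scale with severity
CONDITION_PRESETS: dict[str, dict] = {
    "unwounded": {"n_wounds": 1, "perimeter_um": 320.0, "amplitude": 0.0,
                  "speed_um_min": 0.0},
    "single": {"n_wounds": 1, "perimeter_um": 320.0, "amplitude": 400.0,
               "speed_um_min": 3.0},
    "double": {"n_wounds": 2, "perimeter_um": 544.0, "amplitude": 700.0,
               "speed_um_min": 4.0},
}


@dataclass
class CohortMember:
    fish: str
    condition: str
    spec: PhantomSpec


def scripted_cohort(
    n_fish: int = 4,
    conditions: Sequence[str] = ("unwounded", "single", "double"),
    seed: int = 7,
    base: PhantomSpec | None = None,
) -> list[CohortMember]:
    """Condition-stratified phantom specs with per-fish seeds.

    The unwounded preset keeps a sham margin (so the same ROI machinery
    measures baseline CTF) but zero wound signal and zero drift; wounded
    presets scale signal amplitude and drift with severity, forcing the
    recoverable orderings CTF(double) > CTF(single) > CTF(unwounded) and
    speed(double) > speed(single).
    """
    if n_fish < 1:
        raise SpecError("n_fish must be >= 1")
    base = base or PhantomSpec()
    children = np.random.SeedSequence(seed).spawn(len(conditions) * n_fish)
    members = []
    i = 0
    for condition in conditions:
        preset = CONDITION_PRESETS[condition]
        for f in range(n_fish):
            child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            i += 1
            spec = replace(
                base,
                wound=replace(base.wound,
                              n_wounds=preset["n_wounds"],
                              perimeter_um=preset["perimeter_um"],
                              amplitude=preset["amplitude"]),
                cells=replace(base.cells,
                              speed_um_min=preset["speed_um_min"]),
                seed=child_seed,
            )
            members.append(CohortMember(f"{condition}_{f}", condition, spec))
    return members
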