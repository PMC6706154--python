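"""Track selection and migration kinetics.

Tracks are filtered by a temporal inclusion criterion (P5: percent of
window frames with a distinguishable centroid, default 70%), grouped
into time domains (T1 = 30–59, T2 = 60–89, T3 = 90–120, T4 = 30–90,
T5 = 30–120 MPI) and concentric spatial domains S1–S4 about the wound
epicenter S_o, and summarised by a directional metric suite:

* instantaneous speed, Δt-weighted mean velocity, path / net / max
  distance, meandering index (net ÷ path);
* static ratio — fraction of steps of at most P6 (default 0.9 μm);
* forward migration index FMI — fraction of steps that decrease the
  Euclidean distance to S_o — and forward-to-backward index
  FBI = (forward − backward) / total steps;
* wound recruitment counts at checkpoint times.

Across a detection gap of g frames a single step with Δt = g × sampling
is used; absent centroids contribute no measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ImagingMetadata, frame_to_mpi, mpi_to_frame
from .ros import WoundROI
from .tracking import Track, TrackSet


@dataclass
class SelectionCriteria:
    """P5: minimum % of window frames with a centroid; P6: static threshold (μm)."""

    p5: float = 70.0
    p6: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.p5 <= 100:
            raise ValueError("p5 must be in (0, 100]")
        if self.p6 < 0:
            raise ValueError("p6 must be >= 0")


@dataclass(frozen=True)
class TimeDomain:
    """Closed MPI interval used to window tracks."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")


#: built-in analysis windows (MPI, inclusive)
TIME_DOMAINS: dict[str, TimeDomain] = {
    "T1": TimeDomain("T1", 30, 59),
    "T2": TimeDomain("T2", 60, 89),
    "T3": TimeDomain("T3", 90, 120),
    "T4": TimeDomain("T4", 30, 90),
    "T5": TimeDomain("T5", 30, 120),
}


@dataclass
class SpaceDomains:
    """Concentric shells about the wound epicenter S_o.

    S1 is the disc of radius r1 = |N_o − S_o| (N_o: notochord tip);
    S2–S4 are successive shells of width P9:
    r_k = r1 + (k − 1)·P9, Sk = (r_{k−1}, r_k].  Positions beyond r4 map
    to no domain.  Distances use as many coordinates as S_o provides
    (2-D epicenters compare in the imaging plane).
    """

    s_o: np.ndarray
    n_o: np.ndarray
    p9: float = 50.0

    def __post_init__(self) -> None:
        self.s_o = np.asarray(self.s_o, dtype=float)
        self.n_o = np.asarray(self.n_o, dtype=float)
        if self.s_o.shape != self.n_o.shape:
            raise ValueError("S_o and N_o must have the same dimensionality")
        if self.p9 <= 0:
            raise ValueError("P9 must be > 0")
        if self.r1 <= 0:
            raise ValueError("S_o and N_o must not coincide")

    @property
    def r1(self) -> float:
        return float(np.linalg.norm(self.n_o - self.s_o))

    @property
    def radii(self) -> list[float]:
        return [self.r1 + k * self.p9 for k in range(4)]

    def assign(self, position: np.ndarray) -> str | None:
        d = _dist(np.asarray(position, float), self.s_o)
        for k, r in enumerate(self.radii, start=1):
            if d <= r:
                return f"S{k}"
        return None


@dataclass
class TrackMetrics:
    """Per-track kinetic summary over one analysis window."""

    track_id: int
    window: str
    n_steps: int
    speeds: np.ndarray              # μm/min per step
    mean_velocity: float            # path / elapsed time (μm/min)
    path_length: float              # μm
    net_distance: float             # μm
    max_distance: float             # μm
    meandering_index: float | None  # net/path; None when path == 0
    static_ratio: float
    oriented_net: float             # d(first, S_o) − d(last, S_o), μm
    fmi: float
    fbi: float
    space_domain: str | None = None


def _dist(p: np.ndarray, q: np.ndarray) -> float:
    k = min(p.shape[-1], q.shape[-1])
    return float(np.linalg.norm(p[..., :k] - q[..., :k]))


def window_frames(window: TimeDomain, metadata: ImagingMetadata) -> list[int]:
    """Frame indices whose MPI falls inside the (closed) window."""
    return [f for f in range(metadata.n_frames)
            if window.start <= frame_to_mpi(f, metadata) <= window.end]


def clip_track(track: Track, window: TimeDomain,
               metadata: ImagingMetadata) -> Track:
    """Copy of a track restricted to in-window detections."""
    out = Track(id=track.id, flags=set(track.flags))
    for f, det in track.detections:
        if window.start <= frame_to_mpi(f, metadata) <= window.end:
            out.append(f, det)
    return out


def select_tracks(
    trackset: TrackSet,
    window: TimeDomain,
    criteria: SelectionCriteria,
    metadata: ImagingMetadata,
) -> TrackSet:
    """Retain tracks with a centroid in ≥ P5 % of window frames (inclusive).

    Returned tracks are clipped to the window so all downstream metrics
    use in-window detections only.  An empty selection is a warning-level
    outcome, not an error.
    """
    frames = window_frames(window, metadata)
    if not frames:
        raise ValueError(f"window {window.label} does not overlap the imaging span")
    n_window = len(frames)
    selected = []
    for tr in trackset:
        clipped = clip_track(tr, window, metadata)
        # integer-exact percent comparison: n_in/n_window*100 >= p5
        if len(clipped) > 0 and 100.0 * len(clipped) >= criteria.p5 * n_window - 1e-9:
            selected.append(clipped)
    return TrackSet(tracks=selected, unassigned=[], params=trackset.params)


def step_displacements(
    track: Track, metadata: ImagingMetadata
) -> list[tuple[float, np.ndarray]]:
    """(Δt in min, displacement vector in μm) between consecutive detections.

    Across a gap of g missing frames the step spans Δt = (g + 1) × sampling;
    intermediate positions are never interpolated.
    """
    if len(track) < 2:
        return []
    steps = []
    for (f0, d0), (f1, d1) in zip(track.detections[:-1], track.detections[1:]):
        steps.append(((f1 - f0) * metadata.sampling, d1.pos - d0.pos))
    return steps


def track_metrics(
    track: Track,
    s_o: np.ndarray,
    criteria: SelectionCriteria,
    metadata: ImagingMetadata,
    window: str = "",
    domains: SpaceDomains | None = None,
) -> TrackMetrics:
    """Full kinetic metric suite for one (already selected) track.

    A step is forward when it strictly decreases the Euclidean distance
    to S_o, backward when it strictly increases it; zero-change steps
    count only in the FBI denominator.  A step is static when its length
    is at most P6 (boundary inclusive).
    """
    if len(track) < 2:
        raise ValueError("track_metrics needs >= 2 in-window detections")
    s_o = np.asarray(s_o, dtype=float)
    steps = step_displacements(track, metadata)
    lengths = np.array([float(np.linalg.norm(v)) for _, v in steps])
    dts = np.array([dt for dt, _ in steps])
    positions = track.positions

    path = float(lengths.sum())
    net = _dist(positions[-1], positions[0])
    max_d = max(_dist(p, positions[0]) for p in positions)
    mi = (net / path) if path > 0 else None

    d_to_wound = np.array([_dist(p, s_o) for p in positions])
    oriented = d_to_wound[:-1] - d_to_wound[1:]   # >0: toward the wound
    n = len(steps)
    n_fwd = int((oriented > 0).sum())
    n_bwd = int((oriented < 0).sum())

    dom = None
    if domains is not None:
        dom = domains.assign(positions[0])

    return TrackMetrics(
        track_id=track.id,
        window=window,
        n_steps=n,
        speeds=lengths / dts,
        mean_velocity=path / float(dts.sum()),
        path_length=path,
        net_distance=net,
        max_distance=max_d,
        meandering_index=mi,
        static_ratio=float((lengths <= criteria.p6 + 1e-12).sum()) / n,
        oriented_net=float(d_to_wound[0] - d_to_wound[-1]),
        fmi=n_fwd / n,
        fbi=(n_fwd - n_bwd) / n,
        space_domain=dom,
    )


def assign_space_domain(position: np.ndarray,
                        domains: SpaceDomains) -> str | None:
    """Shell label of a position (S1–S4) or None beyond the outermost radius."""
    return domains.assign(position)


def track_distance(a: Track, b: Track) -> float | None:
    """Mean frame-wise distance between two tracks over co-detected frames.

    Auxiliary pairwise measure; returns None with no frame overlap.
    """
    pa = {f: det.pos for f, det in a.detections}
    common = [f for f, _ in b.detections if f in pa]
    if not common:
        return None
    pb = {f: det.pos for f, det in b.detections}
    return float(np.mean([np.linalg.norm(pa[f] - pb[f]) for f in common]))


def count_at_wound(
    trackset: TrackSet,
    wound: WoundROI | tuple[np.ndarray, float],
    checkpoints: Sequence[float],
    metadata: ImagingMetadata,
) -> pd.DataFrame:
    """Distinct tracks present inside the wound region at checkpoint MPIs.

    ``wound`` is either a :class:`~fintrack.ros.WoundROI` mask (membership
    of the xy centroid pixel) or an ``(S_o, radius_um)`` pair.  Checkpoints
    outside the imaged span raise an IndexError.
    """
    rows = []
    for mpi in checkpoints:
        f = mpi_to_frame(mpi, metadata)   # bounds-checked
        count = 0
        for tr in trackset:
            det = dict(tr.detections).get(f)
            if det is None:
                continue
            if isinstance(wound, WoundROI):
                col = int(round(det.x_um / metadata.lateral_res))
                row = int(round(det.y_um / metadata.lateral_res))
                h, w = wound.mask.shape
                inside = 0 <= row < h and 0 <= col < w and bool(wound.mask[row, col])
            else:
                s_o, radius = wound
                inside = _dist(det.pos, np.asarray(s_o, float)) <= radius
            count += inside
        rows.append({"mpi": mpi, "count": int(count)})
    return pd.DataFrame(rows, columns=["mpi", "count"])


_METRIC_COLUMNS = ["mean_velocity", "path_length", "net_distance",
                   "max_distance", "meandering_index", "static_ratio",
                   "oriented_net", "fmi", "fbi"]


def metrics_to_dataframe(metrics: Iterable[TrackMetrics],
                         fish: str = "fish",
                         condition: str = "") -> pd.DataFrame:
    """Wide per-track table with identifying columns."""
    rows = []
    for m in metrics:
        row = {"fish": fish, "condition": condition, "track_id": m.track_id,
               "time_domain": m.window, "space_domain": m.space_domain,
               "n_steps": m.n_steps}
        for c in _METRIC_COLUMNS:
            row[c] = getattr(m, c)
        rows.append(row)
    return pd.DataFrame(rows, columns=["fish", "condition", "track_id",
                                       "time_domain", "space_domain",
                                       "n_steps"] + _METRIC_COLUMNS)


def group_summary(
    table: pd.DataFrame,
    by: Sequence[str] = ("condition", "time_domain"),
    fish_col: str | None = "fish",
    metrics: Sequence[str] = tuple(_METRIC_COLUMNS),
) -> pd.DataFrame:
    """n, mean ± SD of each metric per group.

    With a fish factor present, per-fish means are taken first and the
    mean/SD computed across fish (each animal contributes one value, the
    convention for grouped in vivo comparisons); n is then the number of
    fish.  SD is 0 when n = 1.
    """
    if table.empty:
        raise ValueError("group_summary needs >= 1 metric row")
    by = [c for c in by if c in table.columns]
    metrics = [m for m in metrics if m in table.columns]
    work = table
    if fish_col and fish_col in table.columns:
        work = (table.groupby(by + [fish_col], dropna=False)[metrics]
                .mean().reset_index())
    rows = []
    for key, grp in work.groupby(by, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(dict(zip(by, key)) | {
                "metric": m, "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            })
    return pd.DataFrame(rows, columns=list(by) + ["metric", "n", "mean", "sd"])
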