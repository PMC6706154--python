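"""Wound-region reactive-oxygen-species (ROS) probe quantification.

Per time frame, the RED probe channel is fused to a 2-D composite,
denoised, and segmented into a fish-tissue mask; a user-traced wound
margin polyline is dilated by a radial distance P3 (default 65 μm) and
intersected with tissue to form the wound ROI.  Fluorescence is then
summarised as the corrected total fluorescence

    CTF = A × (I − B)

where A is the ROI area, I the mean ROI intensity, and B the pooled mean
of user-placed circular background ROIs.  X = I − B and the integrated
density IntDen = A × X; the uncorrected A × I is retained as well so
either background-handling convention is recoverable.

Intensities I, B, X are reported on the raw bit-depth scale of the input
TIFFs; the jointly rescaled composite is used only for segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .io import ImagingMetadata, TimeLapse, VolumeFrame, frame_to_mpi

log = logging.getLogger("fintrack")


class GeometryError(ValueError):
    """An ROI falls outside the image domain."""


class MeasurementError(ValueError):
    """A measurement cannot be formed (e.g. empty wound ROI)."""


@dataclass
class CompositeFrame:
    """2-D fusion of one frame's z-sections.

    ``image`` is the maximum-intensity projection after a single joint
    linear rescale (frame-wide min → 0, max → 1) applied identically to
    all sections; ``raw`` is the projection of the unscaled stack, used
    for all intensity measurements.
    """

    index: int
    image: np.ndarray
    raw: np.ndarray


@dataclass
class WoundMargin:
    """User-traced wound polyline in pixel coordinates (x, y), ≥ 2 vertices."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 \
                or self.vertices.shape[1] != 2:
            raise ValueError("margin needs >= 2 (x, y) vertices")

    def perimeter_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    def perimeter_um(self, metadata: ImagingMetadata) -> float:
        return self.perimeter_px() * metadata.lateral_res


@dataclass
class WoundROI:
    """Wound measurement region: margin dilated by P3, restricted to tissue."""

    frame: int
    mask: np.ndarray
    area_px: int
    area_um2: float


@dataclass
class BackgroundSet:
    """Circular background ROIs as (cx, cy, diameter) triples in pixels."""

    circles: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        if len(self.circles) < 1:
            raise ValueError("background set needs >= 1 circle")


@dataclass
class RosParams:
    """Tunables of the probe-quantification path.

    ``threshold`` is the tissue threshold P1 on the rescaled composite
    ([0, 1] scale), or the sentinel ``"otsu"`` for a data-driven default.
    ``p3_um`` is the radial wound-band distance in μm.
    """

    threshold: float | str = "otsu"
    median_size: int = 3
    gaussian_sigma: float = 1.0
    morph_radius: int = 20
    p3_um: float = 65.0
    background: BackgroundSet | None = None
    pool_pixels: bool = True          # False: average per-circle means
    projection: str = "max"           # or "mean"

    def __post_init__(self) -> None:
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.morph_radius <= 0 or self.p3_um <= 0:
            raise ValueError("morph_radius and p3_um must be > 0")


@dataclass
class FluorescenceRecord:
    """Per-frame fluorescence measurement tuple."""

    frame: int
    mpi: float
    area_px: int
    area_um2: float
    intensity: float        # I: mean ROI intensity, raw scale
    background: float       # B: pooled background mean
    corrected: float        # X = I - B
    intden: float           # A * X
    ctf: float              # corrected total fluorescence, == A * X
    intden_raw: float       # uncorrected A * I


def project_composite(volume: VolumeFrame, mode: str = "max") -> CompositeFrame:
    """Fuse a z-stack into a 2-D composite with joint per-frame rescaling.

    All sections of the frame share one linear rescale (stack min → 0,
    stack max → 1) so relative z-intensity structure is preserved; the
    fused image is the per-pixel maximum (or mean for ``mode="mean"``).
    A constant stack yields an all-zero composite with a logged warning.
    """
    stack = np.asarray(volume.data, dtype=np.float64)
    reduce = np.max if mode == "max" else np.mean
    raw = reduce(stack, axis=0)
    lo, hi = stack.min(), stack.max()
    if hi == lo:
        log.warning("frame %d: constant stack, composite is all-zero", volume.index)
        scaled = np.zeros_like(raw)
    else:
        scaled = reduce((stack - lo) / (hi - lo), axis=0)
    return CompositeFrame(volume.index, scaled, raw)


def denoise(comp: CompositeFrame, params: RosParams) -> CompositeFrame:
    """Median filter (impulse noise) then Gaussian blur (shot noise).

    ``median_size=1`` with ``gaussian_sigma=0`` is the identity.
    """
    img = comp.image
    if params.median_size > 1:
        img = ndi.median_filter(img, size=params.median_size)
    if params.gaussian_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=params.gaussian_sigma)
    return CompositeFrame(comp.index, img, comp.raw)


def _disc_opening(mask: np.ndarray, radius: float) -> np.ndarray:
    # Euclidean-disc opening via two distance transforms: erosion keeps
    # pixels farther than `radius` from background, dilation re-grows them.
    if radius <= 0 or not mask.any() or mask.all():
        return mask.copy()
    eroded = ndi.distance_transform_edt(mask) > radius
    if not eroded.any():
        return eroded
    return ndi.distance_transform_edt(~eroded) <= radius


def segment_tissue(comp: CompositeFrame, params: RosParams) -> np.ndarray:
    """Threshold the (denoised) composite and clean it by disc opening.

    The opening (erosion then dilation with a disc of ``morph_radius``)
    removes spurious speckle smaller than the disc without shrinking the
    retained tissue boundary.  Returns a boolean mask.
    """
    img = comp.image
    if params.threshold == "otsu":
        if img.max() == img.min():
            log.warning("frame %d: flat image, tissue mask empty", comp.index)
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold)
        if not np.isfinite(thr):
            raise ValueError("tissue threshold must be finite or 'otsu'")
    binary = img >= thr
    if not binary.any():
        log.warning("frame %d: threshold above image maximum, empty mask",
                    comp.index)
        return binary
    return _disc_opening(binary, params.morph_radius)


def distance_to_polyline(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    """Exact per-pixel Euclidean distance (px) to a polyline's segments.

    Vertices may be sub-pixel; pixel centers sit at integer (x, y).
    """
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    best = np.full(pts.shape[0], np.inf)
    v = np.asarray(vertices, dtype=float)
    for a, b in zip(v[:-1], v[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(pts - a, axis=1)
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(pts - proj, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(h, w)


def build_wound_roi(
    margin: WoundMargin | Sequence[WoundMargin],
    tissue: np.ndarray,
    params: RosParams,
    metadata: ImagingMetadata,
    frame: int = 0,
) -> WoundROI:
    """Wound ROI = pixels within P3 μm of the margin(s), restricted to tissue.

    Multiple margins (e.g. a doubly wounded fin) contribute the union of
    their bands.
    """
    margins = [margin] if isinstance(margin, WoundMargin) else list(margin)
    radius_px = params.p3_um / metadata.lateral_res
    dist = np.minimum.reduce(
        [distance_to_polyline(tissue.shape, m.vertices) for m in margins])
    mask = (dist <= radius_px) & tissue
    area = int(mask.sum())
    if area == 0:
        raise MeasurementError(
            f"frame {frame}: wound ROI does not intersect tissue; "
            "adjust the margin, P3 or the tissue threshold")
    return WoundROI(frame, mask, area, area * metadata.lateral_res ** 2)


def _circle_pixels(shape: tuple[int, int], cx: float, cy: float,
                   diameter: float) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    r = diameter / 2.0
    if cx - r < -0.5 or cx + r > w - 0.5 or cy - r < -0.5 or cy + r > h - 0.5:
        raise GeometryError(f"background circle ({cx}, {cy}, d={diameter}) "
                            "extends outside the image")
    y0, y1 = max(0, int(np.floor(cy - r))), min(h - 1, int(np.ceil(cy + r)))
    x0, x1 = max(0, int(np.floor(cx - r))), min(w - 1, int(np.ceil(cx + r)))
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
    return ys[inside], xs[inside]


def measure_background(comp: CompositeFrame, rois: BackgroundSet,
                       pool_pixels: bool = True) -> float:
    """Single background value B for the frame (raw intensity scale).

    Default pools all pixels of all circles into one mean; the
    alternative averages per-circle means (differs only when circles
    cover unequal pixel counts).
    """
    if pool_pixels:
        vals = [comp.raw[_circle_pixels(comp.raw.shape, *c)] for c in rois.circles]
        return float(np.concatenate(vals).mean())
    means = [float(comp.raw[_circle_pixels(comp.raw.shape, *c)].mean())
             for c in rois.circles]
    return float(np.mean(means))


def compute_ctf(
    comp: CompositeFrame,
    roi: WoundROI,
    background: float,
    metadata: ImagingMetadata,
) -> FluorescenceRecord:
    """Corrected total fluorescence of one frame's wound ROI.

    I is the mean raw-projection intensity over the ROI; X = I − B;
    IntDen = CTF = A × X.  Negative X (background above ROI signal) is
    retained, not clamped, so time-series averages stay unbiased.
    """
    if roi.area_px <= 0:
        raise MeasurementError("ROI area must be positive")
    intensity = float(comp.raw[roi.mask].mean())
    corrected = intensity - background
    intden = roi.area_px * corrected
    return FluorescenceRecord(
        frame=comp.index,
        mpi=frame_to_mpi(comp.index, metadata),
        area_px=roi.area_px,
        area_um2=roi.area_um2,
        intensity=intensity,
        background=background,
        corrected=corrected,
        intden=intden,
        ctf=intden,
        intden_raw=roi.area_px * intensity,
    )


def place_baseline_circles(
    tissue: np.ndarray,
    n: int = 40,
    diameter: float = 10.0,
    seed: int | None = None,
    exclude: np.ndarray | None = None,
    max_tries: int = 20000,
) -> BackgroundSet:
    """Seeded random placement of baseline circles fully inside tissue.

    ``exclude`` (e.g. a notochord mask) removes regions from consideration.
    Raises :class:`MeasurementError` when fewer than ``n`` circles fit.
    """
    rng = np.random.default_rng(seed)
    allowed = tissue if exclude is None else (tissue & ~exclude)
    # candidate centers: tissue eroded by the circle radius (image border
    # counts as background so circles stay fully inside the frame)
    padded = np.pad(allowed, 1, constant_values=False)
    eroded = ndi.distance_transform_edt(padded)[1:-1, 1:-1] > diameter / 2.0
    ys, xs = np.nonzero(eroded)
    if ys.size == 0:
        raise MeasurementError("no tissue region can hold a baseline circle")
    circles: list[tuple[float, float, float]] = []
    taken = np.zeros(len(ys), dtype=bool)
    for _ in range(max_tries):
        if len(circles) == n:
            break
        i = int(rng.integers(len(ys)))
        if taken[i]:
            continue
        cx, cy = float(xs[i]), float(ys[i])
        if any((cx - c[0]) ** 2 + (cy - c[1]) ** 2 < diameter ** 2 for c in circles):
            continue
        circles.append((cx, cy, diameter))
        taken[i] = True
    if len(circles) < n:
        raise MeasurementError(
            f"could only place {len(circles)} of {n} baseline circles")
    return BackgroundSet(circles)


def unwounded_baseline(
    comp: CompositeFrame,
    circles: BackgroundSet,
    background: float,
    metadata: ImagingMetadata,
) -> FluorescenceRecord:
    """Baseline CTF of an unwounded fin from n circular tissue ROIs.

    The per-circle means are averaged to a single I (the stochastic
    baseline); A is the total pixel count of all circles; CTF follows
    the same A × (I − B) convention as the wound measurement.
    """
    pix = [_circle_pixels(comp.raw.shape, *c) for c in circles.circles]
    means = [float(comp.raw[p].mean()) for p in pix]
    intensity = float(np.mean(means))
    area = int(sum(p[0].size for p in pix))
    corrected = intensity - background
    intden = area * corrected
    return FluorescenceRecord(
        frame=comp.index, mpi=frame_to_mpi(comp.index, metadata),
        area_px=area, area_um2=area * metadata.lateral_res ** 2,
        intensity=intensity, background=background, corrected=corrected,
        intden=intden, ctf=intden, intden_raw=area * intensity,
    )


def ros_timeseries(
    lapse: TimeLapse,
    margins: Mapping[int, WoundMargin],
    params: RosParams,
    metadata: ImagingMetadata | None = None,
) -> list[FluorescenceRecord]:
    """Frame-by-frame CTF over a RED-channel time lapse.

    ``margins`` maps frame indices to traced margins; the margin given at
    frame k applies from k onward until overridden, so small fin shifts
    can be corrected mid-series.  A margin for frame 0 is required.
    """
    metadata = metadata or lapse.metadata
    if params.background is None:
        raise MeasurementError("RosParams.background must be set for a time series")
    if 0 not in margins:
        raise MeasurementError("a wound margin for frame 0 is required")
    switch = sorted(margins)
    records: list[FluorescenceRecord] = []
    current = margins[0]
    for frame in lapse:
        while switch and switch[0] <= frame.index:
            current = margins[switch.pop(0)]
        comp = project_composite(frame, params.projection)
        tissue = segment_tissue(denoise(comp, params), params)
        try:
            roi = build_wound_roi(current, tissue, params, metadata, frame.index)
            bkg = measure_background(comp, params.background, params.pool_pixels)
            records.append(compute_ctf(comp, roi, bkg, metadata))
        except (MeasurementError, GeometryError) as err:
            raise type(err)(f"frame {frame.index}: {err}") from err
    return records


def records_to_rows(records: Iterable[FluorescenceRecord],
                    fish: str = "fish") -> list[dict]:
    """Flatten records for CSV/workbook export."""
    return [
        {"fish": fish, "frame": r.frame, "mpi": r.mpi, "A_px": r.area_px,
         "A_um2": r.area_um2, "I": r.intensity, "B": r.background,
         "X": r.corrected, "IntDen": r.intden, "CTF": r.ctf}
        for r in records
    ]
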