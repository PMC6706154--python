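# fintrack

Quantitative image analysis for wound-healing assays in larval zebrafish
caudal fins. From 3D+t confocal time lapses (brightfield, a 561 nm
reactive-oxygen-species probe such as dihydroethidium, and a 488 nm
macrophage reporter), `fintrack` measures two things in parallel:

1. **Wound oxidative-stress signal** — per-frame corrected total
   fluorescence of a standardized wound region, and
2. **Macrophage migration kinetics** — 3-D cell detection, keyhole-gated
   track linking, and a directional metric suite (speed, meandering
   index, static ratio, forward-migration indices, wound recruitment).

It is aimed at labs running the common larval-fin injury assay
(512×512 px at 1.64 μm/px, 7 z-sections at 10 μm, ~60 s sampling over
25–130 minutes post injury) who want reproducible, scriptable numbers
instead of manual per-image measurements.

## The measurements

**Corrected total fluorescence (CTF).** A user-traced wound-margin
polyline is dilated by a radial distance P3 (default 65 μm) and
intersected with the segmented fin tissue to form the wound ROI of area
*A*. With *I* the mean ROI intensity and *B* the pooled mean of circular
background ROIs,

    X = I − B,   IntDen = A · X,   CTF = A · (I − B)

computed frame by frame on the raw-intensity maximum projection.
Unwounded fins get a baseline CTF from 40 ten-pixel-diameter circles
placed in tissue. Negative values are kept, not clamped.

**Keyhole tracking.** Cells are segmented per frame in 3-D by hysteresis
thresholding with an 80 px² minimum in-plane area, then linked through
time: a candidate may extend a track if it falls in a disc of radius ρ
(default 15 μm) around the last position *or* in a wedge (half-angle
30°, reach 3× the last displacement) along the predicted direction —
the "keyhole". Assignment is greedy in distance with deterministic
tie-breaks.

**Metric suite.** For tracks with a centroid in ≥ P5 % (default 70 %) of
the frames of an analysis window (built-ins T1 = 30–59, T2 = 60–89,
T3 = 90–120, T4 = 30–90, T5 = 30–120 MPI): instantaneous speed, mean
velocity, path/net/max distance, meandering index (net ÷ path), static
ratio (steps ≤ 0.9 μm), FMI (fraction of steps toward the wound
epicenter S_o), FBI = (forward − backward)/total, concentric spatial
domains S1–S4 about S_o, and macrophage counts at the wound over time.

**Validation.** Automated masks are scored against reference masks with
the DICE coefficient, 2|X∩Y|/(|X|+|Y|); ≥ 0.7 is effective overlap.

Because no public reference imaging sets exist for this assay, the
package ships a seeded phantom generator (`fintrack.phantom`) that
renders the full acquisition geometry with exact ground-truth masks,
tracks and fluorescence, so every stage is testable end to end.

## Worked example

Generate a reduced synthetic imaging set (256×256 px, 40 frames, 3
z-sections, 8 cells) and run both measurement arms:

```python
import numpy as np
import fintrack as ft

spec = ft.PhantomSpec(width=256, height=256,
                      metadata=ft.ImagingMetadata(n_frames=40, n_z=3),
                      cells=ft.CellSpec(n=8), seed=42)
lapses, truth = ft.generate_phantom(spec)
md = spec.metadata

# wound fluorescence, frame by frame
params = ft.RosParams(background=truth.background_rois)
records = ft.ros_timeseries(lapses["RED"], {0: truth.margins}, params, md)

# macrophage tracking and kinetics
det = ft.DetectionParams(low=300, high=1500, min_area=80)
tracks = ft.flag_quality(ft.link_frames(
    ft.detect_timelapse(lapses["GREEN"], det, md)))
selected = ft.select_tracks(tracks, ft.TimeDomain("full", 25, 64),
                            ft.SelectionCriteria(), md)
metrics = [ft.track_metrics(tr, truth.s_o_um, ft.SelectionCriteria(),
                            md, "full") for tr in selected if len(tr) >= 2]
```

Output for this seed:

```
frame 0: MPI 25, A = 14608 px^2, I = 400.8, B = 119.4, CTF = 4.111e+06
mean CTF over 40 frames: 4.116e+06 (ground truth 4.382e+06)
8 tracks selected of 8
mean velocity 3.03 um/min (scripted truth 2.96), mean FMI 0.89, mean meandering index 0.78
tissue DICE vs truth: 0.990
```

Reading this: the wound ROI covers 14 608 px²; its mean intensity 400.8
minus the background 119.4 gives X ≈ 281, and A·X ≈ 4.1×10⁶ is the
frame's CTF (raw 16-bit intensity · px² units). All 8 simulated
macrophages are recovered as single gap-free tracks; their measured mean
velocity (3.03 μm/min) matches the scripted truth within a few percent,
and the high FMI (0.89) reflects the built-in drift toward the wound.

## Command line

A thin CLI mirrors the library: `fintrack simulate | ingest | ros |
track | kinetics | validate | export` (see `fintrack --help`). Session
parameters and ROIs travel in versioned YAML files; tabular outputs are
CSV with an xlsx convenience mirror.

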