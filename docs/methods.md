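# Methods

This note documents the models, conventions and design choices behind
`fintrack`, the parameters that matter, and what the synthetic phantoms
do and do not establish about behaviour on real microscope data.

## Coordinate and unit conventions

Pixel coordinates are 0-based, x rightward, y downward, z by stack
index. Frame labels in file names are 1-based (`T0001` is frame index
0); all in-memory indices are 0-based. Physical conversions use the
acquisition constants: lateral resolution (default 1.64 μm/px), z
spacing (10 μm), sampling interval (1 min/frame) and the start of
imaging in minutes post injury (MPI, default 25). All gating and metric
distances are 3-D Euclidean in μm under this anisotropic scaling; a
2-D analysis simply passes 2-D positions.

## Fluorescence quantification

**Projection.** Each frame's z-sections are fused by maximum-intensity
projection. For segmentation, the stack is first rescaled jointly
(frame-wide min→0, max→1) so relative z structure is preserved;
intensity *measurements* always use the unscaled projection, keeping
I, B, X and CTF on the raw bit-depth scale of the input TIFFs. A mean
projection is available (`RosParams.projection="mean"`), but the
maximum is the default because these cells and the probe signal span
only 2–3 of the 7 sections and a mean would dilute peak signal.

**Denoising.** A median filter (default 3×3, impulse noise) followed by
a Gaussian blur (default σ = 1 px, shot noise). Size 1 / σ 0 is the
identity.

**Tissue segmentation.** Threshold (user value P1, or Otsu on the
denoised composite when unset — a deterministic default for unattended
batch runs) followed by morphological *opening* with a Euclidean disc
of radius 20 px. Opening rather than bare erosion: erosion alone would
retract the true tissue boundary by the kernel radius, while opening
removes speckle smaller than the disc and returns the retained boundary
to place. The opening is computed with two exact Euclidean distance
transforms (erode: distance-to-background > r; dilate back), which is
exact for a disc structuring element and much faster than a dense
20-px footprint.

One practical caveat surfaced by the tests: under joint per-frame
rescaling, a wound signal that brightens over time pushes tissue down
the [0, 1] scale, so a data-driven (Otsu) threshold can drift across
frames. For time series where the dynamic range changes strongly, a
fixed P1 keeps the ROI area stable.

**Wound ROI.** The traced margin polyline (sub-pixel vertices allowed)
is dilated by the radial distance P3 (default 65 μm) using exact
per-pixel point-to-segment distances — not a rasterized dilation — and
intersected with the tissue mask. Multiple margins (double wounds)
contribute the union of their bands. The ROI is monotone in P3 by
construction.

**Background and CTF.** B is the pooled pixel mean over all background
circles (the unweighted reading of "averaged to a single value");
per-circle averaging, which differs only when circles cover unequal
pixel counts, is available behind `pool_pixels=False`. Then X = I − B,
IntDen = A·X and CTF = A·(I − B). The uncorrected A·I is stored too, so
either integrated-density convention is recoverable from the record.
Negative X (background above ROI signal) propagates to negative CTF
and is never clamped — clamping would bias time-series averages.
Unwounded baselines average the per-circle means of n = 40 circles of
10 px diameter (user-placed, or seeded-random inside tissue) into a
single I, with A the total circle pixel count.

## Cell detection and keyhole linking

**Detection.** Hysteresis segmentation in 3-D: voxels ≥ high seed
regions and grow through voxels ≥ low (a single-threshold mode is the
degenerate low = high). Components are 26-connected; an optional z-gap
bridge merges components split across empty sections. The minimum
"surface area" (default 80 px²) is enforced on the largest single-plane
footprint of the 3-D component, since in-plane pixel count at the
lateral resolution is what that criterion describes. Centroids are
intensity-weighted and converted to μm.

**Keyhole gate.** The linking gate is the union of (a) a disc of radius
ρ = 15 μm about the track's last position, catching slow or reversing
cells, and (b) a wedge with apex at the last position, axis toward the
constant-velocity prediction p + (p − p_prev), half-angle 30° and
radial reach 3× the last displacement, catching persistent motion. A
track with a single detection uses a plain disc (first-link radius,
20 μm); a zero-velocity prediction degrades to the disc alone. These
defaults were chosen for the phantom's motion regime (mean step
≤ 5 μm/frame) and are fully exposed in `KeyholeParams`.

**Assignment.** Within a frame, gated (track, candidate) pairs are
matched greedily in ascending distance with a total ordering of
tie-breaks (distance, then track id, then candidate coordinates), so
identical inputs always give identical tracks. Greedy matching
reproduces the sequential keyhole behaviour and is cheap; a global
optimal-assignment mode (Hungarian) exists and is used by the tests as
an independent cross-check on well-separated scenes, where the two must
agree. Unmatched candidates seed new tracks — every detection belongs
to exactly one track, making conservation trivially auditable. Tracks
unmatched for more than `max_gap` (default 1) frames terminate.

**Quality flags.** Lifespan-1 tracks are flagged `artifact`; pairs of
tracks co-detected within a fusion radius (default 10 μm) are flagged
`collision`. Flags are advisory and filterable; nothing is deleted.

## Track selection and kinetics

A track enters a window's analysis when its centroid is detectable in
at least P5 % (default 70 %, boundary inclusive — 63 of 90 frames
qualifies) of the window's frames; retained tracks are clipped to the
window so absent centroids contribute no measures. Steps span
consecutive detections only; across a gap of g frames Δt = g × sampling
and no interpolation is performed.

Per track: instantaneous speeds |d_i|/Δt_i; mean velocity = path length
over elapsed detected time (i.e. the Δt-weighted mean of speeds; an
unweighted mean is a flag away); net, max and path distances;
meandering index = net/path (reported as missing, not 0, for zero-path
tracks); static ratio = fraction of steps ≤ P6 (default 0.9 μm,
boundary static-inclusive). Orientation uses the *radial* convention:
a step is forward iff it strictly decreases the Euclidean distance to
the wound epicenter S_o. FMI = forward/total; FBI =
(forward − backward)/total, with zero-change steps counting only in the
denominator, so FBI = 2·FMI − 1 exactly when no step is radially
neutral. A projection-on-axis FMI variant common elsewhere in the
migration literature is intentionally not the default, because wounds
here are point-like epicenters.

Spatial domains are concentric shells about S_o: S1 is the disc of
radius r1 = |N_o − S_o| (N_o the notochord tip), and S2–S4 are
successive shells of width P9 (default 50 μm), upper boundaries closed;
positions beyond r4 map to no domain. The geometry of these domains is
a documented modelling choice — shells, not sectors or anatomical
regions. A track's domain is that of its first in-window detection
(per-step assignment is available). "Distance between tracks" is
provided as an auxiliary pairwise measure (mean frame-wise distance
over co-detected frames) but excluded from default summaries for lack
of a standard downstream use.

Group summaries compute n, mean and SD per (condition × window ×
domain) cell; when a fish factor is present, per-fish means are taken
first and statistics run across fish, so each animal contributes one
value. Inferential statistics are deliberately out of scope — the
long-format CSV export feeds any stats package.

## Validation and export

DICE = 2|X∩Y|/(|X|+|Y|); two empty masks score 1 (perfect agreement on
absence) with a logged warning. Sequences report per-frame values,
mean ± SD, and flag frames below the 0.7 effectiveness threshold. CSV
mirrors are the canonical output (sorted, full precision, byte-stable);
the xlsx workbook is a convenience view. Export is append-safe keyed by
(experiment, fish): re-analysed keys replace their rows, others are
preserved, and re-export of unchanged inputs is byte-identical.

## The phantom generator

The phantom emulates the acquisition protocol — 512×512 px at
1.64 μm/px, 7 z-sections at 10 μm, 90 frames at 1 min from 25 MPI,
16-bit, three channels — with exact ground truth:

* **Tissue**: a fixed fin-shaped polygon; BF renders it dark on a
  bright field.
* **Wound**: a V-shaped margin polyline hitting the perimeter target
  within 1 % (default 320 μm; double wounds split 544 μm across two
  stacked Vs). The RED probe signal decays exponentially from the
  margin (decay length 25 μm) on top of tissue autofluorescence (150)
  and a camera offset (100); an optional linear amplitude growth makes
  monotone-CTF scenarios.
* **Cells**: anisotropic 3-D Gaussians (nominal radius 8 μm, spanning
  2–3 z-sections, within the 10–20 μm depth range of these cells) on a
  drift-plus-diffusion walk toward per-cell arrival slots near the
  wound (drift 3 μm/min, jitter SD 1 μm/step). The walk maintains a
  pairwise separation of 25 μm — the density regime the tracker's
  recovery guarantees refer to — and rejects steps leaving the tissue.
  Default speeds put true mean velocities in the 2.5–4.5 μm/min range
  typical of these cells.
* **Noise**: Poisson shot noise (gain 4) then Gaussian read noise
  (SD 10), applied last; disabling both yields frames equal to the
  quantized ground-truth render, and the analytic per-frame CTF equals
  the pixel-sum over the noise-free projection exactly.

All randomness flows from one seed through spawned per-frame child
streams, so output is bit-identical across runs and frames can be
rendered independently — the full default phantom (~1 GB as arrays) is
streamed rather than materialised.

Cohorts (`scripted_cohort`) stratify unwounded / single / double
conditions: zero wound signal and zero drift for unwounded (a sham
margin is kept so the same ROI machinery measures baseline CTF), and
signal amplitude, perimeter and drift scaling with severity. This
forces the recoverable orderings CTF(double) > CTF(single) >
CTF(unwounded) and speed(double) > speed(single); cohort membership,
seeds and true parameters are recorded for recovery testing. The motion
model exists to make metric recovery testable against known truth — it
is not a chemotaxis model, and nothing here simulates probe chemistry
or reaction–diffusion kinetics.

**What phantom results do not show.** Real fins move, bleach, and have
heterogeneous autofluorescence; real macrophages change shape, touch,
and leave the volume; real wound margins are drawn by hand on drifting
anatomy. Passing the phantom suites demonstrates that the *algorithms*
are implemented correctly against exact truth, not that the default
thresholds transfer to any particular microscope. P1, the hysteresis
pair and the keyhole radii are expected to need per-dataset tuning.

## Problem sizes in the test suite

Unit tests run on reduced geometries (typically 160×160 px, 12 frames,
3 z-sections, 5 cells); the end-to-end segmentation validation and the
file-accounting checks run at the full default geometry (90 frames,
512×512×7, 1890 files); the cohort recovery study runs 12 phantoms at
256×256 px, 40 frames, 3 z-sections and 8 cells. These sizes are the
package's chosen trade-off between coverage and a test suite that runs
in minutes; the scripted orderings and density conditions are preserved
at every size.

## Known limitations

* The wound margin is user input (or phantom truth); no automated
  margin detection from brightfield is attempted.
* Brightfield is ingested and rendered but plays no role in detection
  or tracking.
* Hysteresis detection has no shape model: touching cells below the
  separation the thresholds can resolve merge into one detection
  (surfaced as `collision` flags after linking, not fixed).
* No photobleaching correction and no ratiometric (biosensor-style)
  analysis; CTF assumes a single-channel intensity probe.
* Session files are YAML with a schema version; there is no migration
  machinery yet — unknown versions are refused explicitly.
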