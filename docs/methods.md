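# Methods

This note documents the forward models, parameter choices, numerical
conventions and known limitations of the package. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is an
empirical claim beyond what the code reproduces.

## Axis convention

One convention is declared once and used everywhere: image **rows** are
axial (depth, positive down from the transducer face), image **columns**
are lateral, and the **slice index** of a volume is elevation (the sweep
direction). Physical coordinates are (x lateral, y axial, z elevation) in
mm; `Volume.spacing_mm` and `origin_mm` are stored in (axial, lateral,
elevation) order. Freehand volumes are reconstructed directly on this
convention, so no posterior reorientation of the gridded volume is needed.

## The digital phantom

`default_phantom()` models a multi-purpose grayscale QA phantom under a
10-mm water standoff:

| element | layout | purpose |
|---|---|---|
| surface | depth 10 mm + gentle quadratic curvature (≤ ~1 mm) | stability metric |
| axial filaments | x = −12, z = 30, depths 20–50 mm (10-mm spacing) | 30-mm axial span |
| elevation filaments | x = 12, depth 20, z = 5–55 mm | 50-mm elevation span |
| resolution wire | (4.5, 20, 25) mm, 0.1-mm diameter | FWHM measurements |
| contrast cylinders | r = 3.5 mm, depth 35, x = −18…18 | −9…+6 dB levels |

Echo levels are 8-bit gray: tissue background 90, water 8, surface
interface peak 220, wire response amplitude 160, additive zero-mean
Gaussian speckle of σ = 6 by default. The scanner's dB→gray mapping is a
configurable **linear** map, `gray = background + g·dB` with g = 6.3
gray/dB by default, so recovering the contrast-resolution slope is a
parameter-recovery experiment; an amplitude map
(`gray = background·10^(dB/20)`) is available as an option. Real scanners
apply a proprietary log-compression; neither map is claimed to reproduce a
specific device.

Distance-calibration errors are injected through
`apply_calibration_scale(phantom, axial_scale, elevation_scale)`, which
rescales the rendered filament coordinates about the first filament of
each group while leaving the nominal ground-truth spans (30/50 mm) in
place — exactly what a miscalibrated scan converter does to an image.

## Imaging forward model

`render_frame` is a geometric model of the imaging chain, not a wave
simulation. The beam is a separable Gaussian PSF with FWHM widths (axial
0.33 mm, lateral 0.5 mm, elevation/slice thickness 1.02 mm by default —
values chosen to be representative of a ~10 MHz intra-operative probe at
its focus). Wires and filaments are rendered as the beam response centered
on their intersection with the scan plane (anisotropy is evaluated in the
probe frame, so tilted poses are handled exactly); the surface as a bright
interface with the axial profile; cylinders as constant-gray disks.
Speckle is additive Gaussian on the 8-bit gray scale — a documented
fidelity limit (real speckle is multiplicative, correlated and
Rayleigh-like), sufficient for metrics that average over ROIs or use
noise-free renders. Frames are clipped to [0, 255] and quantized to uint8.
Pixel spacings follow the scanner's depth setting (0.10–0.12 mm at 4–5-cm
depth); continuous-mode frames are rendered at instantaneous poses with no
intra-frame motion blur (the blur kernel of a real scanner is unknown and
at 0.1–1 mm/frame motion the effect is sub-pixel).

## Acquisition simulation

**Motorized.** Poses advance in exact elevation steps (0.1/0.2/0.5/1.0 mm)
with zero deviation; stepwise timestamps are spaced by the 0.5-s dwell,
continuous ones by 1/FPS with step = velocity/FPS. Compound imaging
averages 5 renders at the identical pose (noise std shrinks by √5) and is
available only for stepwise movement.

**Freehand.** Constant mean elevation velocity (default 3 mm/s over a
60-mm sweep) plus tremor: per axis, a sum of three random-frequency
sinusoids in the physiological 8–12 Hz band whose total displacement std
equals the configured amplitude, plus integrated-white-noise drift. Zero
amplitudes reduce exactly to an ideal sweep. Operator presets differ only
in steadiness (A: 0.3 mm / 0.5°; B: 0.15 mm / 0.3°) — a modeling choice to
exercise the operator-variability statistics, not a claim about any real
operator.

**Tracking.** The true path is resampled at 40 Hz; i.i.d. Gaussian noise
is added so the **3-D error-norm RMS** equals the sensor specification
(0.48 mm position, 0.30° orientation — per-component σ is RMS/√3); the
stream's timestamps carry a constant clock offset (−30 ms by default)
relative to the image clock. Real EM-tracking error has bias and drift
components this white model ignores, which makes the simulated freehand
stability pessimistic relative to a well-calibrated commercial system.

**Temporal calibration.** A shifted constant-velocity sweep is
indistinguishable from itself at any lag, so — as in practice — the offset
is estimated from a dedicated calibration acquisition: the probe bobs
axially (0.8 Hz, ±4 mm, 6 s, far below the frame rate so nothing aliases)
and the image-derived axial position (surface row per frame) is
cross-correlated, after linear detrending, with the tracked axial position
over a ±250-ms lag grid at 2-ms resolution. The estimate is applied to the
tracking timestamps before gridding.

## Reconstruction

**Stacking** places frame k's pixels unchanged at slice k; elevation
spacing is the step size. **PNN** interpolates the pose at each frame time
(linear in position and in the small-angle orientation triple between
40-Hz samples), maps every pixel to its nearest voxel on an isotropic grid
(0.22 mm default), keeps the **maximum** value on collisions, and then
fills each empty voxel lying within a Chebyshev radius of 3 voxels of any
filled voxel with the value of the Euclidean-nearest filled voxel.
Distance ties are broken toward the smallest flattened voxel index
(equivalently, lexicographic neighbor offset). Whether a real PNN
implementation fills with the nearest value or a local mean within that
distance is not documented anywhere we could verify; nearest-value was
chosen and is pinned by a brute-force oracle test. Frames without
bracketing tracking samples are dropped and counted in the volume's
provenance. The voxel grid's origin snaps to a multiple of the voxel size,
so an ideal sweep at step = voxel size degenerates to bit-exact stacking.

## Numerical conventions in the metrics

* **Peak finding** is an automated argmax; gray-value ties resolve to the
  tied voxel nearest the tied-set centroid (the automated analogue of
  picking the center pixel of a saturated marker), then to the smallest
  index. A ±1-px manual-selection jitter can be emulated by perturbing the
  ROI, but is off by default.
* **FWHM**: background = median of the outer 10 % of profile samples; a
  clipped peak (no half-crossing on one side) raises rather than returning
  a truncated width. On a noise-free Gaussian ladder (σ = 0.1–1.0 mm,
  0.1-mm sampling) the measured FWHM is within 0.023 mm of 2√(2 ln 2)σ.
* **Surface segmentation** uses the first axial index with gray ≥ 100
  (8-bit) per elevation column of the mid-lateral plane; the baseline row
  sits 10 px above the shallowest surface point of the central-25 %
  window (both configurable). `Df` is the forward difference; min/max are
  converted to mm after differencing (equivalent up to the positive
  spacing factor). The phantom's curvature is deliberately not detrended.
* **ICC** is ICC(2,1) (two-way random effects, absolute agreement, single
  measures), labeled as such in all outputs; the flavor is a convention
  choice. Zero between-target variance produces a warning and the value as
  computed, never a crash. The freehand-vs-motorized contrast is reported
  as Welch's t; fitting a mixed model is left to downstream tools, which
  can consume the long-format table directly.

## Problem sizes

Unit and property tests run on frames of 20–140 rows and tiny voxel grids;
the PNN oracle suite uses 100 random 6×6×6 instances. Recovery experiments
use the sizes of the scenarios they emulate: 600-slice stacks for
stability (150 baseline columns, ≥10 seeds), 0.12-mm pixels and 0.22-mm
PNN voxels throughout, full 480×420 frames for the end-to-end examples.
The grid replication defaults to a coarse-pixel preset (0.28-mm pixels)
for routine runs; `--preset full` renders at native resolution.

## Known limitations

* **Sub-pixel stability floor.** The surface is segmented at integer pixel
  indices, so the measured stability RMS cannot fall below the pixel-
  quantization floor: for a random-walk surface with increment std σ
  (pixels), the quantized forward difference has `E[Df²] ≈ σ√(2/π)` for
  σ ≲ 0.6 px, inflating the recovered RMS by ~29 % at σ = 0.5 px (0.06 mm
  at 0.12-mm pixels) but only ~12 % at σ = 0.77 px. Recovery of stability
  values below about half a pixel is therefore quantization-limited — a
  property of the measurement procedure itself, shared by any
  threshold-per-column segmentation, not of the simulator.
* No acoustic propagation, attenuation/TGC, refraction, shadowing or
  speckle correlation; no intra-frame motion blur; EM noise is white.
* Passing recovery tests show the *measurement procedures* are unbiased at
  these conditions; they cannot validate scanner-specific behavior (gray
  mapping, true PSF shape) that the simulator parameterizes by fiat.
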