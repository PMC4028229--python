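# Methods

This note documents the models, numerical choices and limitations of the
`epioct` pipeline in one place.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself verify.

## Coordinate conventions

Lateral `x` in mm, origin at the scan centre, positive = nasal (right eye)
on the horizontal meridian and superior on the vertical one.  Axial `z` in
mm of *optical* depth, increasing downward from the image top.  Above the
front surface the medium is air, so optical and physical depth coincide;
below it they differ by the group index.  Intensity arrays are indexed
`[a_scan, axial_sample]`; A-scans are telecentric (parallel vertical
rays), matching a telecentric light-delivery scan head — no fan-beam
geometry is modelled.

## The synthetic cornea

**Geometry.**  The default raster is 2048 A-scans × 4096 samples over
13.465 mm × 7.281 mm (air), i.e. 6.6 µm lateral and 1.8 µm axial pitch,
with a 4.6-µm axial PSF FWHM in air (4.6/1.389 ≈ 3.3 µm in tissue).  The
anterior surface is a sphere of radius 7.8 mm (a typical adult anterior
corneal radius), apex 0.8 mm below the image top.  A flat-surface limit
(`anterior_radius_mm = inf`) exists for closed-form checks.

**Thickness field.**  Epithelial thickness at signed lateral distance `d`
(mm) from the corneal apex is

    T(d, dir) = T0 + c_dir · |d|^p   [µm],  p = 3 by default,

with direction chosen by the sign of `d` and the meridian.  The default
coefficients are solved from the 5-mm endpoints 63 µm (temporal, nasal),
58 µm (superior) and 72 µm (inferior) with `T0` = 52 µm, i.e.
`c = (T5 − T0)/125` = 0.088 / 0.048 / 0.16 µm·mm⁻³.  A cubic rather than
quadratic radial term is used because, for the inferior direction, no
quadratic can keep the paracentral zone (radius 1.5–3 mm) below ~57 µm
while reaching ~72 µm at 5 mm.  With these defaults the *annular* zone
means (averaged over the four directions) are ≈ 52.1 µm central,
≈ 53.2 µm paracentral and ≈ 58.5 µm peripheral, inside the target ranges
51–53 / 52–57 / 58–72 µm.  Per-direction peripheral means straddle these
ranges (the superior direction alone averages ~55 µm); the ranges are
reproduced by zone averages, not by every direction separately.  The tear
film is not a separate layer; it is absorbed into `T`.

**Back surface and ground truth.**  The back (epithelium–Bowman) surface
is the anterior sphere offset *inward along the local normal* by `T`, so
the perpendicular thickness has exact ground truth by construction.  Each
rendered scan carries the true front curve, back polyline, per-A-scan
refracted ray, in-tissue path length and thickness.

**Refraction forward model.**  For the A-scan at `x`: the front echo sits
at the surface depth `z_f(x)`; the refracted direction follows Snell's law
at the local normal (air → n = 1.389); the physical path `s(x)` to the
back surface is found by numerical ray–polyline intersection (vertex
windows around the entry point; the lateral walk of the refracted ray over
a ~50-µm path is only a few µm, so a ±0.6-mm window is generous); the back
echo is placed at optical depth `z_f + n·s`.  Echoes are Gaussian ridges
(front: PSF FWHM; back: n-broadened), so a three-point parabola on the
log-intensity recovers their centres exactly in the noiseless limit.

**Noise.**  Multiplicative Gaussian speckle (relative SD 0.25), a
folded-Gaussian background floor (SD 600 on the 16-bit scale against a
front-surface amplitude of 18 000), and amplitude attenuation
`exp(−z/2.0 mm)` emulating the spectral-domain sensitivity roll-off.  The
roll-off is what makes the peripheral cornea (deeper by ~1.8 mm of
sagitta at ±5 mm) noisier and drives the centre-to-periphery repeatability
gradient.  The back interface reflects at 0.6× the front amplitude.
These are plausibility choices on an arbitrary intensity scale — the real
instrument's noise figures are unknown — so CoR *magnitudes* from the
phantom are not calibrated to clinical values; only their spatial
structure is meaningful.

**Cohorts and retest.**  Per-subject `T0 ~ N(52.0, 3.2²)` µm, shared by
both eyes; shape coefficients are common to all subjects.  Test 2 differs
from test 1 by a fresh noise realisation plus decentration
(`N(0, 0.05²)` mm) and tilt (`N(0, 0.3²)` degrees).  Tilt is implemented
as a rotation of the *material* axis about the sphere centre: a sphere is
rotation-invariant, so tilt re-orients the thickness pattern without
moving the geometric surface, and combined with decentration it perturbs
the apex-anchored profile between tests.  The default cohort is
21 subjects × 2 eyes × 2 meridians × 2 tests = 168 scans.

**Reduced resolution.**  `ScanGeometry.scaled(f)` divides the pixel counts
by `f` and broadens the rendered PSF by `f`, keeping the ridge ~1 px wide
so sub-pixel localisation stays meaningful on the coarse grid.  Cohort
runs in the test suite and acceptance script use `f = 4` (512 × 1024);
at `f = 8` the front and back ridges overlap (separation/σ ≈ 3) and
thickness acquires a micron-scale bias, so `f = 4` is the supported fast
mode.  Single-scan physics checks run at full resolution.

## Segmentation

Boundaries are laterally continuous minimum-cost paths through the
negative of the axially smoothed, per-A-scan-normalised intensity, found
by dynamic programming with a per-step vertical jump limit (sliding-window
minimum, so the pass is O(pixels)).  Ties break toward the smaller axial
index, making the trace deterministic.  The jump limit defaults to
`ceil(2.0 × lateral/axial pitch ratio)`, enough for the steepest
anatomical slope (~1.8 at the 6.7-mm scan edge).  The back path is
restricted to a band `[front + min_sep, front + max_sep]` (optical µm)
below the front path; `min_sep` is raised to 3× the effective ridge width
when smoothing/PSF would otherwise leak the front ridge into the band.
Sub-pixel refinement is a log-parabola through the three samples around
each node.  A-scans whose ridge strength falls below
`median + 6 × 1.4826·MAD` of the smoothed image are flagged invalid —
this is what blanks eyelid-occluded columns and the noise-dominated far
periphery rather than guessing.  If no A-scan passes, `NoSurfaceFound`
is raised.  The tracer is fully automatic; a second human observer can be
emulated by multiplicative jitter of the smoothing sigma and SNR
threshold (`jitter_params`).

## Refraction correction

Surface normals come from local quadratic fits of the front trace in
±0.25-mm windows (matching the profile bin half-width) rather than finite
differences, which amplify noise in the derivative; windows shrink
one-sidedly at the lateral edges.  Each back echo is repositioned to
`entry + s·t̂`, with `s = (z_back − z_front)/n` and `t̂` the Snell-refracted
unit direction; with `n = 1` the correction is the identity.  The
correction is 2-D within the meridian plane (the analysed scans are
meridian B-scans; out-of-plane refraction is not modelled) and handles a
single interface only.  On noiseless phantoms the corrected back surface
lands within 0.05 µm of ground truth at full resolution — the round-trip
property that anchors the whole pipeline.

## Profiling

The apex is the vertex of a quadratic fitted to the shallowest 0.15 mm of
the front surface; a flat surface is flagged degenerate and anchored at
x = 0.  Thickness is the minimum distance from each front point to the
piecewise-linear corrected back curve (rigid-motion invariant).  Samples
are averaged in ±0.25-mm boxcar bins at 0.5-mm steps — the "average
matrix" — with positions *relative to the detected apex*; scan-centre
anchoring is available via `profile_bscan(anchor_apex=False)` since the
choice is not externally fixed.  Left-eye horizontal profiles are
mirrored onto right-eye orientation; vertical profiles never are.  Empty
bins are explicitly missing and never imputed; averages over profiles use
available values with per-point counts.  Zone membership uses half-open
radius intervals [0, 1.5), [1.5, 3.0), [3.0, 5.0], the outermost closed
so the ±5-mm grid points belong to the peripheral zone.

## Repeatability statistics

CoR uses the sample (n−1) SD of the differences; CoR% divides by the
pooled mean of both tests.  The ICC is ICC(2,1) (two-way random effects,
absolute agreement, single measurement) computed directly from the ANOVA
mean squares — the standard form for test-retest agreement — and is
cross-checked in the tests against a loop-based ANOVA oracle and against
`pingouin`'s ICC(A,1) to 1e-10.  The paired *t* is implemented from the
textbook formula so that degenerate inputs have defined behaviour
(zero-variance, zero-mean differences → t = 0, p = 1; zero-variance,
non-zero mean → p = 0 with a warning), and matches `scipy.stats.ttest_rel`
on regular data.  Reports aggregate over a central 6-mm zone (|x| ≤ 3 mm)
and the periphery (|x| > 3 mm).  No multiple-testing correction is applied
across grid points; per-location p values are reported raw.  Cohort
reports average the two eyes of each subject (after mirroring) before
computing per-location statistics across subjects.

## Problem sizes

Default analysis runs use the 21-subject cohort at reduced resolution
(f = 4; 168 scans), the scale at which the acceptance script reproduces
the 52-µm cohort mean within its ±1.5-µm band in a few minutes.  The
repeatability-gradient check uses five 5-subject horizontal-only cohorts
(median over seeds).  These sizes are the package's fast defaults; all of
them scale up by changing `resolution_factor` and `n_subjects`.

## Known limitations

- No spectral-domain signal formation (interferograms, k-space
  resampling); images are formed directly as Gaussian ridges plus noise.
- Speckle is independent Gaussian, not correlated fully developed speckle;
  absolute CoR/ICC levels therefore do not calibrate to any instrument.
- Motion is rigid jitter only; no intra-scan eye movement or blinks.
- Only the two analysed meridians of a radial pattern are simulated.
- Deeper corneal interfaces (stroma, endothelium) are neither rendered
  with realistic contrast nor segmented.
- Passing the synthetic end-to-end checks demonstrates correctness of the
  *algorithms* under the stated image model, not clinical performance on
  human scans.
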