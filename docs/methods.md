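# Methods

This note documents the models, conventions, and numerical choices behind
`fuslbx`, and what the synthetic-data generators do and do not emulate.

## Cavitation dose metrics

Each sonication pulse is transformed once with a rectangular-window one-sided
DFT, normalized so that an integer-cycle tone of amplitude A appears as a
single bin of magnitude A (interior bins scaled by 2/N, DC and Nyquist by
1/N).  Ten-millisecond pulses at MHz sampling give ~100 Hz bin spacing, which
resolves the 0.3 MHz-wide analysis bands by three orders of magnitude; no
sub-segment averaging or tapering is applied, so the notch geometry is free
of window leakage for bin-aligned tones.

"RMS amplitude" of a band is the root-mean-square of the magnitude-spectrum
bins whose frequency lies in the band (closed interval at both edges).  A bin
falling simultaneously in a kept broadband interval and an excluded band
(possible only exactly at a shared edge) counts as excluded.  Stable
cavitation (SC) uses the subharmonic band `f0/2 ± hw`; inertial cavitation
(IC) uses `[0.3, 2.0]` MHz minus the subharmonic band and the harmonic bands
`n·f0 ± hw`, n = 1..3, with `hw = 0.15` MHz.  Ultraharmonics (e.g. `3·f0/2`)
are *not* excluded: the notch list is exactly the subharmonic plus the first
three harmonics.  For `f0 = 0.65` MHz the kept broadband intervals are
`[0.475, 0.5]`, `[0.8, 1.15]`, `[1.45, 1.8]` MHz.

Doses are normalized in decibels to the pre-microbubble baseline:
`SC_dB = 20 log10(SC_linear / baseline_SC)` with `baseline_SC` the mean
linear level over baseline pulses (those preceding the microbubble injection
time).  A zero-energy baseline leaves the dB track flagged undefined while
linear levels are still reported.  Group comparisons use each animal's mean
baseline and mean post-microbubble *linear* level in a paired t-test.

An alternative reading of "RMS amplitude" — time-domain RMS of a
band-pass-filtered signal — would require filter design choices (order,
ripple, edge behavior) that introduce band-edge artifacts in the notched IC
geometry; the spectral-bin definition is parameter-free and exactly additive
over disjoint bands, which is why it was chosen.

## Opening volumetry

Volumes use axis order (X = left-right, Y = head-foot, Z =
anterior-posterior), Z being the slice axis; world coordinates are mm at
voxel centers, `world = origin + index * spacing`.  The elliptical ROI is
evaluated in-plane per slice (voxel-center membership, boundary inclusive)
over an inclusive slice range, minus an optional user-supplied exclusion mask
(the ventricles in practice; no auto-segmentation is attempted).

The classification threshold is `mean + 3·SD` of the contralateral ROI
intensities, pooled over all of its slices, with the sample (n−1) SD; a FUS+
voxel is open when *strictly* above the threshold.  Pooling (rather than
per-slice re-estimation) was chosen for stability with small ROIs.  Opening
volume equals the open-voxel count times the voxel volume exactly; the
centroid is the unweighted mean of open-voxel centers, and the targeting
offset is centroid minus planned focus, signed per axis.  Pre-contrast
volumes are accepted for difference imaging but classification is post-only.
On pure noise the expected open fraction is the Gaussian tail Φ(−3) ≈ 0.135%,
which the property tests verify.

## Extended Tofts model

The arterial input function is a biexponential population curve
`Cp(t) = A1 e^(−m1(t−t0)) + A2 e^(−m2(t−t0))` for `t ≥ t0`, zero before,
with defaults A1 = 3.99, A2 = 4.78 (mM-scale amplitudes), m1 = 0.144,
m2 = 0.0111 min⁻¹ — classic population values for a gadolinium bolus — and
`t0` set to the protocol's 60 s post-scan-start injection.  The study's own
AIF handling lived inside an external pharmacokinetic tool and is not
recoverable, so the AIF is explicit configuration here; generator and fitter
share it, which makes parameter recovery well-posed.

Because `Cp` is piecewise exponential, the convolution with `e^(−kep t)` has
the closed form `Σᵢ Aᵢ (e^(−mᵢτ) − e^(−kep τ))/(kep − mᵢ)`, `τ = t − t0`,
with the limit `τ e^(−kep τ)` when `kep → mᵢ` (switched at a relative
difference of 1e-10).  Forward curves therefore carry no discretization
error at the 7.5 s protocol sampling, and recovery tests isolate the
optimizer: noiseless fits over a 3×3×3 grid of (Ktrans, ve, vp) recover all
parameters to < 1%.

Fitting is bounded nonlinear least squares (trust-region reflective) on
(Ktrans, ve, vp) with defaults init (0.01 min⁻¹, 0.2, 0.02) and bounds
Ktrans ∈ [0, 1], ve ∈ [1e-4, 1], vp ∈ [0, 0.5]; tolerances ftol = gtol =
1e-10.  An all-zero curve short-circuits to Ktrans = 0, vp = 0.  An optional
five-point multi-start over Ktrans decades (1e-4 … 0.5) guards against local
minima on noisy data; clean curves do not need it.  Signal-to-concentration
conversion is the linear relative-enhancement model
`C = (S − S̄0)/(k·S̄0)` with a user-supplied scale k — flip-angle/T10 maps
needed for the full spoiled-gradient-echo equation are out of scope — and
voxelwise Ktrans maps are summarized as the arithmetic mean over a
5 × 5 voxel window, matching the study's ROI convention.

## Biomarker statistics

The 4PL curve `OD(x) = D + (A−D)/(1+(x/C)^B)` uses the limit convention
OD(0) = A for B > 0.  Inversion is analytic and only defined strictly
between the asymptotes; values at or beyond them are reported as
below/above the quantitation limit.  Curve fitting initializes A and D from
the extreme standards, C at the geometric mid concentration, B = 1.

The paired t-test uses `t = d̄/(s_d/√n)` with the sample SD of the
differences and a two-sided Student-t p on n−1 degrees of freedom.  All-zero
differences return the null outcome (t = 0, p = 1); a constant *nonzero*
difference has an undefined statistic and raises a degenerate-variance
error.  (Constancy is detected exactly, not via the floating-point SD, which
can be ~1e-18 instead of 0 for identical values.)

The Wilcoxon matched-pairs signed-rank test is exact: zero differences are
dropped (Wilcoxon's convention, not Pratt's), ties in |d| receive mid-ranks,
`W = min(W⁺, W⁻)`, and the two-sided p doubles the lower tail of the null
distribution of W⁺ over all 2^m sign assignments, capped at 1.  The null
counts are computed by expanding `Πᵢ (1 + z^{2rᵢ})` by dynamic programming on
the doubled-rank lattice (mid-ranks are half-integers), which is identical to
literal enumeration; the test suite checks this against brute-force
enumeration for all n ≤ 10 and against an independent exact implementation on
tie-free data.  n > 20 is refused rather than silently approximated.

## Synthetic-data generators

All generators are pure functions of their configuration, including the
seed.

**PCD.**  Defaults follow the sonication protocol: f0 = 0.65 MHz, 1 Hz pulse
repetition frequency, 10 ms pulses, 3 min treatment (180 pulses), microbubble
injection midway between pulse 14 and 15 (15 baseline pulses).  The sampling
rate defaults to 10 MHz, comfortably above twice the highest analysis band
edge (2.1 MHz).  Every pulse carries the harmonic tones and a white-noise
floor of SD `broadband_sd`; post-microbubble pulses add the subharmonic tone,
and an optional `post_broadband_sd` raises the post-injection noise floor to
emulate inertial cavitation.  Microbubble arrival is instantaneous — no
circulation kinetics — and broadband emission is stationary white noise, not
burst-like transients; that suffices to exercise the band algebra and dose
normalization, but it means passing tests say nothing about transient-rich
real recordings.  No quantitative emission levels are published for this
protocol, so the tone amplitude defaults (1.0/0.3/0.1 harmonic, 0.5
subharmonic, 0.02 noise SD, arbitrary pressure units) are arbitrary and
exist to give clean detectability; only ratios and dB changes are meaningful.

**DCE.**  Curves are sampled every 7.5 s over 10 min with the bolus at 60 s,
the protocol's grid; noise is additive Gaussian with default SD 0
(noiseless), so recovery tests are exact and noisy behavior is probed only
in dedicated stochastic tests.

**T1 phantoms.**  Gaussian background (default 100 ± 5 intensity units) at
0.68 × 0.68 × 1.5 mm voxels with an additive ellipsoidal enhancement
(default 50, i.e. 10× the noise SD — strong, unambiguous enhancement as in a
successful opening).  Ellipsoid membership is by voxel center, the simplest
unambiguous rasterization; its volume converges to (4/3)πabc as voxels
shrink, and at the T1 resolution the discretization error for a 1.21 cm³
opening is under 1%.  The phantoms contain no anatomy, bias fields,
ventricles, or registration error, so threshold-rule tests validate the
classifier's arithmetic, not its robustness to real-brain confounds.

**Biomarker panels.**  Per animal and analyte, (pre, post) is a bivariate
normal with the configured margins and within-animal correlation (default
0.5 — plausible biological pairing, unreported in the study), clipped at
zero.  Clipping (rather than resample-truncation) keeps the large-n sample
mean within sampling error of the configured mean even though the printed
SDs are large relative to the means.  Defaults are the printed group values:
GFAP 0.156 ± 0.068 → 0.353 ± 0.149 ng/mL, MBP 0.091 ± 0.034 → 0.364 ± 0.159
ng/mL.  The default 4PL curve (A = 0.05, D = 2.5, C = 0.5 ng/mL, B = 1.2) is
a generic sandwich-ELISA shape whose dynamic range covers those levels.

## Pipeline

The pipeline runs the four arms on a synthetic cohort: 7 animals for the
cavitation/volume/biomarker arms and 4 for Ktrans, matching the study's
group sizes.  Per-arm and per-animal seeds derive from the run seed through
`numpy` seed sequences, so a fixed configuration yields a byte-identical
JSON report.  In the opening arm each animal's FUS+ opening volume is drawn
from N(1.21, 1.84) cm³ clipped to [0.05, 2.8] cm³ — the opening must exist
and fit inside the analysis ROI and grid — and the opening centroid is
displaced from the planned focus by the fixed per-axis offsets
(−1.9, −0.4, +5.3) mm rather than per-animal draws, whose printed spreads
would push openings off the simulation grid.  FUS− volumes apply the same
mean + 3 SD rule with the ROI roles swapped.  These choices preserve the
structural comparisons (signs of paired differences, exact Wilcoxon p,
paired-t outcomes) that the report is meant to exercise.  The null
configuration (`effect=False`) removes the subharmonic tone, the
enhancement, the Ktrans elevation, and the biomarker shift, leaving six
exact level-0.05 tests whose aggregate rejection rate the suite checks.

Pipeline-level tests and the acceptance script run the PCD arm at reduced
problem sizes (1–2 ms pulses, ~12 pulses per animal) — the band algebra and
normalization are independent of pulse length and count — while
single-recording tests exercise the full protocol geometry.

## Known limitations

* No acoustic propagation, skull attenuation, microbubble dynamics, or MR
  sequence simulation; generators emulate the *outputs* of those physical
  layers, not the physics.
* No image registration: pre/post volumes are assumed co-registered, as in a
  single anesthetized session.
* The exact Wilcoxon is limited to n ≤ 20 by design; larger panels need a
  large-sample approximation that is deliberately out of scope.
* No multiple-testing correction across analytes or arms (none was applied
  in the original analysis being mirrored).
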