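# fuslbx

Quantification pipeline for **focused-ultrasound-enabled liquid biopsy
(FUS-LBx)** experiments: low-intensity focused ultrasound (FUS) plus
circulating microbubbles transiently opens the blood-brain barrier (BBB) so
that brain-restricted protein biomarkers leak into the bloodstream, where a
simple blood draw can measure them.  Validating the technique in a large
animal requires four quantitative readouts, and this package implements all
of them as a tested, reusable library with a seeded synthetic-data generator,
so the entire analysis runs end-to-end with no external data:

1. **Cavitation dose monitoring** (`fuslbx.cavitation`).  Passive cavitation
   detection (PCD) records acoustic emissions during each sonication pulse.
   Stable cavitation (SC, sustained bubble oscillation) is quantified as the
   RMS spectral amplitude in the subharmonic band `f0/2 ± 0.15 MHz`; inertial
   cavitation (IC, violent collapse) as the RMS over the broadband window
   0.3–2 MHz after notching out `f0/2 ± 0.15` and `n·f0 ± 0.15` MHz
   (n = 1, 2, 3).  Levels are normalized in dB to the pre-microbubble
   baseline and compared pre/post with paired t-tests.
2. **BBB-opening volumetry** (`fuslbx.opening`).  In post-contrast
   T1-weighted MRI, a voxel in the sonicated (FUS+) elliptical ROI is
   classified as "open" when its intensity exceeds `mean + 3·SD` of the
   contralateral (FUS−) ROI.  Opening volume is the per-slice open-voxel sum
   times the voxel volume; targeting offset is the open-mask centroid minus
   the planned focus, per axis.
3. **Pharmacokinetic permeability** (`fuslbx.pharmacokinetics`).  The
   extended Tofts model

   `Ct(t) = Ktrans ∫₀ᵗ Cp(τ) e^(−kep (t−τ)) dτ + vp Cp(t)`,  `kep = Ktrans/ve`

   is fitted to dynamic contrast-enhanced (DCE) MRI concentration curves by
   bounded nonlinear least squares to estimate `Ktrans` (min⁻¹), the standard
   index of BBB permeability.  The biexponential population arterial input
   function makes the convolution analytic, so forward curves are exact.
4. **Biomarker statistics** (`fuslbx.biomarkers`).  ELISA readouts are
   quantified through a four-parameter logistic (4PL) standard curve
   (`OD(x) = D + (A−D)/(1+(x/C)^B)`, fitted and analytically inverted), and
   paired pre/post panels are tested with the paired t-test and the *exact*
   Wilcoxon matched-pairs signed-rank test (at n = 7 animals, uniformly
   signed differences give p = 2/2⁷ = 0.0156 — only the exact convention
   produces this value).

`fuslbx.synthetic` generates every input with known ground truth (PCD
waveforms, DCE curves, T1 phantoms with ellipsoidal openings, paired
biomarker panels, ELISA plates), and `fuslbx.pipeline` orchestrates
simulate → analyze → report for a whole synthetic cohort (7 animals; 4 for
the Ktrans arm).

## Worked example

```python
import fuslbx as f

# Fit the extended Tofts model to a simulated DCE curve
cfg = f.DCESimConfig(truth=f.ToftsParams(ktrans=9.9e-3, ve=0.1, vp=0.01))
curve = f.simulate_tissue_curve(cfg)          # 7.5 s sampling, 10 min, 60 s bolus
res = f.fit_tofts(curve, cfg.effective_aif)
print(res.summary())

# Paired biomarker statistics on a 7-animal panel
panel = f.simulate_biomarker_panel(f.BiomarkerSimConfig(seed=1))
print(f.summarize_panel(panel).to_string(index=False))
```

prints

```
Extended Tofts model fit
========================================
n observations : 81
Ktrans (min^-1): 0.0099
ve             : 0.1
vp             : 0.01
kep (min^-1)   : 0.099
RSS            : 3.13734e-31
converged      : True

analyte  n  pre_mean   pre_sd  post_mean  post_sd  t_statistic  p_two_sided
   GFAP  7  0.165804 0.053856   0.380619 0.096394     9.169906     0.000095
    MBP  7  0.085332 0.014958   0.293004 0.217281     2.675505     0.036756
```

The fitter recovers the ground-truth influx constant (0.0099 min⁻¹) exactly
from the noiseless curve, and the 7-animal panel — generated at the plasma
GFAP/MBP calibration built into the defaults — shows the significant
post-sonication rise in both brain-specific proteins.

A command-line interface wraps every stage on files:

```sh
fuslbx simulate pcd --out rec.bin --seed 1
fuslbx analyze cavitation --input rec.bin --out dose.csv
fuslbx run --out report/        # full synthetic cohort, all four arms
```

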