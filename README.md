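# fdgquant

Quantification chain for longitudinal ¹⁸F-FDG PET studies of tumor-bearing
mice: plasma input-function reconstruction from image-derived blood data,
Patlak graphical analysis, sphere-model partial-volume correction, and
selection among blood-glucose/tumor-size regression models — plus a
synthetic-cohort generator so the whole chain runs and is testable without
animal data.

## The problem

In longitudinal small-animal FDG-PET, the quantities of interest — the
standardized uptake value (SUV) and the net FDG influx constant
*K*ᵢ = *K*₁*k*₃/(*k*₂+*k*₃) — are confounded by blood glucose level and by
tumor size. Small tumors lose apparent activity to the partial-volume
effect (PVE), and in some tumor lines FDG uptake saturates with glucose, so
raw SUV/*K*ᵢ trends over a growth study can be artifacts. This package
implements the full correction and model-selection machinery needed to
separate those effects:

1. **Input function.** The arterial plasma curve
   *C*ₚ(*t*) = *A*₁e^(−μ₁t) + *A*₂e^(−μ₂t) + *A*₃e^(−μ₃t) −
   (*A*₁+*A*₂+*A*₃)e^(−μ₄t) (zero at injection) is estimated by a Bayesian
   maximum-a-posteriori fit that simultaneously matches the early
   (< 1 min) left-ventricle curve (corrected for delay, dispersion and
   chamber recovery), one late whole-blood sample converted to plasma with
   the equilibrium ratio R_PB(*t*) = 0.386e^(−0.191t) + 1.165, and the
   muscle and liver curves under full two-tissue compartment models.
2. **Kinetics.** Tumor *K*ᵢ and intercept come from the Patlak plot
   *C*ᴛ/*C*ₚ vs ∫*C*ₚ/*C*ₚ over 15–60 min; SUV uses the last 15-min frame;
   MRGlu = *K*ᵢ·[Glc]/LC with lumped constants 1.4 (U87) and 1.0 (MDA).
3. **Partial volume.** The tumor is treated as a uniform sphere (diameter
   (6*V*/π)^⅓ from the caliper volume 0.5·L·W²) on a 10% background,
   blurred by an isotropic Gaussian PSF; the recovery coefficient RC is
   the mean blurred intensity inside the sphere, and measured values are
   divided by it.
4. **Model selection.** Four mean models relate a response *Y* (SUV/RC or
   *K*ᵢ/RC) to glucose and diameter: *Y* = *a*; *Y* = *a* + *c*·d;
   *Y* = *a*/(*b*+[Glc]); *Y* = (*a* + *c*·d)/(*b*+[Glc]). Each is fitted
   by least squares and by maximum-likelihood mixed-effects fits (per-mouse
   random deviations, diagonal covariance, all subsets); a non-significant
   *b* triggers a rebuild with *b* = 0; mixed fits are adopted only on a
   significant likelihood-ratio test; the winner is ranked by AICc.

The synthetic-data module generates cohorts with the full longitudinal
structure (linear tumor growth from ~2.5 mm, necrosis onset thresholds,
correlated glucose drift under anesthesia, dose ~ 18.28 ± 1.19 MBq,
count-statistics TAC noise, PV attenuation by current tumor size), with
every ground-truth value retained for recovery testing.

## Worked example

Simulate one U87 mouse, reconstruct the input function of a session, and
quantify it:

```python
from fdgquant import (CohortConfig, simulate_cohort, preprocess_early_lv,
                      fit_input_function, patlak_analysis, compute_suv,
                      mrglu, recovery_coefficient, apply_rc,
                      LUMPED_CONSTANTS)
from fdgquant.patlak import last_frame_value

cfg = CohortConfig(n_mice={"U87": 2, "MDA": 0})
rec = [r for r in simulate_cohort(cfg, seed=7)
       if r.session_id == "U8702_d015"][0]
sched = rec.tacs["tumor"].schedule

early = preprocess_early_lv(rec.tacs["LV"].values, sched, delay_s=2.0,
                            dispersion_tau_s=5.0, blood_rc=0.85)
fit = fit_input_function(early, rec.blood_sample,
                         rec.tacs["muscle"].values,
                         rec.tacs["liver"].values, sched)
pat = patlak_analysis(rec.tacs["tumor"].values, fit.input, sched)
rc = recovery_coefficient(rec.tumor_diameter, cfg.pv)
```

which prints, with the obvious formatting code:

```
session          : U8702_d015 (U87, day 15)
tumor diameter   : 4.60 mm
blood glucose    : 6.95 mmol/L (mean of start/end)
Patlak Ki        : 0.0306 mL/min/mL  (R^2 = 0.9996)
Patlak intercept : 0.510
SUV (last 15 min): 1.273
MRGlu            : 0.1519 umol/min/mL (LC = 1.4)
recovery coeff.  : 0.664
PV-corrected Ki  : 0.0461 mL/min/mL
true tissue Ki   : 0.0480 mL/min/mL
```

The measured 4.6 mm tumor recovers only 66% of its true activity (RC
0.664); dividing the Patlak slope by RC brings the estimate within ~4% of
the generating tissue *K*ᵢ for this session (the cohort-median input-fit
error is 3–5% at the default noise level).

The same chain runs from the shell:

```bash
fdgquant simulate --seed 7 --out cohort/
fdgquant fit-input --cohort-dir cohort/ --out cohort/input_fits.json
fdgquant quantify --cohort-dir cohort/ --input-fits cohort/input_fits.json --out cohort/metrics.csv
fdgquant pvcorrect --metrics cohort/metrics.csv --out cohort/metrics_pv.csv
fdgquant select-model --metrics cohort/metrics_pv.csv --response ki_over_rc --tumor-type U87
fdgquant run-all --seed 7 --out run/        # everything at once
```

On default synthetic cohorts the selection stage reproduces the expected
qualitative pattern: U87 chooses the inverse-glucose model
(*K*ᵢ/RC = *a*/[Glc], fixed effects) while MDA chooses the constant model
with a per-mouse random intercept.

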