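# Methods

This note documents the models implemented in `fdgquant`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate about real data.

## Frame schedule

All dynamic data live on the 35-frame, 60-minute protocol
(4×1 s, 15×0.5 s, 1×2 s, 1×4 s, 1×6 s, 1×15 s, 3×30 s, 1×60 s, 1×120 s,
3×180 s, 3×900 s, 1×51 s; total 3599.5 s). Frame values everywhere are
**frame averages** (integral over the frame divided by its duration), not
midpoint samples: list-mode data are binned that way, and midpoint
sampling visibly biases the 900-s frames. Where a "frame time" is needed
(Patlak cut, plotting) the frame mid-time is used.

## Tissue model

Tissues follow the two-tissue compartment FDG model with rates K1
(mL/min/mL), k2, k3, k4 (1/min) and a vascular fraction VB:

    C_T(t) = C1(t) + C2(t) + VB * C_B(t),     C_B = C_p / R_PB(t)

The vascular term is additive. Under this convention the late-time Patlak
slope of an irreversible tissue (k4 = 0) is exactly Ki = K1·k3/(k2+k3)
and the intercept is k2/(k2+k3)·C1/C_p + VB·C_B/C_p, which is the pair of
identities the graphical analysis relies on; a (1−VB)-weighted mixture
would make the measured slope (1−VB)·Ki and break the micro-parameter
oracle used in the tests.

Because the input is a sum of exponentials, C1 and C2 are computed in
closed form by convolution of exponentials (eigen-rates α₁ ≤ α₂ of the
2×2 kinetic system; α₁ = 0 when k4 = 0). Rate collisions (an input rate
equal to a kinetic eigenvalue) use the exact confluent limit t·e^(−αt);
a repeated eigenvalue (only possible at k3 = 0, k2 = k4) is split by a
relative 1e−7 nudge, far below measurement precision. Frame averages of
the tissue term are analytic; only the vascular term, which involves the
non-exponential ratio R_PB, is averaged with 8-point Gauss–Legendre
quadrature per frame (validated against adaptive quadrature at 1e−12).
Tumors are simulated irreversible (k4 = 0), muscle and liver with k4 > 0,
consistent with the Patlak linearity assumption used for tumors only.

## Input-function reconstruction

The plasma curve is the 4-exponential bolus form with implied fourth
amplitude −(A1+A2+A3), so C_p(0) = 0 exactly; with μ4 the largest rate
and A1..A3 ≥ 0 the curve is non-negative. The fit is a simultaneous MAP
estimation of 17 parameters (7 input, 5 muscle, 5 liver) against four
data blocks:

* early whole-blood points from the LV chamber, after shifting the time
  base by the delay (default 2 s), deconvolving the monoexponential
  dispersion kernel (default τ = 5 s) and dividing by the chamber
  recovery factor. The deconvolution works on frame averages via the
  exact identity b̄ = m̄ + τ·Δy/Δt per frame (edge values interpolated
  from the frame means), and the fit compares frame-averaged model
  predictions over the same windows — this removed a 2–3% systematic
  bias seen with instantaneous-sample deconvolution;
* one late whole-blood sample (70–80 min) converted to plasma by R_PB at
  its exact draw time;
* the muscle and liver TACs under their two-tissue models.

Residuals are standardized by assumed measurement SDs: TAC frames get the
count-statistics model SD = scale·√(value/duration); the early points are
further inflated by √(1 + 2(τ/Δ)²) (noise amplification of the
deconvolution) and floored by a 2%-of-peak systematic term (interpolation
artifacts scale with the bolus peak); the late sample uses a relative SD
(2% by default, matching the generator's sample noise). The Gaussian
penalty on log-parameters uses log-normal priors with 50% CV centered on
typical mouse FDG values (table in `input_function.default_priors`);
priors are overridable and the penalty weight is a parameter. Fitting is
in log-parameter space (positivity by construction), with ≥5 multi-starts
and the best objective kept; μ1 < μ2 < μ3 is enforced by relabeling.
Delay and dispersion constants are configuration inputs, not estimated.

Measured performance under the default noise model: median plasma
AUC(0–60) error ≈ 5% and median downstream Ki discrepancy ≈ 4% over 50
noisy sessions; on noiseless data the full chain returns the generating
Ki within 1% (median 0.3%).

## Patlak, SUV, MRGlu

Patlak x and y are built frame-consistently: y = (frame-averaged tumor
TAC)/(frame-averaged C_p), x = (frame-averaged running integral of
C_p)/(frame-averaged C_p), all from the fitted analytic input — no
trapezoid quadrature anywhere. Frames with mid-time in [t* = 15, 60] min
enter an unweighted OLS line (the four late points have similar
precision); slope = Ki, intercept = Int. SUV uses the mean of the last
900-s frame (≈ 45–60 min) over injected dose per body weight; MRGlu =
Ki·[Glc]/LC with [Glc] the mean of the start- and end-of-scan glucose
readings and LC = 1.4 (U87) / 1.0 (MDA).

## Partial-volume model

The tumor is a uniform unit-intensity sphere of the caliper-derived
volume on a uniform background at fraction β = 0.10, blurred by an
isotropic Gaussian PSF. RC is the mean blurred intensity inside the true
sphere boundary, computed by radial quadrature of the closed-form
erf/exp profile (validated against a 3-D grid convolution to 4 decimals).
RC is strictly increasing in diameter, → β as d → 0 and → 1 as d → ∞;
the large-sphere approach to 1 is slow, with boundary-shell loss
3σ/(R√(2π)) (≈ 2% at d = 50·FWHM). Beyond R > 50σ the analytic
asymptotic branch takes over (continuous to 5 decimals at the switch).
The ROI is the true sphere support, not an isocontour — an isocontour
would need a threshold that is not part of the model. Default FWHM is
1.75 mm (typical for the scanner class used in such studies), exposed in
config and calibratable by root-finding (`calibrate_fwhm`).

A consequence worth knowing: calibrating the FWHM so that a 1 mm sphere
has RC = 0.34 at β = 0.10 forces FWHM ≈ 0.88 mm, and the same model then
gives RC ≈ 0.96 for a 20 mm sphere. A Gaussian-blur sphere model cannot
simultaneously produce RC = 0.34 at d = 1 mm and RC = 0.93 at d = 20 mm;
any published pair of that shape implies heavier-than-Gaussian resolution
loss at large diameters.

## Glucose/size regression and model selection

Four mean models (constant; linear in diameter; inverse-glucose
saturation a/(b+[Glc]); their combination) are fitted to SUV/RC and
Ki/RC. Everything uses maximum likelihood, never REML, so log-likelihoods
are comparable across different fixed-effect structures and usable in
LRTs; k counts mean parameters plus all variance parameters.

* Fixed fits: models linear in the transformed regressors (1, d, 1/Glc,
  d/Glc) are solved by linear least squares; a free b is profiled (the
  linear part solved exactly at each b) over a grid plus bounded
  refinement. b is constrained ≥ 0: it is a half-saturation glucose
  concentration, and unconstrained profiling lets b approach −min(Glc)
  where the 1/(b+Glc) regressor explodes, which empirically made the
  b Wald test anti-conservative (13.5% size at nominal 5%).
* Mixed fits: per-mouse Gaussian deviations on any subset of the model's
  parameters, independent across parameters (diagonal covariance). The
  marginal likelihood y_i ~ N(f(x_i;θ), Z_i D Z_i' + σ²I) with Z_i the
  Jacobian in the random parameters at zero deviation is exact when the
  random parameters enter linearly (a and c always; also a, c given b in
  models 3–4) and is the first-order (Beal–Sheiner) linearization when b
  itself is random. Optimization is L-BFGS-B over (θ, log SDs) from
  three starts including a near-degenerate one; if the optimizer stalls
  above the fixed fit, the τ → 0 solution is substituted, so the mixed
  log-likelihood never falls below the fixed one. Fits with τ below
  1e−5 of the response scale are flagged singular. The linear cases are
  cross-checked in the tests against statsmodels MixedLM (ML, diagonal
  covariance) to ~1e−4 in log-likelihood.
* Selection procedure, in order: (i) fixed fits of models 1–4; (ii) if b
  is not significant (two-sided Wald on the fixed fit, α = 0.05), models
  3–4 are rebuilt with b = 0 before anything else — testing b on the
  fixed fit is the simplest order consistent with rebuilding both the
  fixed and mixed variants; (iii) all non-empty random-effect subsets are
  fitted (skipped with < 2 mice); (iv) a mixed variant replaces the fixed
  fit only if the LRT against it is significant, with df = number of
  added variance parameters (the chi-square reference is conservative at
  the variance boundary; no correction is applied); multiple significant
  variants are resolved by LRT when nested, AICc otherwise; (v) the four
  representatives are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with
  ties closer than 0.5 broken toward fewer parameters.

## Synthetic cohorts

The generator emulates the study design end to end; defaults:

| quantity | default | basis |
|---|---|---|
| cohort | 8 U87 + 11 MDA mice | study design |
| dose | N(18.28, 1.19) MBq, > 0 | reported protocol |
| body weight | N(25, 2.5) g, > 15 | typical adult SCID mouse |
| glucose start/end (U87) | N(7.79, 2.52) / N(8.45, 2.37) mmol/L | reported cohort means |
| glucose start/end (MDA) | N(6.88, 2.52) / N(8.19, 2.25) mmol/L | reported cohort means |
| glucose floor / correlation | 2 mmol/L; r = 0.5 | physiology; unreported, exposed as a knob |
| growth | start N(2.5, 0.33) mm; rate N(2.2, 0.5) mm/week; stop past 10 mm | scan-at-2.5-mm design; ≈3–4 scans per mouse |
| necrosis | eligible at d ≥ 5 (MDA) / d > 8 mm (U87); weekly onset 0.7 / 0.5, persistent | reported thresholds and case counts |
| bolus shape (per 18.28 MBq) | A = (6e5, 8e5, 2.5e6) Bq/mL; μ = (0.018, 0.5, 3.5, 7.0) /min | bolus peak ≈ 18 s, 60-min tail ≈ 12% of peak; physiologic choice frozen before testing |
| tumor kinetics | k2 = 0.25, k3 = 0.06, k4 = 0; VB 0.08 (U87) / 0.04 (MDA); K1 solves the target Ki | FDG literature ranges; VB split reproduces the higher U87 intercept |
| Ki truth models | U87: a/[Glc], a = 0.27, residual SD 0.01; MDA: a = 0.04, between-mouse SD 0.014, residual SD 0.003 | reported best-fit relationships |
| TAC noise | SD = 30·√(value/duration_min) Bq/mL | unreported; chosen so early 0.5-s frames carry ~30% noise and late 900-s frames ~1–2%, typical of mouse dynamic reconstructions |
| LV degradation | delay 2 s, dispersion τ 5 s, chamber recovery 0.85 | standard image-derived-input corrections |

All randomness flows from one seed through `numpy` `SeedSequence`
spawning; each session stores its sub-seed, and reruns are byte-identical
(CSVs are written at 17 significant digits and parsed with round-trip
precision).

What the generator does **not** emulate: voxel-level imaging (no
scatter/randoms/attenuation physics, no reconstruction correlations
between frames), cold-core TAC shapes after necrosis (necrosis is a
binary exclusion flag; the TAC itself stays "hot"), insulin effects, and
inter-scanner differences. Passing recovery tests therefore show that the
estimators are correct and well-calibrated under the stated noise model,
not that they are robust to reconstruction artifacts absent from it.

## Numerical choices and degenerate inputs

* Patlak requires ≥ 2 points with positive plasma values and nonzero
  x-variance; t* = 60 min raises (no frames remain).
* AICc requires n > k + 1; models that cannot satisfy it on a small
  cohort are recorded as per-cell errors and selection proceeds on the
  rest (an entire tumor type failing is reported, not fatal to the run).
* The LRT rejects a negative deviance beyond a relative 1e−6 tolerance;
  in the selection tournament a larger model that converged worse than a
  nested smaller one is simply not adopted.
* `calibrate_fwhm` brackets in [0.1, 10] mm and refuses targets at or
  below the background fraction.
* Noisy TAC values may be negative and are kept (real reconstructions
  produce them); the input-function fit clips only its variance model,
  never the data.

## Known limitations

* The Patlak slope has a small negative transient bias (< 0.5% under the
  default bolus; up to ~2.5% for inputs with slowly-decaying second
  components), inherent to the 15-min linearity cut.
* The MAP fit's prior shrinks parameters toward typical values by design;
  with strongly atypical physiology the plasma-curve tail can be biased
  by a few percent. Priors and weights are exposed for such cases.
* The first-order NLME approximation for a random half-saturation b is
  not validated against an exact-likelihood reference (none is available
  in-package); random effects on b rarely survive selection in practice.
* Single-session Ki/RC errors have a heavy-ish tail (~10–19% for a few
  percent of sessions at default noise) driven by input-fit outliers;
  cohort-level regressions average over this.
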