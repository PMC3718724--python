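"""Plasma input-function reconstruction from image-derived blood data.

The arterial plasma FDG curve drives every kinetic model downstream, but
longitudinal mouse studies cannot afford serial arterial sampling.  The
approach implemented here reconstructs the plasma curve from

* the early (t < 1 min) left-ventricle time-activity curve, corrected for
  delay, dispersion and chamber partial-volume/spillover,
* one whole-blood sample drawn at the end of the scan (70-80 min), and
* the muscle and liver time-activity curves, each modeled with a full
  two-tissue (4-rate-constant) compartment model driven by the candidate
  plasma curve.

The plasma curve is parameterized as a sum of four exponentials whose
amplitudes sum to zero, so the curve is exactly zero at injection time:

    C_p(t) = A1 e^(-mu1 t) + A2 e^(-mu2 t) + A3 e^(-mu3 t)
             - (A1 + A2 + A3) e^(-mu4 t)

Whole-blood and plasma concentrations are interconverted with the
time-dependent equilibrium ratio R_PB(t) = 0.386 exp(-0.191 t) + 1.165
(t in minutes), which tends to 1.165 at late times as red-cell uptake
equilibrates.

All parameters (plasma curve plus both tissue models) are estimated in a
single weighted least-squares problem with a Gaussian penalty on the
log-parameters around prior means — a maximum a posteriori (MAP) fit that
stabilizes the many weakly identified tissue rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .schedule import FrameSchedule

__all__ = [
    "PlasmaRatioModel",
    "DEFAULT_PLASMA_RATIO",
    "plasma_ratio",
    "whole_blood_to_plasma",
    "plasma_to_whole_blood",
    "InputFunctionParams",
    "eval_input",
    "integral_input",
    "preprocess_early_lv",
    "EarlyBloodCurve",
    "InputFitResult",
    "fit_input_function",
    "default_priors",
]


# ---------------------------------------------------------------------------
# plasma / whole-blood equilibrium ratio


@dataclass(frozen=True)
class PlasmaRatioModel:
    """Time-dependent plasma-to-whole-blood FDG concentration ratio.

    ratio(t) = amplitude * exp(-rate * t) + asymptote, t in minutes.
    Strictly decreasing from amplitude+asymptote at t=0 to the asymptote.
    """

    amplitude: float = 0.386
    rate: float = 0.191  # 1/min
    asymptote: float = 1.165

    def __call__(self, t_min):
        t = np.asarray(t_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        return self.amplitude * np.exp(-self.rate * t) + self.asymptote


DEFAULT_PLASMA_RATIO = PlasmaRatioModel()


def plasma_ratio(t_min, model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO):
    """Plasma-to-whole-blood ratio R_PB at time ``t_min`` (minutes)."""
    return model(t_min)


def whole_blood_to_plasma(sample_time_min, whole_blood_conc,
                          model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO):
    """Convert a whole-blood concentration (Bq/mL) to plasma."""
    conc = np.asarray(whole_blood_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    return conc * model(sample_time_min)


def plasma_to_whole_blood(sample_time_min, plasma_conc,
                          model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO):
    """Inverse of :func:`whole_blood_to_plasma`."""
    conc = np.asarray(plasma_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    return conc / model(sample_time_min)


# ---------------------------------------------------------------------------
# 4-exponential input function


@dataclass(frozen=True)
class InputFunctionParams:
    """Sum-of-four-exponentials plasma curve with zero value at t=0.

    Amplitudes in Bq/mL, rates in 1/min.  The fourth amplitude is implied,
    A4 = -(A1+A2+A3), which forces C_p(0) = 0.  With mu4 the largest rate
    and A1..A3 >= 0 the curve is non-negative for t > 0.
    """

    A1: float
    A2: float
    A3: float
    mu1: float
    mu2: float
    mu3: float
    mu4: float

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "mu3", "mu4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3,
                         -(self.A1 + self.A2 + self.A3)])

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2, self.mu3, self.mu4])

    def sorted_rates(self) -> "InputFunctionParams":
        """Relabel so that mu1 < mu2 < mu3 (mu4 untouched: its amplitude
        is tied to the others and not exchangeable)."""
        order = np.argsort([self.mu1, self.mu2, self.mu3])
        amps = [self.A1, self.A2, self.A3]
        mus = [self.mu1, self.mu2, self.mu3]
        return InputFunctionParams(
            A1=amps[order[0]], A2=amps[order[1]], A3=amps[order[2]],
            mu1=mus[order[0]], mu2=mus[order[1]], mu3=mus[order[2]],
            mu4=self.mu4,
        )

    def scaled(self, factor: float) -> "InputFunctionParams":
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor,
                       A3=self.A3 * factor)

    def __call__(self, t_min):
        return eval_input(self, t_min)


def eval_input(params: InputFunctionParams, t_min):
    """Evaluate the plasma curve C_p(t) (Bq/mL) at ``t_min`` minutes."""
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    out = np.zeros_like(t)
    for a, mu in zip(params.amplitudes, params.rates):
        out += a * np.exp(-mu * t)
    return out if np.ndim(t_min) else float(out[0])


def integral_input(params: InputFunctionParams, t_min):
    """Exact analytic integral of C_p from 0 to t (Bq*min/mL)."""
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    out = np.zeros_like(t)
    for a, mu in zip(params.amplitudes, params.rates):
        out += (a / mu) * (1.0 - np.exp(-mu * t))
    return out if np.ndim(t_min) else float(out[0])


# ---------------------------------------------------------------------------
# early left-ventricle preprocessing


@dataclass(frozen=True)
class EarlyBloodCurve:
    """Frame-averaged whole-blood estimates for the first minute.

    times_min are frame mid-times on the delay-corrected time base;
    window_* give the frame boundaries so the fit can compare against
    frame-averaged model predictions.
    """

    times_min: np.ndarray
    values: np.ndarray          # Bq/mL, whole blood
    window_starts_min: np.ndarray
    window_ends_min: np.ndarray

    def __iter__(self):  # unpacks like the (times, values) pair
        return iter((self.times_min, self.values))


def preprocess_early_lv(lv_tac_values, schedule: FrameSchedule, *,
                        delay_s: float = 2.0, dispersion_tau_s: float = 5.0,
                        blood_rc: float = 1.0) -> EarlyBloodCurve:
    """Recover the early whole-blood curve from the left-ventricle TAC.

    The LV chamber signal lags the true blood curve (catheter/circulation
    delay), is smeared by dispersion, and is attenuated by partial volume
    and spillover.  This applies the standard corrections:

    * time base shifted by ``-delay_s``;
    * monoexponential dispersion kernel (time constant ``dispersion_tau_s``)
      deconvolved on frame averages — the dispersion ODE y' = (b - y)/tau
      gives the exact per-frame identity b_avg = m_avg + tau * (y(end) -
      y(start)) / duration, with the frame-edge values interpolated from
      the measured frame means;
    * division by ``blood_rc``, the recovery of the chamber ROI.

    Red-cell partition is NOT handled here: the returned curve is whole
    blood, to be converted to plasma with R_PB(t).

    Only frames fully inside the first minute are returned.
    """
    if delay_s < 0 or dispersion_tau_s < 0 or blood_rc <= 0:
        raise ValueError("delay, tau must be >= 0 and blood_rc > 0")
    if delay_s >= 60.0:
        raise ValueError("delay exceeds the first-minute span")
    values = np.asarray(lv_tac_values, dtype=float)
    if values.shape[0] != schedule.n_frames:
        raise ValueError("TAC length does not match schedule")

    early = schedule.frames_within(60.0)
    n_early = early.n_frames
    starts = early.starts_s - delay_s
    ends = early.ends_s - delay_s
    mids = early.mid_times_s - delay_s
    v = values[:n_early] / blood_rc
    if dispersion_tau_s > 0:
        from scipy.interpolate import PchipInterpolator
        edge = PchipInterpolator(mids, v, extrapolate=True)
        v = v + dispersion_tau_s * (edge(ends) - edge(starts)) \
            / early.durations_s
    keep = mids > 0
    return EarlyBloodCurve(mids[keep] / 60.0, v[keep],
                           np.clip(starts[keep], 0.0, None) / 60.0,
                           ends[keep] / 60.0)


# ---------------------------------------------------------------------------
# MAP fit


#: Prior means for the shared fit: plasma-curve shape plus muscle and liver
#: two-tissue models.  Amplitudes are per-MBq-of-injected-dose scales times
#: a nominal dose; the fit is insensitive to the prior amplitude scale
#: because amplitudes are strongly data-determined.  Rates in 1/min.
_PRIOR_MEANS = {
    "A1": 6.0e5, "A2": 8.0e5, "A3": 2.5e6,
    "mu1": 0.018, "mu2": 0.5, "mu3": 3.5, "mu4": 7.0,
    "musc_K1": 0.08, "musc_k2": 0.35, "musc_k3": 0.04, "musc_k4": 0.004,
    "musc_VB": 0.03,
    "liv_K1": 0.6, "liv_k2": 0.9, "liv_k3": 0.02, "liv_k4": 0.02,
    "liv_VB": 0.2,
}

_PARAM_NAMES = list(_PRIOR_MEANS)


def default_priors(cv: float = 0.5) -> dict[str, tuple[float, float]]:
    """Log-normal priors: name -> (median, sd of log).

    The default 50% coefficient of variation translates to an sd of
    sqrt(log(1+cv^2)) on the log scale.
    """
    sd_log = float(np.sqrt(np.log1p(cv ** 2)))
    return {k: (v, sd_log) for k, v in _PRIOR_MEANS.items()}


@dataclass
class InputFitResult:
    """Outcome of the simultaneous MAP input-function fit."""

    input: InputFunctionParams
    muscle_kin: "TissueKinetics"  # noqa: F821 - forward ref, see compartment
    liver_kin: "TissueKinetics"  # noqa: F821
    objective: float
    converged: bool
    n_starts: int
    residual_sums: dict[str, float] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)


def _pack(values: dict[str, float]) -> np.ndarray:
    return np.log([values[k] for k in _PARAM_NAMES])


def _unpack(x: np.ndarray) -> dict[str, float]:
    return {k: float(v) for k, v in zip(_PARAM_NAMES, np.exp(x))}


def fit_input_function(
    early_blood: tuple[np.ndarray, np.ndarray],
    late_sample: tuple[float, float],
    muscle_tac: np.ndarray,
    liver_tac: np.ndarray,
    schedule: FrameSchedule,
    *,
    priors: dict[str, tuple[float, float]] | None = None,
    prior_weight: float = 1.0,
    noise_scale: float = 30.0,
    early_tau_s: float = 5.0,
    early_sys_cv: float = 0.02,
    late_sample_cv: float = 0.02,
    late_sample_weight: float = 1.0,
    n_starts: int = 5,
    ratio_model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO,
    seed: int = 0,
) -> InputFitResult:
    """Simultaneous MAP estimation of the plasma curve and tissue models.

    Parameters
    ----------
    early_blood
        ``(times_min, whole_blood_Bq_per_mL)`` from
        :func:`preprocess_early_lv`; converted to plasma internally.
    late_sample
        ``(time_min, whole_blood_Bq_per_mL)`` of the end-of-scan draw.
    muscle_tac, liver_tac
        Frame-averaged TACs (Bq/mL) on ``schedule``.
    priors
        name -> (median, sd_log) for each of the 17 parameters; defaults
        to :func:`default_priors`.
    prior_weight
        Multiplier on the Gaussian log-parameter penalty; 0 disables it.
    noise_scale
        Assumed measurement-noise scale of the count-statistics model
        (frame SD = noise_scale * sqrt(value / duration_min)); sets the
        inverse-variance weights of all TAC residuals.
    late_sample_cv
        Assumed relative SD of the gamma-counted blood sample; its weight
        is 1/(cv * value), optionally scaled by ``late_sample_weight``.

    Notes
    -----
    All residuals are standardized by their assumed measurement SDs
    (inverse-variance weighting), so the objective is a proper MAP
    posterior: data chi-square plus the Gaussian log-parameter penalty.
    All parameters are fitted on the log scale, which enforces
    positivity.  The optimizer is restarted from ``n_starts`` perturbed
    initializations and the best objective is kept.  mu1 < mu2 < mu3 is
    enforced by relabeling after the fit.
    """
    from .compartment import TissueKinetics, tissue_frame_averages

    t_early, wb_early = (np.asarray(a, dtype=float) for a in early_blood)
    if np.all(wb_early < 0):
        raise ValueError("early blood curve is entirely negative")
    windows = None
    if isinstance(early_blood, EarlyBloodCurve):
        windows = (early_blood.window_starts_min,
                   early_blood.window_ends_min)
    t_late, wb_late = late_sample
    if not (50.0 <= t_late <= 100.0):
        raise ValueError("late sample expected near end of scan (min)")
    plasma_late = float(wb_late) * float(ratio_model(t_late))

    muscle_tac = np.asarray(muscle_tac, dtype=float)
    liver_tac = np.asarray(liver_tac, dtype=float)
    priors = dict(priors or default_priors())

    dur_min = schedule.durations_s / 60.0

    def _sigma(values, durations):
        v = np.clip(np.abs(values), 0.05 * np.max(np.abs(values)), None)
        return noise_scale * np.sqrt(v / durations)

    # early points carry their local frame spacing as effective duration;
    # the dispersion deconvolution (b = m + tau*dm/dt) amplifies their
    # noise by roughly sqrt(1 + 2 (tau/spacing)^2)
    if len(t_early) > 1:
        spac = np.abs(np.gradient(t_early))
    else:
        spac = np.array([1.0 / 60.0])
    # noise inflation from the deconvolution, plus a systematic floor
    # (frame-averaging and interpolation artifacts scale with the peak)
    inflation = np.sqrt(1.0 + 2.0 * (early_tau_s / (spac * 60.0)) ** 2)
    sys_sd = early_sys_cv * np.max(np.abs(wb_early))
    w_early = 1.0 / np.hypot(_sigma(wb_early, spac) * inflation, sys_sd)

    if windows is not None:
        gx, gw = np.polynomial.legendre.leggauss(8)
        gx, gw = 0.5 * (gx + 1.0), 0.5 * gw
        tt_early = (windows[0][:, None]
                    + (windows[1] - windows[0])[:, None] * gx[None, :])
        r_early_t = ratio_model(tt_early.ravel()).reshape(tt_early.shape)

        def predict_early_wb(ifp: InputFunctionParams) -> np.ndarray:
            vals = eval_input(ifp, tt_early.ravel()).reshape(tt_early.shape)
            return ((vals / r_early_t) * gw[None, :]).sum(axis=1)
    else:
        def predict_early_wb(ifp: InputFunctionParams) -> np.ndarray:
            return eval_input(ifp, t_early) / np.asarray(
                ratio_model(t_early))
    w_tac_m = 1.0 / _sigma(muscle_tac, dur_min)
    w_tac_l = 1.0 / _sigma(liver_tac, dur_min)
    w_late = late_sample_weight / max(late_sample_cv * plasma_late, 1e-12)

    prior_means = np.log([priors[k][0] for k in _PARAM_NAMES])
    prior_sds = np.array([priors[k][1] for k in _PARAM_NAMES])

    trace: list[float] = []

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x)
        ifp = InputFunctionParams(p["A1"], p["A2"], p["A3"],
                                  p["mu1"], p["mu2"], p["mu3"], p["mu4"])
        musc = TissueKinetics(p["musc_K1"], p["musc_k2"], p["musc_k3"],
                              p["musc_k4"], min(p["musc_VB"], 1.0))
        liv = TissueKinetics(p["liv_K1"], p["liv_k2"], p["liv_k3"],
                             p["liv_k4"], min(p["liv_VB"], 1.0))
        r_blood = (predict_early_wb(ifp) - wb_early) * w_early
        r_late = np.array([(eval_input(ifp, t_late) - plasma_late)
                           * w_late])
        pred_m = tissue_frame_averages(ifp, musc, schedule, ratio_model)
        pred_l = tissue_frame_averages(ifp, liv, schedule, ratio_model)
        r_musc = (pred_m - muscle_tac) * w_tac_m
        r_liv = (pred_l - liver_tac) * w_tac_l
        r_prior = np.sqrt(prior_weight) * (x - prior_means) / prior_sds
        return np.concatenate([r_blood, r_late, r_musc, r_liv, r_prior])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x0 = prior_means.copy()
        # data-informed amplitude initialization: scale prior amplitudes to
        # the observed early peak
        i_pk = int(np.argmax(wb_early))
        peak = max(wb_early[i_pk] * float(ratio_model(t_early[i_pk])), 1e-9)
        amp0 = _PRIOR_MEANS["A1"] + _PRIOR_MEANS["A2"] + _PRIOR_MEANS["A3"]
        x0[:3] += np.log(peak / (0.8 * amp0) + 1e-300)
        if start > 0:
            x0 = x0 + rng.normal(0.0, 0.3, size=x0.size)
        try:
            sol = least_squares(residuals, x0, method="trf",
                                xtol=1e-10, ftol=1e-10, max_nfev=2500)
        except (ValueError, FloatingPointError):
            continue
        obj = float(np.sum(sol.fun ** 2))
        if best is None or obj < best[0] - 1e-12:
            best = (obj, sol)
            trace.append(obj)
    if best is None:
        raise RuntimeError("input-function fit failed from every start")
    obj, sol = best

    p = _unpack(sol.x)
    ifp = InputFunctionParams(p["A1"], p["A2"], p["A3"],
                              p["mu1"], p["mu2"], p["mu3"], p["mu4"])
    ifp = ifp.sorted_rates()
    musc = TissueKinetics(p["musc_K1"], p["musc_k2"], p["musc_k3"],
                          p["musc_k4"], min(p["musc_VB"], 1.0))
    liv = TissueKinetics(p["liv_K1"], p["liv_k2"], p["liv_k3"],
                         p["liv_k4"], min(p["liv_VB"], 1.0))

    r = residuals(sol.x)
    n_e, n_f = len(t_early), schedule.n_frames
    sums = {
        "early_blood": float(np.sum(r[:n_e] ** 2)),
        "late_sample": float(r[n_e] ** 2),
        "muscle": float(np.sum(r[n_e + 1:n_e + 1 + n_f] ** 2)),
        "liver": float(np.sum(r[n_e + 1 + n_f:n_e + 1 + 2 * n_f] ** 2)),
        "prior": float(np.sum(r[n_e + 1 + 2 * n_f:] ** 2)),
    }
    return InputFitResult(
        input=ifp, muscle_kin=musc, liver_kin=liv, objective=obj,
        converged=bool(sol.success), n_starts=max(1, n_starts),
        residual_sums=sums, objective_trace=trace,
    )
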