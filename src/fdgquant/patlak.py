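"""SUV, Patlak graphical analysis, and metabolic rate of glucose.

For an irreversibly trapped tracer the Patlak transform

    C_T(t)/C_p(t) = Ki * [int_0^t C_p(tau) dtau / C_p(t)] + Int

becomes linear once the free compartment has equilibrated (here after
t* = 15 min); the slope is the net influx constant Ki = K1*k3/(k2+k3) and
the intercept Int reflects the vascular fraction plus the reversible
compartment's distribution volume.

The transform is evaluated frame-consistently: y is the frame-averaged
tissue concentration over the frame-averaged plasma curve, and x is the
frame-averaged running plasma integral over the frame-averaged plasma
curve, all from the analytic input-function representation, so no
quadrature error enters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartment import ExpMix
from .input_function import InputFunctionParams
from .schedule import FrameSchedule

__all__ = ["PatlakResult", "MetabolicResult", "compute_suv", "ki_micro",
           "patlak_points", "patlak_fit", "patlak_analysis", "mrglu",
           "LUMPED_CONSTANTS", "last_frame_value"]

#: Lumped constant converting FDG flux to glucose flux, per tumor line.
LUMPED_CONSTANTS = {"U87": 1.4, "MDA": 1.0}


@dataclass(frozen=True)
class PatlakResult:
    """Slope/intercept of the Patlak line over [t_star, 60] min."""

    Ki: float          # mL/min/mL
    Int: float         # unitless
    r_squared: float
    n_points: int
    t_star: float = 15.0


@dataclass(frozen=True)
class MetabolicResult:
    """Session-level uptake metrics."""

    SUV: float
    Ki: float
    MRGlu: float       # umol/min/mL
    LC: float
    glucose_mean: float  # mmol/L


def compute_suv(roi_conc_mbq_ml: float, injected_dose_mbq: float,
                weight_g: float) -> float:
    """Standardized uptake value: concentration / (dose / body weight)."""
    if injected_dose_mbq <= 0 or weight_g <= 0:
        raise ValueError("dose and weight must be positive")
    return roi_conc_mbq_ml / (injected_dose_mbq / weight_g)


def last_frame_value(tac_values, schedule: FrameSchedule) -> float:
    """Mean concentration of the last 15-min (900 s) frame.

    The default protocol ends ...3x900 s, 1x51 s; the SUV convention uses
    the last 900-s frame (centered near 52 min), not the trailing stub.
    """
    values = np.asarray(tac_values, dtype=float)
    durs = schedule.durations_s
    idx = np.nonzero(durs >= 900.0)[0]
    i = int(idx[-1]) if idx.size else int(np.argmax(durs))
    return float(values[i])


def ki_micro(K1: float, k2: float, k3: float) -> float:
    """Net influx constant K1*k3/(k2+k3) from micro-parameters."""
    if k2 + k3 <= 0:
        raise ValueError("k2 + k3 must be positive")
    return K1 * k3 / (k2 + k3)


def _input_frame_terms(params: InputFunctionParams,
                       schedule: FrameSchedule):
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    amps, rates = params.amplitudes, params.rates
    cp_mix = ExpMix(amps, rates, np.zeros(4, dtype=int))
    # running integral of Cp is itself constant + exponentials
    int_mix = ExpMix(np.concatenate([amps / rates, -amps / rates]),
                     np.concatenate([np.zeros(4), rates]),
                     np.zeros(8, dtype=int))
    return cp_mix.frame_averages(starts, ends), \
        int_mix.frame_averages(starts, ends)


def patlak_points(tumor_tac, input_params: InputFunctionParams,
                  schedule: FrameSchedule, t_star: float = 15.0):
    """Patlak (x, y) pairs for frames with mid-time in [t_star, 60] min."""
    values = np.asarray(tumor_tac, dtype=float)
    if values.shape[0] != schedule.n_frames:
        raise ValueError("TAC length does not match schedule")
    mid = schedule.mid_times_min
    mask = (mid >= t_star) & (mid <= 60.0)
    if not np.any(mask):
        raise ValueError(f"no frames with mid-time in [{t_star}, 60] min")
    cp, icp = _input_frame_terms(input_params, schedule)
    if np.any(cp[mask] <= 0):
        raise ValueError("plasma curve must be positive over used frames")
    x = icp[mask] / cp[mask]
    y = values[mask] / cp[mask]
    return x, y


def patlak_fit(x, y, t_star: float = 15.0) -> PatlakResult:
    """Ordinary least-squares line through the Patlak points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 Patlak points")
    if np.ptp(x) == 0:
        raise ValueError("zero x-variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PatlakResult(Ki=float(slope), Int=float(intercept),
                        r_squared=r2, n_points=int(x.size), t_star=t_star)


def patlak_analysis(tumor_tac, input_params: InputFunctionParams,
                    schedule: FrameSchedule,
                    t_star: float = 15.0) -> PatlakResult:
    """Transform and fit in one call."""
    x, y = patlak_points(tumor_tac, input_params, schedule, t_star)
    return patlak_fit(x, y, t_star)


def mrglu(Ki: float, glucose_mean_mmol_l: float, LC: float) -> float:
    """Metabolic rate of glucose, Ki * [Glc] / LC (umol/min/mL)."""
    if LC <= 0:
        raise ValueError("lumped constant must be positive")
    return Ki * glucose_mean_mmol_l / LC
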