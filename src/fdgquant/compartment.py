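"""Analytic two-tissue compartment model driven by a multi-exponential input.

The standard irreversible/reversible FDG model has a free compartment C1
(transport in K1, out k2; phosphorylation k3) and a trapped compartment C2
(dephosphorylation k4).  The measured signal adds a vascular term:

    C_T(t) = C1 + C2 + VB * C_B(t),   C_B = C_p / R_PB(t)

(the vascular term is additive; with this convention the late-time Patlak
slope of an irreversible tissue is exactly K1*k3/(k2+k3) and the intercept
is k2/(k2+k3) * C1/C_p + VB * C_B/C_p, matching the graphical-analysis
identities used downstream).

Because the plasma input is a sum of exponentials, C1 and C2 are sums of
exponentials too (convolutions of exponentials), so frame averages of the
tissue term are computed in closed form.  Only the small vascular term,
which involves the non-exponential ratio R_PB, is averaged by fixed-order
Gauss-Legendre quadrature per frame.

Eigenvalue/rate collisions (an input rate mu equal to a kinetic eigenvalue
alpha) are handled with the exact confluent limit t*exp(-alpha t) rather
than failing or perturbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .input_function import (DEFAULT_PLASMA_RATIO, InputFunctionParams,
                             PlasmaRatioModel)
from .schedule import FrameSchedule

__all__ = ["TissueKinetics", "tissue_curve", "tissue_frame_averages",
           "ExpMix"]


@dataclass(frozen=True)
class TissueKinetics:
    """Micro-parameters of the two-tissue compartment model.

    K1 in mL/min/mL, k2..k4 in 1/min, VB the blood volume fraction.
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0
    VB: float = 0.05

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.VB <= 1.0:
            raise ValueError("VB must lie in [0, 1]")

    @property
    def ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3); 0 when no exchange occurs."""
        denom = self.k2 + self.k3
        if denom == 0.0:
            if self.k3 > 0:  # unreachable: k3>0 implies denom>0
                raise ValueError("k2 + k3 must be positive when k3 > 0")
            return 0.0
        return self.K1 * self.k3 / denom


class ExpMix:
    """Mixture sum(c_j * t^p_j * exp(-lam_j * t)) with p_j in {0, 1}.

    Closed under the convolutions needed here; provides pointwise
    evaluation, the running integral from 0, and exact frame averages.
    Time in minutes, rates in 1/min.
    """

    __slots__ = ("coef", "rate", "power")

    def __init__(self, coef, rate, power):
        self.coef = np.asarray(coef, dtype=float)
        self.rate = np.asarray(rate, dtype=float)
        self.power = np.asarray(power, dtype=int)

    @classmethod
    def from_input(cls, params: InputFunctionParams) -> "ExpMix":
        return cls(params.amplitudes, params.rates,
                   np.zeros(4, dtype=int))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, lam, p in zip(self.coef, self.rate, self.power):
            term = c * np.exp(-lam * t)
            if p:
                term = term * t
            out += term
        return out

    def cumulative(self, t):
        """Integral from 0 to t, term by term, exact."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, lam, p in zip(self.coef, self.rate, self.power):
            if p == 0:
                if lam == 0.0:
                    out += c * t
                else:
                    out += (c / lam) * (1.0 - np.exp(-lam * t))
            else:
                if lam == 0.0:
                    out += c * t ** 2 / 2.0
                else:
                    out += (c / lam ** 2) * (
                        1.0 - np.exp(-lam * t) * (1.0 + lam * t))
        return out

    def frame_averages(self, starts, ends):
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        ci = self.cumulative(ends) - self.cumulative(starts)
        return ci / (ends - starts)


def _convolve_exp(input_mix: ExpMix, alpha: float,
                  rel_tol: float = 1e-9) -> ExpMix:
    """Convolution of the input mixture with exp(-alpha t).

    For each pure-exponential input term c*exp(-mu t):
        (exp(-alpha .) * exp(-mu .))(t) = (exp(-mu t) - exp(-alpha t))
                                          / (alpha - mu)
    with the confluent limit t*exp(-alpha t) when alpha == mu.
    """
    coefs: list[float] = []
    rates: list[float] = []
    powers: list[int] = []
    scale = max(abs(alpha), float(np.max(np.abs(input_mix.rate))), 1.0)
    for c, mu, p in zip(input_mix.coef, input_mix.rate, input_mix.power):
        if p != 0:  # input terms are pure exponentials here
            raise ValueError("input mixture must have power-0 terms")
        if abs(alpha - mu) <= rel_tol * scale:
            coefs.append(c)
            rates.append(alpha)
            powers.append(1)
        else:
            d = alpha - mu
            coefs.extend([c / d, -c / d])
            rates.extend([mu, alpha])
            powers.extend([0, 0])
    return ExpMix(coefs, rates, powers)


def _tissue_expmix(ifp: InputFunctionParams, kin: TissueKinetics) -> ExpMix:
    """Closed-form C1(t)+C2(t) as an exponential mixture.

    Eigen-rates alpha1 <= alpha2 of the 2x2 kinetic system; alpha1 = 0 for
    the irreversible case k4 = 0, which the formulas handle naturally.
    """
    K1, k2, k3, k4 = kin.K1, kin.k2, kin.k3, kin.k4
    if K1 == 0.0:
        return ExpMix([], [], [])
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    alpha1 = 0.5 * (s - disc)
    alpha2 = 0.5 * (s + disc)

    input_mix = ExpMix.from_input(ifp)
    if disc <= 1e-12 * max(s, 1.0):
        # repeated eigenvalue (only when k3=0, k2=k4); nudge apart —
        # the split is far below any physical precision
        eps = 1e-7 * max(s, 1.0) + 1e-12
        alpha1, alpha2 = alpha1 - eps, alpha2 + eps

    # impulse response h(t) = e1*exp(-alpha1 t) + e2*exp(-alpha2 t)
    # from C1(0)=K1, C2(0)=0 free evolution of the homogeneous system
    d21 = alpha2 - alpha1
    c1 = K1 * (alpha2 - k2 - k3) / d21
    c2 = K1 * (k2 + k3 - alpha1) / d21
    dd = k3 * K1 / d21
    e1 = c1 + dd
    e2 = c2 - dd

    conv1 = _convolve_exp(input_mix, alpha1)
    conv2 = _convolve_exp(input_mix, alpha2)
    return ExpMix(
        np.concatenate([e1 * conv1.coef, e2 * conv2.coef]),
        np.concatenate([conv1.rate, conv2.rate]),
        np.concatenate([conv1.power, conv2.power]),
    )


# Gauss-Legendre nodes/weights on [0, 1] for the vascular-term average
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def tissue_curve(ifp: InputFunctionParams, kin: TissueKinetics, t_min,
                 ratio_model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO):
    """Instantaneous C_T(t) (Bq/mL) at times ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    mix = _tissue_expmix(ifp, kin)
    tissue = mix(t) if mix.coef.size else np.zeros_like(t)
    blood = ifp(t) / ratio_model(t)
    return tissue + kin.VB * blood


def tissue_frame_averages(
        ifp: InputFunctionParams, kin: TissueKinetics,
        schedule: FrameSchedule,
        ratio_model: PlasmaRatioModel = DEFAULT_PLASMA_RATIO) -> np.ndarray:
    """Frame-averaged C_T on ``schedule`` (exact for the tissue term)."""
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    mix = _tissue_expmix(ifp, kin)
    if mix.coef.size:
        tissue = mix.frame_averages(starts, ends)
    else:
        tissue = np.zeros_like(starts)

    if kin.VB > 0.0:
        # quadrature for the C_p/R_PB vascular term
        tt = starts[:, None] + (ends - starts)[:, None] * _GL_X[None, :]
        vals = ifp(tt.ravel()) / ratio_model(tt.ravel())
        blood = (vals.reshape(tt.shape) * _GL_W[None, :]).sum(axis=1)
    else:
        blood = 0.0
    return tissue + kin.VB * blood
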