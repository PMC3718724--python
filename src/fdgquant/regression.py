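"""Regression of PV-corrected uptake on blood glucose and tumor size.

Four candidate mean models relate a response Y (PV-corrected SUV or Ki)
to the session blood glucose [Glc] (mmol/L) and tumor diameter d (mm):

    model 1:  Y = a
    model 2:  Y = a + c*d
    model 3:  Y = a / (b + [Glc])
    model 4:  Y = (a + c*d) / (b + [Glc])

with b the half-saturation glucose concentration of FDG uptake.  Each
model is fitted by standard least squares and, to account for repeated
measures on the same mouse, by a mixed-effects fit (per-mouse Gaussian
deviations on any subset of the model's parameters, independent across
parameters, estimated by maximum likelihood).  Selection follows a fixed
procedure: a non-significant b triggers a rebuild with b = 0; a mixed fit
replaces the fixed fit only when the likelihood-ratio test against the
fixed fit is significant; competing mixed variants are resolved by LRT
when nested and by the small-sample AICc otherwise; finally the four
per-model representatives are ranked by AICc.

The central class is :class:`GlucoseSizeRegression`, a scikit-learn style
estimator (``fit``/``predict``/``get_params``/``set_params`` with fitted
attributes carrying a trailing underscore); the module-level functions
``fit_fixed`` and ``fit_mixed`` are thin wrappers over it.

Implementation notes: mixed fits maximize the marginal likelihood
y_i ~ N(f(x_i; theta), Z_i D Z_i' + sigma^2 I) with D diagonal, where
Z_i is the Jacobian of the mean model in the random parameters evaluated
at zero deviation.  For random effects on a and c the mean model is
linear in the affected parameters, so the marginal likelihood is exact;
a random b enters nonlinearly and the same expression is then the
first-order (Beal-Sheiner) linearization.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MODEL_PARAMS", "GlucoseSizeModelSpec", "model_predict",
    "GlucoseSizeRegression", "FitResult", "fit_fixed", "fit_mixed",
    "lrt", "aicc", "wald_significance", "select_model", "SelectionReport",
    "simple_linear_regression",
]

#: Free mean parameters of each model (before any b-rebuild).
MODEL_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("a",), 2: ("a", "c"), 3: ("a", "b"), 4: ("a", "b", "c"),
}


@dataclass(frozen=True)
class GlucoseSizeModelSpec:
    """Identifies one candidate fit: mean model, b-rebuild, random set."""

    model_id: int
    b_zeroed: bool = False
    random_effects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError("model_id must be 1..4")
        if self.b_zeroed and "b" not in MODEL_PARAMS[self.model_id]:
            raise ValueError("b_zeroed applies to models 3 and 4 only")
        bad = set(self.random_effects) - set(self.param_names)
        if bad:
            raise ValueError(f"random effects {bad} not in model parameters")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = MODEL_PARAMS[self.model_id]
        if self.b_zeroed:
            names = tuple(p for p in names if p != "b")
        return names

    @property
    def has_free_b(self) -> bool:
        return "b" in self.param_names

    @property
    def label(self) -> str:
        s = f"model {self.model_id}"
        if self.b_zeroed:
            s += " (b=0)"
        if self.random_effects:
            s += " random " + ",".join(self.random_effects)
        return s


def model_predict(spec: GlucoseSizeModelSpec | int, params: dict,
                  glucose, diameter):
    """Evaluate the mean model at the given covariates."""
    if isinstance(spec, int):
        spec = GlucoseSizeModelSpec(spec)
    g = np.asarray(glucose, dtype=float)
    d = np.asarray(diameter, dtype=float)
    a = params["a"]
    c = params.get("c", 0.0)
    b = 0.0 if spec.b_zeroed else params.get("b", 0.0)
    if spec.model_id == 1:
        return np.broadcast_to(np.asarray(a, dtype=float), g.shape).copy()
    if spec.model_id == 2:
        return a + c * d
    denom = b + g
    if np.any(denom == 0):
        raise ZeroDivisionError("b + [Glc] must be nonzero")
    if spec.model_id == 3:
        return a / denom
    return (a + c * d) / denom


# ---------------------------------------------------------------------------
# fit result container


@dataclass
class FitResult:
    """One fitted (model, method) cell with its information criteria."""

    spec: GlucoseSizeModelSpec
    method: str                      # "fixed" | "mixed"
    params: dict[str, float]
    se: dict[str, float]
    random_sd: dict[str, float]
    sigma: float                     # ML residual SD
    loglik: float
    k: int                           # mean params + variance params
    n: int
    aicc: float
    rss: float
    converged: bool = True
    singular: bool = False

    def to_dict(self) -> dict:
        out = asdict(self)
        out["spec"] = {"model_id": self.spec.model_id,
                       "b_zeroed": self.spec.b_zeroed,
                       "random_effects": list(self.spec.random_effects)}
        return out


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion -2ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def lrt(loglik_null: float, loglik_alt: float, df: int,
        tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio statistic D = 2(ll_alt - ll_null) and chi2 P."""
    if df < 1:
        raise ValueError("df must be >= 1")
    D = 2.0 * (loglik_alt - loglik_null)
    if D < -tol * max(1.0, abs(loglik_null)):
        raise ValueError("alternative log-likelihood below null")
    D = max(D, 0.0)
    return D, float(stats.chi2.sf(D, df))


def wald_significance(fit: FitResult, param_name: str,
                      alpha: float = 0.05) -> bool:
    """Two-sided normal-reference test of estimate / SE."""
    if param_name not in fit.params:
        raise KeyError(param_name)
    se = fit.se.get(param_name)
    if se is None or not np.isfinite(se) or se <= 0:
        raise ValueError(f"no usable SE for {param_name!r}")
    z = fit.params[param_name] / se
    return 2.0 * stats.norm.sf(abs(z)) < alpha


# ---------------------------------------------------------------------------
# estimator


class GlucoseSizeRegression:
    """Scikit-learn style estimator for the glucose/size uptake models.

    Parameters
    ----------
    model_id : int
        Mean model 1..4 (see module docstring).
    b_zeroed : bool
        Fit models 3/4 with the half-saturation b fixed to 0.
    random_effects : tuple of str
        Parameters carrying per-group Gaussian deviations; empty means a
        standard (fixed-effects only) least-squares fit.
    alpha : float
        Significance level used by :meth:`b_is_significant`.

    After ``fit(X, y, groups=...)`` the instance exposes ``params_``,
    ``se_``, ``random_sd_``, ``sigma_``, ``loglik_``, ``aicc_``, ``rss_``,
    ``result_`` (a :class:`FitResult`).  ``X`` is ``(n, 2)`` with columns
    ``[glucose, diameter]`` or a DataFrame with those columns.
    """

    _MIN_LOG_SD = -12.0

    def __init__(self, model_id: int = 1, b_zeroed: bool = False,
                 random_effects: tuple[str, ...] = (), alpha: float = 0.05):
        self.model_id = model_id
        self.b_zeroed = b_zeroed
        self.random_effects = random_effects
        self.alpha = alpha

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"model_id": self.model_id, "b_zeroed": self.b_zeroed,
                "random_effects": self.random_effects, "alpha": self.alpha}

    def set_params(self, **params) -> "GlucoseSizeRegression":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        return (f"GlucoseSizeRegression(model_id={self.model_id}, "
                f"b_zeroed={self.b_zeroed}, "
                f"random_effects={self.random_effects!r})")

    # -- helpers -----------------------------------------------------------
    @property
    def spec(self) -> GlucoseSizeModelSpec:
        return GlucoseSizeModelSpec(self.model_id, self.b_zeroed,
                                    tuple(self.random_effects))

    @staticmethod
    def _validate_X(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, pd.DataFrame):
            g = X["glucose"].to_numpy(dtype=float)
            d = X["diameter"].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("X must be (n, 2): [glucose, diameter]")
            g, d = X[:, 0], X[:, 1]
        if np.any(~np.isfinite(g)) or np.any(~np.isfinite(d)):
            raise ValueError("non-finite covariates")
        return g, d

    def _design(self, g: np.ndarray, d: np.ndarray,
                b: float) -> np.ndarray:
        """Regressor matrix of the parameters that enter linearly (a, c)."""
        denom = b + g if self.model_id in (3, 4) else np.ones_like(g)
        cols = [1.0 / denom]
        if "c" in self.spec.param_names:
            cols.append(d / denom)
        return np.column_stack(cols)

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, groups=None) -> "GlucoseSizeRegression":
        g, d = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape != g.shape:
            raise ValueError("y length mismatch")
        spec = self.spec
        if spec.model_id in (3, 4) and spec.b_zeroed and np.any(g == 0):
            raise ValueError("glucose must be nonzero when b is zeroed")
        if spec.random_effects:
            if groups is None:
                raise ValueError("mixed fit requires groups")
            groups = np.asarray(groups)
            if len(np.unique(groups)) < 2:
                raise ValueError("mixed fit requires >= 2 groups")
            result = self._fit_mixed(g, d, y, groups)
        else:
            result = self._fit_fixed(g, d, y)
        self.result_ = result
        self.params_ = result.params
        self.se_ = result.se
        self.random_sd_ = result.random_sd
        self.sigma_ = result.sigma
        self.loglik_ = result.loglik
        self.aicc_ = result.aicc
        self.rss_ = result.rss
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted")
        g, d = self._validate_X(X)
        return model_predict(self.spec, self.params_, g, d)

    def b_is_significant(self) -> bool:
        return wald_significance(self.result_, "b", self.alpha)

    # fixed-effects ---------------------------------------------------------
    def _fit_fixed(self, g, d, y) -> FitResult:
        spec = self.spec
        n = y.size
        p = len(spec.param_names)
        if n <= p:
            raise ValueError("need n > number of mean parameters")

        if not spec.has_free_b:
            b_hat = 0.0
            X = self._design(g, d, b_hat)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError("rank-deficient design")
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            b_hat, beta, resid = self._profile_b(g, d, y)
        rss = float(resid @ resid)
        sigma2_ml = max(rss / n, 1e-300)
        loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2_ml) + 1.0)

        params: dict[str, float] = {}
        lin_names = [p_ for p_ in spec.param_names if p_ != "b"]
        for name, val in zip(lin_names, beta):
            params[name] = float(val)
        if spec.has_free_b:
            params["b"] = float(b_hat)

        se = self._fixed_se(g, d, params, rss, n)
        k = p + 1
        return FitResult(
            spec=spec, method="fixed", params=params, se=se, random_sd={},
            sigma=float(math.sqrt(sigma2_ml)), loglik=float(loglik),
            k=k, n=n, aicc=aicc(loglik, k, n), rss=rss,
        )

    def _profile_b(self, g, d, y):
        """Nonlinear LS over b with the linear part solved exactly.

        b is a half-saturation glucose concentration and is constrained
        non-negative; the profile is scanned on a grid up to well beyond
        the physiological range, then refined.
        """

        def inner(b: float):
            X = self._design(g, d, b)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r), beta, r

        b_grid = np.concatenate([[0.0], np.geomspace(0.01, 200, 40)])
        rss_grid = [inner(b)[0] for b in b_grid]
        i = int(np.argmin(rss_grid))
        lo = b_grid[max(i - 1, 0)]
        hi = b_grid[min(i + 1, len(b_grid) - 1)]
        lo = max(lo, 0.0)
        res = optimize.minimize_scalar(lambda b: inner(b)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        b_best = float(res.x) if res.fun <= rss_grid[i] else float(b_grid[i])
        rss, beta, r = inner(b_best)
        return b_best, beta, r

    def _fixed_se(self, g, d, params, rss, n) -> dict[str, float]:
        spec = self.spec
        names = list(spec.param_names)
        J = _mean_jacobian(spec, params, g, d, names)
        dof = max(n - len(names), 1)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            ses = np.full(len(names), np.nan)
        return {nm: float(s) for nm, s in zip(names, ses)}

    # mixed-effects ---------------------------------------------------------
    def _fit_mixed(self, g, d, y, groups) -> FitResult:
        spec = self.spec
        n = y.size
        names = list(spec.param_names)
        q = len(spec.random_effects)
        uniq, gidx = np.unique(groups, return_inverse=True)

        # start from the fixed fit
        fixed = GlucoseSizeRegression(self.model_id, self.b_zeroed).fit(
            np.column_stack([g, d]), y)
        theta0 = np.array([fixed.params_[nm] for nm in names])
        sigma0 = max(fixed.sigma_, 1e-8)
        scale = max(float(np.std(y)), 1e-8)

        blocks = [np.flatnonzero(gidx == j) for j in range(len(uniq))]

        def neg_loglik(psi: np.ndarray) -> float:
            theta = psi[:len(names)]
            log_tau = psi[len(names):len(names) + q]
            log_sig = psi[-1]
            pars = dict(zip(names, theta))
            try:
                mu = model_predict(spec, pars, g, d)
            except ZeroDivisionError:
                return 1e12
            Z = _mean_jacobian(spec, pars, g, d,
                               list(spec.random_effects))
            tau2 = np.exp(2.0 * log_tau)
            sig2 = math.exp(2.0 * log_sig)
            r = y - mu
            nll = 0.0
            for idx in blocks:
                Zi = Z[idx]
                Vi = Zi * tau2 @ Zi.T + sig2 * np.eye(idx.size)
                try:
                    L = np.linalg.cholesky(Vi)
                except np.linalg.LinAlgError:
                    return 1e12
                ri = r[idx]
                z = np.linalg.solve(L, ri)
                nll += 0.5 * (idx.size * math.log(2.0 * math.pi)
                              + 2.0 * np.sum(np.log(np.diag(L)))
                              + float(z @ z))
            return float(nll)

        lb = self._MIN_LOG_SD + math.log(scale)
        ub = math.log(scale) + 5.0
        best = None
        starts = []
        for tau_frac in (0.5, 1.5):
            psi0 = np.concatenate([
                theta0,
                np.full(q, math.log(max(tau_frac * sigma0, 1e-8))),
                [math.log(sigma0)],
            ])
            starts.append(psi0)
        # a near-degenerate start helps the singular (tau ~ 0) pattern
        starts.append(np.concatenate([
            theta0, np.full(q, lb + 0.5), [math.log(sigma0)]]))

        bounds = ([(None, None)] * len(names)
                  + [(lb, ub)] * q + [(lb, ub)])
        for psi0 in starts:
            res = optimize.minimize(neg_loglik, psi0, method="L-BFGS-B",
                                    bounds=bounds)
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        assert best is not None

        # polish: mixed ML must never fall below the fixed fit; if the
        # optimizer stalled above it, the degenerate tau -> 0 solution is
        # at least as good
        degen = np.concatenate([theta0, np.full(q, lb), [math.log(sigma0)]])
        if neg_loglik(degen) < best.fun:
            best_x, best_fun = degen, neg_loglik(degen)
            converged = True
        else:
            best_x, best_fun = best.x, float(best.fun)
            converged = bool(best.success)

        theta = best_x[:len(names)]
        tau = np.exp(best_x[len(names):len(names) + q])
        sigma = math.exp(best_x[-1])
        loglik = -best_fun
        params = dict(zip(names, (float(t) for t in theta)))
        random_sd = dict(zip(spec.random_effects, (float(t) for t in tau)))
        singular = bool(np.any(tau < 1e-5 * scale))

        se = _numeric_wald_se(neg_loglik, best_x, len(names), names)
        pars = dict(zip(names, theta))
        mu = model_predict(spec, pars, g, d)
        rss = float(np.sum((y - mu) ** 2))
        k = len(names) + q + 1
        return FitResult(
            spec=spec, method="mixed", params=params, se=se,
            random_sd=random_sd, sigma=float(sigma), loglik=float(loglik),
            k=k, n=n, aicc=aicc(loglik, k, n), rss=rss,
            converged=converged, singular=singular,
        )


def _mean_jacobian(spec: GlucoseSizeModelSpec, params: dict,
                   g: np.ndarray, d: np.ndarray,
                   wrt: list[str]) -> np.ndarray:
    """Analytic Jacobian of the mean model in the named parameters."""
    a = params.get("a", 0.0)
    c = params.get("c", 0.0)
    b = 0.0 if spec.b_zeroed else params.get("b", 0.0)
    ones = np.ones_like(g)
    if spec.model_id in (1, 2):
        cols = {"a": ones, "c": d}
    else:
        denom = b + g
        num = a + c * d if spec.model_id == 4 else a
        cols = {"a": 1.0 / denom, "c": d / denom,
                "b": -num / denom ** 2}
    return np.column_stack([cols[nm] for nm in wrt]) if wrt else \
        np.empty((g.size, 0))


def _numeric_wald_se(fun, x, n_mean: int, names: list[str],
                     rel_step: float = 1e-4) -> dict[str, float]:
    """SEs of the mean parameters from a numerical Hessian at the optimum."""
    m = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((m, m))
    f0 = fun(x)
    for i in range(m):
        for j in range(i, m):
            xi, xj = h[i], h[j]
            if i == j:
                fp = fun(x + _e(m, i, xi))
                fm = fun(x - _e(m, i, xi))
                H[i, i] = (fp - 2 * f0 + fm) / xi ** 2
            else:
                fpp = fun(x + _e(m, i, xi) + _e(m, j, xj))
                fpm = fun(x + _e(m, i, xi) - _e(m, j, xj))
                fmp = fun(x - _e(m, i, xi) + _e(m, j, xj))
                fmm = fun(x - _e(m, i, xi) - _e(m, j, xj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * xi * xj)
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov)[:n_mean], 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(n_mean, np.nan)
    return {nm: float(s) for nm, s in zip(names, ses)}


def _e(m: int, i: int, step: float) -> np.ndarray:
    v = np.zeros(m)
    v[i] = step
    return v


# ---------------------------------------------------------------------------
# module-level wrappers


def _as_xy(data: pd.DataFrame, response: str):
    X = data[["glucose", "diameter"]].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    groups = data["mouse_id"].to_numpy() if "mouse_id" in data else None
    return X, y, groups


def fit_fixed(spec: GlucoseSizeModelSpec, data: pd.DataFrame,
              response: str = "y") -> FitResult:
    """Standard least-squares fit of one mean model."""
    est = GlucoseSizeRegression(spec.model_id, spec.b_zeroed)
    X, y, _ = _as_xy(data, response)
    return est.fit(X, y).result_


def fit_mixed(spec: GlucoseSizeModelSpec, data: pd.DataFrame,
              random_subset: tuple[str, ...],
              response: str = "y") -> FitResult:
    """ML mixed-effects fit with per-mouse deviations on ``random_subset``."""
    if not random_subset:
        raise ValueError("random_subset must be non-empty")
    est = GlucoseSizeRegression(spec.model_id, spec.b_zeroed,
                                tuple(random_subset))
    X, y, groups = _as_xy(data, response)
    if groups is None:
        raise ValueError("data must carry a mouse_id column")
    return est.fit(X, y, groups=groups).result_


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionReport:
    """Full record of the per-model fits and the final AICc ranking."""

    response: str
    fits: dict[str, FitResult]            # label -> fit (all cells tried)
    representatives: dict[int, FitResult]  # model_id -> chosen method
    lrt_results: dict[int, dict]          # model_id -> {D, P, random_set}
    b_rebuilt: dict[int, bool]            # model 3/4 -> rebuilt with b=0
    ranking: list[int]                    # model ids, best first
    chosen_model: int
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def chosen_fit(self) -> FitResult:
        return self.representatives[self.chosen_model]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
            "representatives": {str(k): v.to_dict()
                                for k, v in self.representatives.items()},
            "lrt": {str(k): v for k, v in self.lrt_results.items()},
            "b_rebuilt": {str(k): v for k, v in self.b_rebuilt.items()},
            "ranking": self.ranking,
            "chosen_model": self.chosen_model,
            "errors": self.errors,
        }

    def table(self) -> pd.DataFrame:
        """Human-readable summary mirroring a model-comparison table."""
        rows = []
        for mid in sorted(self.representatives):
            rep = self.representatives[mid]
            fx = self.fits.get(f"model{mid}_fixed")
            info = self.lrt_results.get(mid, {})
            rows.append({
                "model": mid,
                "loglik_standard": fx.loglik if fx else np.nan,
                "loglik_mixed": info.get("loglik_mixed", np.nan),
                "random_parameters": ",".join(info.get("random_set", ())),
                "D": info.get("D", np.nan),
                "P": info.get("P", np.nan),
                "method": rep.method,
                "AICc": rep.aicc,
                "RSS": rep.rss,
                "chosen": mid == self.chosen_model,
            })
        return pd.DataFrame(rows)


def _is_nested(sub: tuple[str, ...], sup: tuple[str, ...]) -> bool:
    return set(sub) < set(sup)


def select_model(data: pd.DataFrame, response_label: str = "y", *,
                 alpha: float = 0.05, aicc_tie: float = 0.5,
                 allow_random_b: bool = True) -> SelectionReport:
    """Run the full fitting/selection procedure on one response variable.

    Steps: (i) fixed fits of models 1-4; (ii) rebuild models 3/4 with b=0
    when b is not significant in the fixed fit; (iii) mixed fits over all
    non-empty random-effect subsets (skipped with < 2 mice); (iv) per
    model adopt the mixed fit only if its LRT against the fixed fit is
    significant, resolving multiple significant variants by LRT (nested)
    or AICc (non-nested); (v) rank the four representatives by AICc,
    breaking near-ties (< ``aicc_tie``) toward fewer parameters.
    """
    data = data.copy()
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    reps: dict[int, FitResult] = {}
    lrt_results: dict[int, dict] = {}
    b_rebuilt: dict[int, bool] = {}

    groups = data["mouse_id"].to_numpy() if "mouse_id" in data else None
    can_mix = groups is not None and len(np.unique(groups)) >= 2

    for mid in (1, 2, 3, 4):
        spec = GlucoseSizeModelSpec(mid)
        try:
            fx = fit_fixed(spec, data, response_label)
        except (ValueError, np.linalg.LinAlgError) as err:
            errors[f"model{mid}_fixed"] = str(err)
            continue
        # (ii) b-significance rebuild, decided on the fixed fit
        if spec.has_free_b:
            try:
                keep_b = wald_significance(fx, "b", alpha)
            except ValueError:
                keep_b = False
            b_rebuilt[mid] = not keep_b
            if not keep_b:
                spec = GlucoseSizeModelSpec(mid, b_zeroed=True)
                fx = fit_fixed(spec, data, response_label)
        fits[f"model{mid}_fixed"] = fx

        # (iii) all random-effect subsets
        cand: list[FitResult] = []
        if can_mix:
            pool = [p for p in spec.param_names
                    if allow_random_b or p != "b"]
            for r in range(1, len(pool) + 1):
                for sub in itertools.combinations(pool, r):
                    mspec = GlucoseSizeModelSpec(mid, spec.b_zeroed, sub)
                    try:
                        mx = fit_mixed(mspec, data, sub, response_label)
                    except (ValueError, np.linalg.LinAlgError) as err:
                        errors[mspec.label] = str(err)
                        continue
                    fits[mspec.label] = mx
                    cand.append(mx)

        # (iv) adopt mixed only on significant LRT vs fixed
        sig: list[FitResult] = []
        best_info = None
        for mx in cand:
            try:
                D, P = lrt(fx.loglik, mx.loglik,
                           df=len(mx.spec.random_effects))
            except ValueError:
                continue
            info = {"D": D, "P": P,
                    "random_set": mx.spec.random_effects,
                    "loglik_mixed": mx.loglik}
            if best_info is None or P < best_info["P"]:
                best_info = info
            if P < alpha:
                sig.append(mx)
        if sig:
            current = min(
                sig, key=lambda f: (len(f.spec.random_effects), f.aicc))
            for other in sig:
                if other is current:
                    continue
                cur_re = current.spec.random_effects
                oth_re = other.spec.random_effects
                if _is_nested(cur_re, oth_re):
                    try:
                        D, P = lrt(current.loglik, other.loglik,
                                   df=len(oth_re) - len(cur_re))
                    except ValueError:
                        continue  # larger model converged worse; keep
                    if P < alpha:
                        current = other
                elif not _is_nested(oth_re, cur_re):
                    if other.aicc < current.aicc - 1e-12:
                        current = other
            rep = current
            D, P = lrt(fx.loglik, rep.loglik,
                       df=len(rep.spec.random_effects))
            lrt_results[mid] = {"D": D, "P": P,
                                "random_set": rep.spec.random_effects,
                                "loglik_mixed": rep.loglik,
                                "adopted_mixed": True}
        else:
            rep = fx
            if best_info is not None:
                lrt_results[mid] = {**best_info, "adopted_mixed": False}
        reps[mid] = rep

    if not reps:
        raise ValueError("every model fit failed")

    # (v) AICc ranking with parsimony tie-break
    def sort_key(mid: int):
        return (reps[mid].aicc, reps[mid].k, mid)

    ranking = sorted(reps, key=sort_key)
    chosen = ranking[0]
    for mid in ranking[1:]:
        if (abs(reps[mid].aicc - reps[chosen].aicc) < aicc_tie
                and reps[mid].k < reps[chosen].k):
            chosen = mid
    ranking = sorted(reps, key=lambda m: (m != chosen, *sort_key(m)))

    return SelectionReport(
        response=response_label, fits=fits, representatives=reps,
        lrt_results=lrt_results, b_rebuilt=b_rebuilt,
        ranking=ranking, chosen_model=chosen, errors=errors,
    )


def simple_linear_regression(y, x) -> tuple[float, float, float, float]:
    """OLS line with t-test on the slope: (slope, intercept, R^2, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero x-variance")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))
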