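"""End-to-end orchestration: simulate → fit-input → quantify → PV-correct
→ model selection, with the cohort-level exclusion rules.

Sessions showing a necrotic core are excluded before any regression (the
uptake becomes heterogeneous and the sphere PV model no longer applies),
as are sessions with tumors at or below the 2.5 mm detectability floor.
Corrected uptake metrics are tumor-type specific: for MDA only the
partial-volume correction applies (SUV/RC, Ki/RC); for U87, whose uptake
varies inversely with blood glucose, the metrics are additionally scaled
by the session glucose ((SUV x [Glc])/RC, (Ki x [Glc])/RC).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .input_function import (InputFunctionParams, fit_input_function,
                             preprocess_early_lv)
from .patlak import (LUMPED_CONSTANTS, compute_suv, last_frame_value,
                     mrglu, patlak_analysis)
from .pvcorr import apply_rc, recovery_coefficient
from .regression import SelectionReport, select_model, \
    simple_linear_regression
from .simulate import (CohortConfig, SessionRecord, read_cohort,
                       simulate_cohort, write_cohort)

__all__ = ["PipelineConfig", "filter_sessions", "corrected_metrics",
           "run_pipeline", "quantify_sessions", "pv_correct_metrics"]

log = logging.getLogger("fdgquant")


@dataclass
class PipelineConfig:
    """Run-level settings; the cohort block configures the generator."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None     # read user CSVs instead of simulating
    t_star: float = 15.0             # Patlak linear-range start, min
    alpha: float = 0.05
    lumped_constants: dict = field(
        default_factory=lambda: dict(LUMPED_CONSTANTS))
    min_diameter_mm: float = 2.5
    responses: tuple[str, ...] = ("ki_over_rc", "suv_over_rc")
    out_dir: str = "fdgquant_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "cohort":
                from .simulate import load_config
                import tempfile
                with tempfile.NamedTemporaryFile(
                        "w", suffix=".yaml", delete=False) as fh:
                    yaml.safe_dump(val, fh)
                cfg.cohort = load_config(fh.name)
            elif hasattr(cfg, key):
                setattr(cfg, key, tuple(val) if key == "responses" else val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def filter_sessions(records: list[SessionRecord],
                    min_diameter_mm: float = 2.5
                    ) -> tuple[list[SessionRecord], dict[str, int]]:
    """Drop necrotic sessions and tumors at/below the diameter floor."""
    kept, n_necrotic, n_small = [], 0, 0
    for rec in records:
        if rec.necrotic:
            n_necrotic += 1
        elif rec.tumor_diameter <= min_diameter_mm:
            n_small += 1
        else:
            kept.append(rec)
    counts = {"input": len(records), "dropped_necrotic": n_necrotic,
              "dropped_small": n_small, "kept": len(kept)}
    log.info("session filter: %s", counts)
    return kept, counts


def corrected_metrics(suv: float, ki: float, rc: float,
                      glucose_mean: float, tumor_type: str,
                      selection: SelectionReport | None = None
                      ) -> tuple[float, float]:
    """Tumor-type-specific PV- and glucose-corrected (SUV, Ki).

    The glucose factor is applied when the selected glucose/size model
    says uptake scales with 1/[Glc] (models 3/4); without a selection
    report the known tumor-type rule is used (U87 yes, MDA no).
    """
    if rc is None or glucose_mean is None:
        raise ValueError("RC and glucose required")
    if selection is not None:
        use_glc = selection.chosen_model in (3, 4)
    else:
        use_glc = tumor_type == "U87"
    factor = glucose_mean if use_glc else 1.0
    return (apply_rc(suv * factor, rc), apply_rc(ki * factor, rc))


# ---------------------------------------------------------------------------
# stage runners


def fit_inputs(records: list[SessionRecord],
               cohort: CohortConfig) -> dict[str, dict]:
    """MAP input-function fit per session -> jsonable dict by session."""
    fits: dict[str, dict] = {}
    for rec in records:
        sched = rec.tacs["tumor"].schedule
        early = preprocess_early_lv(
            rec.tacs["LV"].values, sched,
            delay_s=cohort.lv_delay_s,
            dispersion_tau_s=cohort.lv_dispersion_tau_s,
            blood_rc=cohort.lv_blood_rc)
        res = fit_input_function(
            early, rec.blood_sample, rec.tacs["muscle"].values,
            rec.tacs["liver"].values, sched,
            noise_scale=max(cohort.noise_scale, 1.0),
            early_tau_s=cohort.lv_dispersion_tau_s,
            late_sample_cv=max(cohort.blood_sample_cv, 0.002),
            seed=rec.sub_seed)
        if not res.converged:
            log.warning("input fit did not converge for %s", rec.session_id)
        fits[rec.session_id] = {
            "input": dataclasses.asdict(res.input),
            "muscle": dataclasses.asdict(res.muscle_kin),
            "liver": dataclasses.asdict(res.liver_kin),
            "objective": res.objective,
            "converged": res.converged,
            "residual_sums": res.residual_sums,
        }
    return fits


def quantify_sessions(records: list[SessionRecord], input_fits: dict,
                      t_star: float = 15.0,
                      lumped_constants: dict | None = None) -> pd.DataFrame:
    """SUV, Patlak Ki/Int and MRGlu per session."""
    lcs = lumped_constants or LUMPED_CONSTANTS
    rows = []
    for rec in records:
        sched = rec.tacs["tumor"].schedule
        ifp = InputFunctionParams(**input_fits[rec.session_id]["input"])
        conc_mbq = last_frame_value(rec.tacs["tumor"].values, sched) / 1e6
        suv = compute_suv(conc_mbq, rec.injected_dose, rec.body_weight)
        pat = patlak_analysis(rec.tacs["tumor"].values, ifp, sched, t_star)
        lc = lcs[rec.tumor_type]
        rows.append({
            "session_id": rec.session_id, "mouse_id": rec.mouse_id,
            "tumor_type": rec.tumor_type, "study_day": rec.study_day,
            "diameter_mm": rec.tumor_diameter,
            "glucose_mean": rec.glucose_mean,
            "SUV": suv, "Ki": pat.Ki, "Int": pat.Int,
            "r_squared": pat.r_squared, "LC": lc,
            "MRGlu": mrglu(pat.Ki, rec.glucose_mean, lc),
        })
    return pd.DataFrame(rows)


def pv_correct_metrics(metrics: pd.DataFrame,
                       cohort: CohortConfig) -> pd.DataFrame:
    """Add rc, suv_over_rc, ki_over_rc columns."""
    out = metrics.copy()
    out["rc"] = [recovery_coefficient(d, cohort.pv)
                 for d in out["diameter_mm"]]
    out["suv_over_rc"] = out["SUV"] / out["rc"]
    out["ki_over_rc"] = out["Ki"] / out["rc"]
    return out


def _diagnostics(metrics_pv: pd.DataFrame,
                 selections: dict[str, SelectionReport]) -> pd.DataFrame:
    """Corrected-metric verification regressions (slopes expected ~ 0)."""
    rows = []
    for tumor_type, sub in metrics_pv.groupby("tumor_type"):
        sel = selections.get(f"{tumor_type}:ki_over_rc")
        for metric in ("SUV", "Ki"):
            corr = [corrected_metrics(r.SUV, r.Ki, r.rc, r.glucose_mean,
                                      tumor_type, sel)[metric == "Ki"]
                    for r in sub.itertuples()]
            for covar in ("diameter_mm", "glucose_mean"):
                if len(sub) < 3 or np.ptp(sub[covar].to_numpy()) == 0:
                    continue
                slope, icpt, r2, p = simple_linear_regression(
                    corr, sub[covar].to_numpy())
                rows.append({"tumor_type": tumor_type,
                             "metric": f"corrected_{metric}",
                             "covariate": covar, "slope": slope,
                             "r_squared": r2, "p_value": p})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing all intermediates under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    stage = "simulate"
    try:
        if config.input_dir:
            records = read_cohort(config.input_dir)
            log.info("loaded %d sessions from %s", len(records),
                     config.input_dir)
        else:
            records = simulate_cohort(config.cohort, config.seed)
            write_cohort(records, out)
            log.info("simulated %d sessions (seed %d)", len(records),
                     config.seed)

        stage = "fit-input"
        fits = fit_inputs(records, config.cohort)
        (out / "input_fits.json").write_text(json.dumps(fits, indent=1))

        stage = "quantify"
        metrics = quantify_sessions(records, fits, config.t_star,
                                    config.lumped_constants)
        metrics.to_csv(out / "metrics.csv", index=False)

        stage = "pvcorrect"
        metrics_pv = pv_correct_metrics(metrics, config.cohort)
        metrics_pv.to_csv(out / "metrics_pv.csv", index=False)

        stage = "filter"
        kept, counts = filter_sessions(records, config.min_diameter_mm)
        kept_ids = {r.session_id for r in kept}
        analysis = metrics_pv[metrics_pv["session_id"].isin(kept_ids)]

        stage = "select-model"
        selections: dict[str, SelectionReport] = {}
        selection_errors: dict[str, str] = {}
        for tumor_type, sub in analysis.groupby("tumor_type"):
            for response in config.responses:
                data = sub.rename(columns={"diameter_mm": "diameter",
                                           "glucose_mean": "glucose"})
                try:
                    rep = select_model(data, response, alpha=config.alpha)
                except ValueError as err:
                    # too few eligible sessions for this tumor type
                    selection_errors[f"{tumor_type}:{response}"] = str(err)
                    log.warning("%s %s: selection skipped (%s)",
                                tumor_type, response, err)
                    continue
                selections[f"{tumor_type}:{response}"] = rep
                log.info("%s %s -> model %d (%s)", tumor_type, response,
                         rep.chosen_model, rep.chosen_fit.method)
        (out / "selection_report.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in selections.items()}, indent=1,
            default=float))

        stage = "diagnostics"
        diag = _diagnostics(analysis, selections)
        diag.to_csv(out / "diagnostics.csv", index=False)

        report = {
            "version": __version__,
            "seed": config.seed,
            "n_sessions": len(records),
            "filter_counts": counts,
            "chosen_models": {k: v.chosen_model
                              for k, v in selections.items()},
            "selection_errors": selection_errors,
            "elapsed_s": round(time.time() - t0, 1),
        }
        (out / "report.json").write_text(json.dumps(report, indent=1))
        log.info("pipeline finished in %.1f s", report["elapsed_s"])
        return out
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
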