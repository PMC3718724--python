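"""Synthetic longitudinal mouse FDG-PET cohorts.

Generates complete imaging sessions — plasma input function, organ and
tumor time-activity curves on the 35-frame hour-long schedule, blood
glucose draws, injected dose, caliper tumor geometry, necrosis flags and
a late whole-blood sample — with the statistical structure the analysis
pipeline assumes, so every downstream stage is testable without animal
data.

What is emulated, per session:

* a 4-exponential plasma bolus, zero at injection, scaling linearly with
  injected dose (dose ~ Normal(18.28, 1.19) MBq, truncated positive);
* tumors growing linearly in diameter from about 2.5 mm at the first
  scan until they pass 10 mm, with per-mouse random growth slopes, and a
  necrotic core that can switch on once the diameter reaches 5 mm (MDA)
  or exceeds 8 mm (U87) and then persists;
* blood glucose at scan start and end drawn from truncated correlated
  normals matching the cohort means/SDs, end higher than start
  (anesthesia drift); the model glucose is the start/end mean;
* tumor kinetics chosen to realize a configured "truth" regression of
  net influx Ki on glucose and diameter (the irreversible k4 = 0 tumor),
  muscle and liver given full reversible two-tissue kinetics;
* partial-volume attenuation of the measured tumor TAC by the recovery
  coefficient of its current diameter, and the left-ventricle TAC
  degraded by delay, dispersion and a chamber recovery factor;
* additive Gaussian frame noise with variance proportional to
  value / frame duration (the count-statistics heuristic); noisy values
  may dip below zero and are kept, as in real reconstructions.

Every record stores the sub-seed that generated it and the full ground
truth (input parameters, tissue kinetics, true Ki, true RC), enabling
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compartment import TissueKinetics, tissue_frame_averages
from .input_function import (DEFAULT_PLASMA_RATIO, InputFunctionParams,
                             PlasmaRatioModel, eval_input)
from .pvcorr import PVModel, recovery_coefficient, volume_from_diameter
from .regression import GlucoseSizeModelSpec, model_predict
from .schedule import FrameSchedule, make_default_schedule

__all__ = [
    "TimeActivityCurve", "SessionRecord", "GrowthConfig", "GlucoseConfig",
    "TruthModel", "CohortConfig", "sample_input_function",
    "simulate_tissue_tac", "simulate_growth", "simulate_cohort",
    "add_measurement_noise", "write_cohort", "read_cohort",
    "load_config", "save_config",
]

TISSUES = ("tumor", "LV", "muscle", "liver")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration (Bq/mL) on a schedule."""

    schedule: FrameSchedule
    values: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape[0] != self.schedule.n_frames:
            raise ValueError("values length must equal frame count")


@dataclass
class SessionRecord:
    """One imaging session with measurements and (optionally) truth."""

    mouse_id: str
    tumor_type: str                 # "U87" | "MDA"
    study_day: int
    injected_dose: float            # MBq
    body_weight: float              # g
    tumor_volume: float             # mm^3
    tumor_diameter: float           # mm
    necrotic: bool
    glucose_start: float            # mmol/L
    glucose_end: float
    tacs: dict[str, TimeActivityCurve]
    blood_sample: tuple[float, float]   # (time min, whole blood Bq/mL)
    sub_seed: int = 0
    true_params: dict = field(default_factory=dict)

    @property
    def glucose_mean(self) -> float:
        return 0.5 * (self.glucose_start + self.glucose_end)

    @property
    def session_id(self) -> str:
        return f"{self.mouse_id}_d{self.study_day:03d}"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GrowthConfig:
    start_diameter_mean: float = 2.5    # mm at first scan
    start_diameter_sd: float = 0.33
    rate_mean: float = 2.2              # mm/week
    rate_sd: float = 0.5
    end_diameter: float = 10.0          # stop after exceeding this
    necrosis_weekly_prob: float = 0.7   # onset chance once eligible


@dataclass
class GlucoseConfig:
    start_mean: float
    start_sd: float
    end_mean: float
    end_sd: float
    corr: float = 0.5                   # start/end correlation
    floor: float = 2.0                  # physiologic truncation, mmol/L


@dataclass
class TruthModel:
    """True regression of tissue Ki (mL/min/mL) on glucose/diameter."""

    model_id: int = 1
    params: dict = field(default_factory=lambda: {"a": 0.04})
    b_zeroed: bool = True
    between_mouse_sd: float = 0.0       # SD of per-mouse deviation on a
    residual_sd: float = 0.0            # per-session deviation of Ki

    def spec(self) -> GlucoseSizeModelSpec:
        return GlucoseSizeModelSpec(self.model_id, self.b_zeroed
                                    if self.model_id in (3, 4) else False)


def _default_truths() -> dict:
    return {
        "U87": TruthModel(model_id=3, params={"a": 0.27}, b_zeroed=True,
                          between_mouse_sd=0.0, residual_sd=0.01),
        "MDA": TruthModel(model_id=1, params={"a": 0.04},
                          between_mouse_sd=0.014, residual_sd=0.003),
    }


def _default_glucose() -> dict:
    return {
        "U87": GlucoseConfig(7.79, 2.52, 8.45, 2.37),
        "MDA": GlucoseConfig(6.88, 2.52, 8.19, 2.25),
    }


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults mirror the study design."""

    n_mice: dict = field(default_factory=lambda: {"U87": 8, "MDA": 11})
    growth: dict = field(default_factory=lambda: {
        "U87": GrowthConfig(necrosis_weekly_prob=0.5),
        "MDA": GrowthConfig(necrosis_weekly_prob=0.7)})
    glucose: dict = field(default_factory=_default_glucose)
    truth: dict = field(default_factory=_default_truths)
    dose_mean: float = 18.28            # MBq
    dose_sd: float = 1.19
    weight_mean: float = 25.0           # g
    weight_sd: float = 2.5
    tumor_k2: float = 0.25              # 1/min
    tumor_k3: float = 0.06
    tumor_vb: dict = field(default_factory=lambda: {"U87": 0.08,
                                                    "MDA": 0.04})
    noise_scale: float = 30.0           # TAC noise, 0 disables
    blood_sample_cv: float = 0.02
    lv_blood_rc: float = 0.85           # chamber recovery factor
    lv_delay_s: float = 2.0
    lv_dispersion_tau_s: float = 5.0
    pv: PVModel = field(default_factory=PVModel)
    max_weeks: int = 12


# ---------------------------------------------------------------------------
# building blocks


#: per-MBq amplitudes and rates of the nominal bolus shape
_BASE_AMPS = np.array([6.0e5, 8.0e5, 2.5e6]) / 18.28
_BASE_MUS = np.array([0.018, 0.5, 3.5, 7.0])


def sample_input_function(rng: np.random.Generator,
                          injected_dose: float) -> InputFunctionParams:
    """Draw a plausible bolus shape scaling linearly with dose.

    Amplitudes get 15% and rates 10% log-normal jitter; mu4 is kept the
    largest rate, which (with positive A1..A3) guarantees a non-negative
    curve that rises from zero, peaks within ~2 min and then decays.
    """
    if injected_dose <= 0:
        raise ValueError("injected dose must be positive")
    amps = _BASE_AMPS * injected_dose * rng.lognormal(0.0, 0.15, 3)
    mus = _BASE_MUS * rng.lognormal(0.0, 0.10, 4)
    mus[:3].sort()
    mus[3] = max(mus[3], 1.5 * mus[2])
    return InputFunctionParams(*amps, *mus)


def simulate_tissue_tac(ifp: InputFunctionParams, kin: TissueKinetics,
                        sched: FrameSchedule,
                        plasma_ratio: PlasmaRatioModel = DEFAULT_PLASMA_RATIO,
                        tissue: str = "") -> TimeActivityCurve:
    """Noiseless frame-averaged tissue TAC (analytic solution)."""
    values = tissue_frame_averages(ifp, kin, sched, plasma_ratio)
    return TimeActivityCurve(sched, values, tissue)


def simulate_growth(rng: np.random.Generator, tumor_type: str,
                    n_weeks: int,
                    growth: GrowthConfig | None = None
                    ) -> list[tuple[float, float, bool]]:
    """Weekly (volume mm^3, diameter mm, necrotic) until past 10 mm."""
    if tumor_type not in ("U87", "MDA"):
        raise ValueError(f"unknown tumor type {tumor_type!r}")
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    cfg = growth or GrowthConfig()
    d0 = max(rng.normal(cfg.start_diameter_mean, cfg.start_diameter_sd), 1.0)
    rate = max(rng.normal(cfg.rate_mean, cfg.rate_sd), 0.2)
    out: list[tuple[float, float, bool]] = []
    necrotic = False
    for week in range(n_weeks):
        d = d0 + rate * week
        eligible = d >= 5.0 if tumor_type == "MDA" else d > 8.0
        if eligible and not necrotic:
            necrotic = rng.random() < cfg.necrosis_weekly_prob
        out.append((volume_from_diameter(d), d, necrotic))
        if d > cfg.end_diameter:
            break
    return out


def add_measurement_noise(tac: TimeActivityCurve, rng: np.random.Generator,
                          scale: float) -> TimeActivityCurve:
    """Gaussian frame noise with variance ~ value / frame duration."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        return tac
    dur_min = tac.schedule.durations_s / 60.0
    sd = scale * np.sqrt(np.clip(tac.values, 0.0, None) / dur_min)
    noisy = tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sd
    return TimeActivityCurve(tac.schedule, noisy, tac.tissue)


def _truncated_normal(rng, mean, sd, floor):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    return float(floor + abs(rng.normal(0.0, sd)))


def _draw_glucose(rng, cfg: GlucoseConfig) -> tuple[float, float]:
    for _ in range(1000):
        z1, z2 = rng.normal(size=2)
        z2 = cfg.corr * z1 + np.sqrt(1 - cfg.corr ** 2) * z2
        start = cfg.start_mean + cfg.start_sd * z1
        end = cfg.end_mean + cfg.end_sd * z2
        if start > cfg.floor and end > cfg.floor:
            return float(start), float(end)
    return cfg.start_mean, cfg.end_mean


def _lv_measured_tac(ifp: InputFunctionParams, sched: FrameSchedule,
                     ratio: PlasmaRatioModel, delay_s: float, tau_s: float,
                     rc: float) -> np.ndarray:
    """Forward model of the LV chamber: delayed, dispersed, attenuated.

    The dispersed curve obeys y' = (b - y)/tau, integrated exactly per
    step for piecewise-constant b on a fine grid (0.02 s over the first
    two minutes, 1 s beyond), then frame-averaged.
    """
    edges = np.concatenate([np.arange(0.0, 120.0, 0.02),
                            np.arange(120.0, sched.total_duration_s + 1.0,
                                      1.0)])
    t_shift = np.clip(edges - delay_s, 0.0, None) / 60.0
    wb = eval_input(ifp, t_shift) / ratio(t_shift)
    if tau_s > 0:
        y = np.empty_like(wb)
        y[0] = 0.0
        dt = np.diff(edges)
        decay = np.exp(-dt / tau_s)
        for i in range(1, len(edges)):
            y[i] = y[i - 1] * decay[i - 1] + wb[i] * (1 - decay[i - 1])
        wb = y
    # frame averages by cumulative trapezoid
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (wb[1:] + wb[:-1]) * np.diff(edges))])
    lo = np.interp(sched.starts_s, edges, cum)
    hi = np.interp(sched.ends_s, edges, cum)
    return rc * (hi - lo) / sched.durations_s


def _tumor_kinetics(ki: float, k2: float, k3: float,
                    vb: float) -> TissueKinetics:
    """Irreversible kinetics realizing a target net influx Ki."""
    K1 = ki * (k2 + k3) / k3
    return TissueKinetics(K1=K1, k2=k2, k3=k3, k4=0.0, VB=vb)


def _organ_kinetics(rng: np.random.Generator) -> dict[str, TissueKinetics]:
    j = lambda m, cv=0.2: float(m * rng.lognormal(0.0, cv))  # noqa: E731
    return {
        "muscle": TissueKinetics(j(0.08), j(0.35), j(0.04), j(0.004),
                                 min(j(0.03), 0.3)),
        "liver": TissueKinetics(j(0.6), j(0.9), j(0.02), j(0.02),
                                min(j(0.2), 0.5)),
    }


def simulate_cohort(config: CohortConfig | None = None,
                    seed: int = 0) -> list[SessionRecord]:
    """Generate the full longitudinal cohort, deterministically from seed."""
    cfg = config or CohortConfig()
    if any(n < 0 for n in cfg.n_mice.values()):
        raise ValueError("n_mice must be non-negative")
    sched = make_default_schedule()
    ratio = DEFAULT_PLASMA_RATIO
    root = np.random.SeedSequence(seed)
    records: list[SessionRecord] = []

    for tumor_type in sorted(cfg.n_mice):
        truth: TruthModel = cfg.truth[tumor_type]
        gl_cfg: GlucoseConfig = cfg.glucose[tumor_type]
        gr_cfg: GrowthConfig = cfg.growth[tumor_type]
        n = cfg.n_mice[tumor_type]
        if n == 0:
            continue
        mouse_seeds = root.spawn(n) if n else []
        for m, mss in enumerate(mouse_seeds):
            mouse_id = f"{tumor_type}{m + 1:02d}"
            mrng = np.random.default_rng(mss)
            weight = _truncated_normal(mrng, cfg.weight_mean,
                                       cfg.weight_sd, 15.0)
            mouse_dev = mrng.normal(0.0, truth.between_mouse_sd) \
                if truth.between_mouse_sd > 0 else 0.0
            organs = _organ_kinetics(mrng)
            traj = simulate_growth(mrng, tumor_type, cfg.max_weeks, gr_cfg)
            sess_seeds = mss.spawn(len(traj))
            for w, ((vol, diam, necro), sss) in enumerate(
                    zip(traj, sess_seeds)):
                sub_seed = int(sss.generate_state(1)[0] % (2 ** 31))
                rng = np.random.default_rng(sub_seed)
                records.append(_make_session(
                    cfg, sched, ratio, tumor_type, mouse_id, 1 + 7 * w,
                    weight, vol, diam, necro, mouse_dev, organs,
                    truth, gl_cfg, rng, sub_seed))
    return records


def _make_session(cfg, sched, ratio, tumor_type, mouse_id, study_day,
                  weight, vol, diam, necro, mouse_dev, organs, truth,
                  gl_cfg, rng, sub_seed) -> SessionRecord:
    dose = _truncated_normal(rng, cfg.dose_mean, cfg.dose_sd, 0.0)
    g_start, g_end = _draw_glucose(rng, gl_cfg)
    g_mean = 0.5 * (g_start + g_end)

    spec = truth.spec()
    params = dict(truth.params)
    params["a"] = params.get("a", 0.0) + mouse_dev
    ki_true = float(model_predict(spec, params, g_mean, diam))
    if truth.residual_sd > 0:
        ki_true += float(rng.normal(0.0, truth.residual_sd))
    ki_true = max(ki_true, 1e-4)

    vb = cfg.tumor_vb[tumor_type]
    tumor_kin = _tumor_kinetics(ki_true, cfg.tumor_k2, cfg.tumor_k3, vb)
    ifp = sample_input_function(rng, dose)
    rc = recovery_coefficient(diam, cfg.pv)

    true_tacs = {
        "tumor": tissue_frame_averages(ifp, tumor_kin, sched, ratio),
        "muscle": tissue_frame_averages(ifp, organs["muscle"], sched,
                                        ratio),
        "liver": tissue_frame_averages(ifp, organs["liver"], sched, ratio),
    }
    measured = {
        "tumor": TimeActivityCurve(sched, rc * true_tacs["tumor"], "tumor"),
        "muscle": TimeActivityCurve(sched, true_tacs["muscle"], "muscle"),
        "liver": TimeActivityCurve(sched, true_tacs["liver"], "liver"),
        "LV": TimeActivityCurve(sched, _lv_measured_tac(
            ifp, sched, ratio, cfg.lv_delay_s, cfg.lv_dispersion_tau_s,
            cfg.lv_blood_rc), "LV"),
    }
    if cfg.noise_scale > 0:
        measured = {k: add_measurement_noise(v, rng, cfg.noise_scale)
                    for k, v in measured.items()}

    t_sample = float(rng.uniform(70.0, 80.0))
    wb = float(eval_input(ifp, t_sample)) / float(ratio(t_sample))
    if cfg.blood_sample_cv > 0:
        wb *= float(rng.lognormal(0.0, cfg.blood_sample_cv))

    return SessionRecord(
        mouse_id=mouse_id, tumor_type=tumor_type, study_day=study_day,
        injected_dose=dose, body_weight=weight, tumor_volume=vol,
        tumor_diameter=diam, necrotic=bool(necro),
        glucose_start=g_start, glucose_end=g_end, tacs=measured,
        blood_sample=(t_sample, wb), sub_seed=sub_seed,
        true_params={
            "input_function": dataclasses.asdict(ifp),
            "tumor": dataclasses.asdict(tumor_kin),
            "muscle": dataclasses.asdict(organs["muscle"]),
            "liver": dataclasses.asdict(organs["liver"]),
            "ki": ki_true, "rc": rc, "glucose_mean": g_mean,
        },
    )


# ---------------------------------------------------------------------------
# I/O


def write_cohort(records: list[SessionRecord], outdir) -> None:
    """sessions.csv (scalars), tacs.csv (long format), truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    srows, trows, truth = [], [], {}
    for rec in records:
        srows.append({
            "session_id": rec.session_id, "mouse_id": rec.mouse_id,
            "tumor_type": rec.tumor_type, "study_day": rec.study_day,
            "injected_dose_MBq": rec.injected_dose,
            "body_weight_g": rec.body_weight,
            "tumor_volume_mm3": rec.tumor_volume,
            "tumor_diameter_mm": rec.tumor_diameter,
            "necrotic": rec.necrotic,
            "glucose_start_mmol_L": rec.glucose_start,
            "glucose_end_mmol_L": rec.glucose_end,
            "blood_sample_time_min": rec.blood_sample[0],
            "blood_sample_Bq_per_mL": rec.blood_sample[1],
            "sub_seed": rec.sub_seed,
        })
        for tissue, tac in rec.tacs.items():
            for i, (s, d) in enumerate(tac.schedule.frames):
                trows.append({
                    "session_id": rec.session_id, "tissue": tissue,
                    "frame_index": i, "start_s": s, "duration_s": d,
                    "value_Bq_per_mL": tac.values[i],
                })
        truth[rec.session_id] = rec.true_params
    pd.DataFrame(srows).to_csv(outdir / "sessions.csv", index=False,
                               float_format="%.17g")
    pd.DataFrame(trows).to_csv(outdir / "tacs.csv", index=False,
                               float_format="%.17g")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(indir) -> list[SessionRecord]:
    """Rebuild records from sessions.csv/tacs.csv (+ truth.json if any)."""
    indir = Path(indir)
    sess = pd.read_csv(indir / "sessions.csv", float_precision="round_trip")
    tacs = pd.read_csv(indir / "tacs.csv", float_precision="round_trip")
    truth_path = indir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    records = []
    for _, row in sess.iterrows():
        sid = row["session_id"]
        sub = tacs[tacs["session_id"] == sid]
        tac_map = {}
        for tissue, tdf in sub.groupby("tissue"):
            tdf = tdf.sort_values("frame_index")
            sched = FrameSchedule(tuple(zip(tdf["start_s"],
                                            tdf["duration_s"])))
            tac_map[tissue] = TimeActivityCurve(
                sched, tdf["value_Bq_per_mL"].to_numpy(), tissue)
        records.append(SessionRecord(
            mouse_id=row["mouse_id"], tumor_type=row["tumor_type"],
            study_day=int(row["study_day"]),
            injected_dose=row["injected_dose_MBq"],
            body_weight=row["body_weight_g"],
            tumor_volume=row["tumor_volume_mm3"],
            tumor_diameter=row["tumor_diameter_mm"],
            necrotic=bool(row["necrotic"]),
            glucose_start=row["glucose_start_mmol_L"],
            glucose_end=row["glucose_end_mmol_L"],
            tacs=tac_map,
            blood_sample=(row["blood_sample_time_min"],
                          row["blood_sample_Bq_per_mL"]),
            sub_seed=int(row.get("sub_seed", 0)),
            true_params=truth.get(sid, {}),
        ))
    return records


def _config_to_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["pv"] = {"fwhm": cfg.pv.fwhm,
               "background_fraction": cfg.pv.background_fraction}
    return d


def save_config(cfg: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(cfg)))


def load_config(path) -> CohortConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = CohortConfig()
    for key, val in raw.items():
        if key == "pv":
            cfg.pv = PVModel(**val)
        elif key == "growth":
            cfg.growth = {k: GrowthConfig(**v) for k, v in val.items()}
        elif key == "glucose":
            cfg.glucose = {k: GlucoseConfig(**v) for k, v in val.items()}
        elif key == "truth":
            cfg.truth = {k: TruthModel(**v) for k, v in val.items()}
        elif hasattr(cfg, key):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg
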