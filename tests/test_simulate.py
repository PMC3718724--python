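import filecmp

import numpy as np
import pytest

from fdgquant.compartment import TissueKinetics
from fdgquant.input_function import eval_input
from fdgquant.pvcorr import diameter_from_volume
from fdgquant.simulate import (CohortConfig, GrowthConfig, TruthModel,
                               add_measurement_noise, load_config,
                               sample_input_function, save_config,
                               simulate_cohort, simulate_growth,
                               simulate_tissue_tac, write_cohort,
                               read_cohort)


class TestSampleInputFunction:
    def test_zero_at_injection(self, rng):
        for _ in range(20):
            p = sample_input_function(rng, 18.28)
            assert eval_input(p, 0.0) == 0.0

    def test_dose_linearity(self):
        p1 = sample_input_function(np.random.default_rng(5), 10.0)
        p2 = sample_input_function(np.random.default_rng(5), 20.0)
        assert p2.A1 == pytest.approx(2 * p1.A1)
        assert p2.A3 == pytest.approx(2 * p1.A3)
        assert p2.mu1 == p1.mu1 and p2.mu4 == p1.mu4

    def test_seeded_determinism(self):
        draws1 = [sample_input_function(np.random.default_rng(9), 18.0)
                  for _ in range(5)]
        draws2 = [sample_input_function(np.random.default_rng(9), 18.0)
                  for _ in range(5)]
        assert draws1 == draws2

    def test_bolus_shape(self, rng):
        t = np.linspace(0.0, 80.0, 4000)
        for _ in range(50):
            p = sample_input_function(rng, 18.28)
            c = eval_input(p, t)
            assert np.all(c >= -1e-9)
            assert t[np.argmax(c)] < 2.0
            late = c[t >= 5.0]
            assert np.all(np.diff(late) <= 1e-9)

    def test_rejects_nonpositive_dose(self, rng):
        with pytest.raises(ValueError):
            sample_input_function(rng, 0.0)


class TestGrowth:
    def test_mda_necrosis_only_at_or_above_5mm(self, rng):
        for _ in range(50):
            traj = simulate_growth(rng, "MDA", 10)
            for vol, d, flag in traj:
                if d < 5.0:
                    assert not flag

    def test_u87_necrosis_only_above_8mm(self, rng):
        for _ in range(50):
            traj = simulate_growth(rng, "U87", 10)
            for vol, d, flag in traj:
                if d <= 8.0:
                    assert not flag

    def test_necrosis_persists(self, rng):
        cfg = GrowthConfig(necrosis_weekly_prob=1.0)
        traj = simulate_growth(rng, "MDA", 12, cfg)
        flags = [f for _, _, f in traj]
        if any(flags):
            first = flags.index(True)
            assert all(flags[first:])

    def test_linear_diameter_and_termination(self, rng):
        traj = simulate_growth(rng, "U87", 12)
        ds = [d for _, d, _ in traj]
        steps = np.diff(ds)
        assert np.allclose(steps, steps[0])      # constant weekly slope
        assert all(d <= 10.0 for d in ds[:-1])
        assert diameter_from_volume(traj[0][0]) == pytest.approx(ds[0])

    def test_zero_variance_trajectories_identical(self):
        cfg = GrowthConfig(start_diameter_sd=0.0, rate_sd=0.0,
                           necrosis_weekly_prob=0.0)
        t1 = simulate_growth(np.random.default_rng(1), "MDA", 8, cfg)
        t2 = simulate_growth(np.random.default_rng(2), "MDA", 8, cfg)
        assert t1 == t2

    def test_unknown_type_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_growth(rng, "HELA", 5)


class TestNoise:
    def test_zero_scale_identity(self, schedule, nominal_input, rng):
        tac = simulate_tissue_tac(nominal_input,
                                  TissueKinetics(0.1, 0.2, 0.05),
                                  schedule)
        out = add_measurement_noise(tac, rng, 0.0)
        assert np.array_equal(out.values, tac.values)

    def test_unbiased(self, schedule, nominal_input):
        tac = simulate_tissue_tac(nominal_input,
                                  TissueKinetics(0.1, 0.2, 0.05),
                                  schedule)
        rng = np.random.default_rng(3)
        reps = np.stack([add_measurement_noise(tac, rng, 30.0).values
                         for _ in range(1000)])
        dur = schedule.durations_s / 60.0
        sd = 30.0 * np.sqrt(np.clip(tac.values, 0, None) / dur)
        se = sd / np.sqrt(1000)
        assert np.all(np.abs(reps.mean(0) - tac.values) < 3.2 * se + 1e-9)

    def test_longer_frames_less_noisy(self, schedule, nominal_input):
        """At equal amplitude, empirical variance falls with duration."""
        rng = np.random.default_rng(4)
        from fdgquant.simulate import TimeActivityCurve
        flat = TimeActivityCurve(schedule,
                                 np.full(schedule.n_frames, 1e5))
        reps = np.stack([add_measurement_noise(flat, rng, 30.0).values
                         for _ in range(400)])
        var = reps.var(0)
        short = var[schedule.durations_s == 0.5].mean()
        long = var[schedule.durations_s == 900.0].mean()
        assert long < short / 100.0

    def test_negative_scale_rejected(self, schedule, nominal_input, rng):
        tac = simulate_tissue_tac(nominal_input,
                                  TissueKinetics(0.1, 0.2, 0.05),
                                  schedule)
        with pytest.raises(ValueError):
            add_measurement_noise(tac, rng, -1.0)


class TestCohort:
    def test_empty_cohort(self):
        cfg = CohortConfig(n_mice={"U87": 0, "MDA": 0})
        assert simulate_cohort(cfg, seed=0) == []

    def test_session_structure(self, small_cohort):
        cfg, records = small_cohort
        for rec in records:
            assert set(rec.tacs) == {"tumor", "LV", "muscle", "liver"}
            assert 70.0 <= rec.blood_sample[0] <= 80.0
            assert rec.glucose_mean == pytest.approx(
                0.5 * (rec.glucose_start + rec.glucose_end))
            assert diameter_from_volume(rec.tumor_volume) == \
                pytest.approx(rec.tumor_diameter)

    def test_truth_model_constraint_holds_before_noise(self):
        """U87 truth Ki = a/[Glc] without noise: Ki*[Glc] is constant."""
        cfg = CohortConfig(n_mice={"U87": 3, "MDA": 0})
        cfg.truth["U87"] = TruthModel(model_id=3, params={"a": 0.27},
                                      b_zeroed=True, residual_sd=0.0)
        records = simulate_cohort(cfg, seed=5)
        prods = [rec.true_params["ki"] * rec.true_params["glucose_mean"]
                 for rec in records]
        assert np.allclose(prods, 0.27)

    def test_glucose_means_converge(self):
        """Law of large numbers: cohort glucose means approach the
        configured start/end means at ~500 sessions."""
        cfg = CohortConfig(n_mice={"U87": 0, "MDA": 125},
                           noise_scale=0.0)
        records = simulate_cohort(cfg, seed=8)
        assert len(records) >= 400
        starts = np.array([r.glucose_start for r in records])
        ends = np.array([r.glucose_end for r in records])
        gcfg = cfg.glucose["MDA"]
        # truncation at 2 mmol/L shifts the mean up slightly; stay loose
        assert abs(starts.mean() - gcfg.start_mean) < 0.4
        assert abs(ends.mean() - gcfg.end_mean) < 0.4
        assert ends.mean() > starts.mean()

    def test_dose_distribution(self, small_cohort):
        cfg, records = small_cohort
        doses = np.array([r.injected_dose for r in records])
        assert np.all(doses > 0)
        assert abs(doses.mean() - 18.28) < 1.0

    def test_byte_identical_reruns(self, tmp_path):
        cfg = CohortConfig(n_mice={"U87": 1, "MDA": 1})
        for sub in ("a", "b"):
            write_cohort(simulate_cohort(cfg, seed=33), tmp_path / sub)
        for name in ("sessions.csv", "tacs.csv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name,
                               tmp_path / "b" / name, shallow=False)

    def test_io_round_trip(self, tmp_path, small_cohort):
        cfg, records = small_cohort
        write_cohort(records, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == len(records)
        by_id = {r.session_id: r for r in back}
        for rec in records:
            other = by_id[rec.session_id]
            assert np.allclose(other.tacs["tumor"].values,
                               rec.tacs["tumor"].values)
            assert other.necrotic == rec.necrotic
            assert other.true_params["ki"] == pytest.approx(
                rec.true_params["ki"])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_mice={"U87": 2, "MDA": 5}, noise_scale=12.0)
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert back.n_mice == cfg.n_mice
        assert back.noise_scale == 12.0
        assert back.glucose["U87"].start_mean == \
            cfg.glucose["U87"].start_mean
        assert back.truth["MDA"].between_mouse_sd == \
            cfg.truth["MDA"].between_mouse_sd
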