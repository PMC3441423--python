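import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shpd import ciglm, population
from shpd.ciglm import GainProfile, ModelSpec
from shpd.population import (
    aggregate_gains,
    decay_fit,
    delay_related_fraction,
    gains_rm_anova,
    run_pipeline,
)
from shpd.simulate import GeneratorConfig, simulate_cohort


def _profile(unit_id, condition, gains, lags=None):
    g = np.asarray(gains, dtype=float)
    lags = np.asarray(lags if lags is not None else 0.25 * np.arange(1, len(g) + 1))
    return GainProfile(unit_id=unit_id, condition=condition, model_id="1a",
                       lags_s=lags, gain=g, ci_lo=g * 0.9, ci_hi=g * 1.1,
                       se_log=np.full_like(g, 0.05))


class TestAggregateGains:
    def test_mean_and_sem(self):
        df = aggregate_gains([_profile("a", "baseline", [1.2] * 4),
                              _profile("b", "baseline", [1.4] * 4)])
        summ = population.gain_summary(df)
        assert np.allclose(summ["mean"], 1.3)
        assert np.allclose(summ["sem"], 0.1)

    def test_mismatched_lags_raise(self):
        with pytest.raises(ValueError, match="lags"):
            aggregate_gains([_profile("a", "baseline", [1.0] * 4),
                             _profile("b", "baseline", [1.0] * 5)])

    def test_single_unit_raises(self):
        with pytest.raises(ValueError, match="2 units"):
            aggregate_gains([_profile("a", "baseline", [1.0] * 4)])


class TestDecayFit:
    def test_noiseless_parameters_recovered_exactly(self):
        lags = 0.25 * np.arange(1, 11)
        truth = 1.1 + 0.5 * np.exp(-(lags - 0.25) / 0.5)
        f = decay_fit(lags, truth)
        assert f.asymptote == pytest.approx(1.1, abs=1e-6)
        assert f.amplitude == pytest.approx(0.5, abs=1e-6)
        assert f.tau_s == pytest.approx(0.5, abs=1e-6)

    def test_flat_profile_degenerates_to_mean(self):
        lags = 0.25 * np.arange(1, 11)
        f = decay_fit(lags, np.full(10, 1.2))
        assert abs(f.amplitude) < 1e-6
        assert f.asymptote + f.amplitude == pytest.approx(1.2, abs=1e-5)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(3)
        lags = 0.25 * np.arange(1, 11)
        truth = 1.05 + 0.45 * np.exp(-(lags - 0.25) / 0.35)
        errs = []
        for _ in range(20):
            f = decay_fit(lags, truth + rng.normal(0, 0.02, 10))
            errs.append([f.asymptote - 1.05, f.amplitude - 0.45, f.tau_s - 0.35])
        bias = np.abs(np.mean(errs, axis=0))
        assert np.all(bias < np.array([0.05, 0.1, 0.15]))

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            decay_fit(np.array([0.25, 0.5, 0.75]), np.array([1.2, 1.1, 1.05]))


class TestRmAnova:
    @staticmethod
    def _cohort(n_units, delta=0.0, sd=0.05, seed=0, n_lags=10):
        rng = np.random.default_rng(seed)
        profs = []
        lags = 0.25 * np.arange(1, n_lags + 1)
        for u in range(n_units):
            profs.append(_profile(f"u{u}", "baseline",
                                  1.2 + rng.normal(0, sd, n_lags), lags))
            profs.append(_profile(f"u{u}", "stress",
                                  1.2 - delta + rng.normal(0, sd, n_lags), lags))
        return aggregate_gains(profs)

    def test_identical_conditions_give_zero_condition_f(self):
        res = gains_rm_anova(self._cohort(8, delta=0.0, sd=0.0))
        assert res["effects"]["Condition"]["F"] == pytest.approx(0.0, abs=1e-20)

    def test_uniform_suppression_detected_as_main_effect(self):
        res = gains_rm_anova(self._cohort(20, delta=0.1, seed=1))
        assert res["effects"]["Condition"]["p"] < 0.001
        # interaction should not fire under uniform suppression
        assert res["effects"]["Condition x HistoryTime"]["p"] > 0.01

    def test_unbalanced_table_raises_with_hint(self):
        cohort = self._cohort(5)
        cohort = cohort[~((cohort.unit_id == "u0") & (cohort.condition == "stress"))]
        with pytest.raises(ValueError, match="degenerate units"):
            gains_rm_anova(cohort)

    def test_type_i_error_for_condition_effect(self):
        """Exchangeable truth: Condition effect rejects at ~alpha."""
        rejections = 0
        reps = 120
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            profs = []
            lags = 0.25 * np.arange(1, 6)
            for u in range(8):
                profs.append(_profile(f"u{u}", "baseline",
                                      1.2 + rng.normal(0, 0.05, 5), lags))
                profs.append(_profile(f"u{u}", "stress",
                                      1.2 + rng.normal(0, 0.05, 5), lags))
            res = gains_rm_anova(aggregate_gains(profs))
            rejections += res["effects"]["Condition"]["p"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.05)


class TestDelayRelatedFraction:
    def test_chi2_formula_against_binomial(self):
        # 30/100 flagged vs a null of 5%: one-proportion chi-square
        n, frac, p0 = 100, 0.30, 0.05
        chi2 = n * (frac - p0) ** 2 / (p0 * (1 - p0))
        assert chi2 == pytest.approx(131.58, abs=0.01)
        p_chi = stats.chi2.sf(chi2, 1)
        p_binom = stats.binomtest(30, 100, 0.05).pvalue
        assert p_chi < 1e-20 and p_binom < 1e-15

    def test_observed_equal_to_null_gives_zero_chi2(self, small_cohort):
        rng = np.random.default_rng(0)
        res = delay_related_fraction([small_cohort[0].baseline], rng,
                                     n_shifts=50, null_fraction=0.05)
        assert res["n_units"] == 1
        if res["fraction"] == res["null_fraction"]:
            assert res["chi2"] == 0.0

    def test_stationary_units_are_rarely_flagged(self):
        """Null calibration: homogeneous Poisson units flag at ~alpha."""
        from shpd.simulate import TruthParams
        zeros = np.zeros(10)
        truth = TruthParams(mu=np.log(0.25), alpha=zeros, eta=zeros)
        cfg = GeneratorConfig(n_trials=10, delay_length_s=5.0, n_units=25,
                              seed=33, truth=truth,
                              error_rate={"baseline": 0.0, "stress": 0.0})
        units = simulate_cohort(cfg)
        rng = np.random.default_rng(7)
        res = delay_related_fraction([u.baseline for u in units], rng,
                                     n_shifts=200)
        assert res["fraction"] <= 0.2


class TestPipeline:
    def test_smoke_bundle_is_complete_and_parseable(self, tmp_path):
        cfg = GeneratorConfig(n_trials=12, n_units=2, seed=5,
                              error_rate={"baseline": 0.0, "stress": 0.0})
        report = run_pipeline(cfg, tmp_path / "out", models=("1a", "1b"))
        for name in ("gains.csv", "gof.csv", "fits.json", "report.json",
                     "rates.csv", "cohort_gains.csv", "run.log"):
            assert (tmp_path / "out" / name).exists(), name
        gains = pd.read_csv(tmp_path / "out" / "gains.csv")
        assert set(gains.model_id) <= {"1a", "1b"}
        rep = json.loads((tmp_path / "out" / "report.json").read_text())
        assert rep["n_units_ws"] == 2
        assert "deviance_1a_vs_1b" in rep

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_trials=12, n_units=2, seed=9,
                              error_rate={"baseline": 0.0, "stress": 0.0})
        run_pipeline(cfg, tmp_path / "a", models=("1a", "1b"))
        run_pipeline(cfg, tmp_path / "b", models=("1a", "1b"))
        for name in ("gains.csv", "gof.csv", "fits.json", "report.json",
                     "rates.csv", "cohort_gains.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name
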