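import numpy as np
import pytest
from scipy import stats

from shpd import ciglm
from shpd.ciglm import (
    CountSeries,
    ModelSpec,
    bh_fdr,
    bin_session,
    build_design,
    deviance_test,
    fit,
    gain_profile,
    history_matrix,
)
from shpd.session import Session, SpikeTrain
from shpd.simulate import GeneratorConfig, simulate_cohort

from conftest import make_trial


def _series(counts, stress=0.0, labels=None, bin_width=0.25):
    n = len(counts)
    return CountSeries(
        bin_width=bin_width,
        starts=bin_width * np.arange(n),
        counts=np.asarray(counts),
        stress=np.full(n, stress),
        labels=np.asarray(labels if labels is not None else ["Delay"] * n, dtype=object),
        in_scope=np.ones(n, dtype=bool),
    )


class TestBinning:
    def test_counts_land_in_half_open_bins(self):
        trials = [make_trial(1, 0.0, delay=0.25, run=0.25, branch=0.1,
                             choice=0.05, reward=0.05)]
        sess = Session(session_id="s", condition="baseline", noise_db=60,
                       delay_length_s=0.25, trials=trials,
                       spikes=[SpikeTrain(unit_id="u", times=np.array([0.1, 0.2, 0.6]))],
                       pickup_tail_s=0.05)
        cs = bin_session(sess, bin_width=0.25)
        np.testing.assert_array_equal(cs.counts[:3], [2, 0, 1])

    def test_empty_train_gives_all_zero_counts(self, tiny_session):
        sess = Session(**{**tiny_session.__dict__,
                          "spikes": [SpikeTrain(unit_id="u0", times=np.array([]))]})
        assert bin_session(sess).counts.sum() == 0

    def test_spike_count_conservation(self, small_cohort):
        for unit in small_cohort:
            cs = bin_session(unit.baseline)
            assert cs.counts.sum() == unit.baseline.spikes[0].n_spikes

    def test_scope_excludes_first_trial(self, tiny_session):
        cs = bin_session(tiny_session)
        # trial 1 spans [0, 25): its bins are out of scope
        assert not cs.in_scope[cs.starts < 25.0].any()
        assert cs.in_scope[cs.starts >= 25.0].all()


class TestHistoryMatrix:
    def test_lagged_counts_shift_correctly(self):
        cs = _series([2, 0, 1, 3])
        H, valid = history_matrix(cs, order=2, history_bin=0.25)
        # row for the 4th bin: lag1 = count of bin 3, lag2 = count of bin 2
        np.testing.assert_array_equal(H[3], [1, 0])
        np.testing.assert_array_equal(H[2], [0, 2])
        assert not valid[:2].any() and valid[2:].all()

    def test_coarser_history_bin_sums_observation_bins(self):
        cs = _series([1, 2, 3, 4, 5, 6], bin_width=0.25)
        H, valid = history_matrix(cs, order=2, history_bin=0.5)
        # at bin 4 (count 5): lag1 = bins 2+3 = 7, lag2 = bins 0+1 = 3
        np.testing.assert_array_equal(H[4], [7, 3])
        assert not valid[:4].any()

    def test_non_multiple_history_bin_is_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            history_matrix(_series([1, 2]), order=1, history_bin=0.3)


class TestDesign:
    @pytest.mark.parametrize("model_id,ncols", [
        ("h0", 1),       # intercept only
        ("inhom", 6),    # + 5 interval dummies (Delay is reference)
        ("1b", 22),      # + stress + 10 alpha + 10 eta
        ("1a", 27),      # 1b + 5 interval dummies
        ("2", 33),       # mu + 10 gamma + stress + composite + 10 alpha + 10 eta
        ("3", 33),
    ])
    def test_column_counts_follow_the_model_coding(self, small_cohort, model_id, ncols):
        unit = small_cohort[0]
        series = [bin_session(unit.baseline), bin_session(unit.stress)]
        dm = build_design(series, ModelSpec(model_id=model_id))
        assert len(dm.colnames) == ncols

    def test_single_condition_fit_drops_structural_zeros(self, small_cohort):
        unit = small_cohort[0]
        dm = build_design(bin_session(unit.baseline), ModelSpec(model_id="1b"))
        assert "stress" in dm.dropped
        assert all(f"eta_{k}" in dm.dropped for k in range(1, 11))
        assert len(dm.colnames) == 11  # mu + 10 alpha

    def test_collinear_interval_coding_raises_named_rank_error(self):
        # a series that never leaves one non-reference interval makes that
        # dummy constant and collinear with the intercept
        cs = _series(np.random.default_rng(0).poisson(1.0, 40),
                     labels=["Run"] * 40)
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(cs, ModelSpec(model_id="inhom"))


class TestFit:
    def test_intercept_only_recovers_log_mean_exactly(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.7, size=500)
        dm = build_design(_series(counts), ModelSpec(model_id="h0"))
        fr = fit(dm)
        assert fr.coef["mu"] == pytest.approx(np.log(counts.mean()), abs=1e-8)

    def test_fitted_means_reproduce_total_count(self, small_cohort):
        """IRLS fixed point: sum of fitted means equals the observed total."""
        unit = small_cohort[0]
        series = [bin_session(unit.baseline), bin_session(unit.stress)]
        for mid in ("h0", "inhom", "1b", "1a", "2", "3"):
            dm = build_design(series, ModelSpec(model_id=mid))
            fr = fit(dm)
            beta = np.array([fr.coef[c] for c in dm.colnames])
            assert np.exp(dm.X @ beta).sum() == pytest.approx(dm.y.sum(), rel=1e-6)

    def test_gains_invariant_to_time_origin(self, small_cohort):
        import dataclasses
        unit = small_cohort[0]
        shift = 1234.5

        def shifted(sess):
            trials = [dataclasses.replace(
                tr,
                t_startbox=tr.t_startbox + shift, t_gate=tr.t_gate + shift,
                t_branch=tr.t_branch + shift, t_choice=tr.t_choice + shift,
                t_pickup=tr.t_pickup + shift,
                t_reward=None if tr.t_reward is None else tr.t_reward + shift,
            ) for tr in sess.trials]
            spikes = [SpikeTrain(unit_id=st.unit_id, times=st.times + shift)
                      for st in sess.spikes]
            return dataclasses.replace(sess, trials=trials, spikes=spikes)

        spec = ModelSpec(model_id="1a")
        fr0 = fit(build_design([bin_session(unit.baseline),
                                bin_session(unit.stress)], spec))
        fr1 = fit(build_design([bin_session(shifted(unit.baseline)),
                                bin_session(shifted(unit.stress))], spec))
        for name in fr0.coef:
            assert fr0.coef[name] == pytest.approx(fr1.coef[name], abs=1e-6)

    def test_baseline_only_1b_close_to_joint_1a_alpha(self, small_cohort):
        """Baseline history columns only see baseline bins, so a baseline-only
        refit agrees closely (shared mu/B couple the fits, so not exactly)."""
        unit = small_cohort[0]
        joint = fit(build_design([bin_session(unit.baseline),
                                  bin_session(unit.stress)],
                                 ModelSpec(model_id="1a")))
        solo = fit(build_design(bin_session(unit.baseline),
                                ModelSpec(model_id="1b")))
        a_joint = np.array([joint.coef[f"alpha_{k}"] for k in range(1, 11)])
        a_solo = np.array([solo.coef[f"alpha_{k}"] for k in range(1, 11)])
        assert np.max(np.abs(a_joint - a_solo)) < 0.2

    def test_non_integer_counts_are_rejected(self):
        dm = build_design(_series([1, 2, 0, 1]), ModelSpec(model_id="h0"))
        dm.y = dm.y + 0.5
        with pytest.raises(ValueError, match="integer"):
            fit(dm)


class TestGainProfile:
    def test_zero_coefficient_is_unit_gain_with_bracketing_ci(self, small_cohort):
        unit = small_cohort[0]
        fr = fit(build_design([bin_session(unit.baseline),
                               bin_session(unit.stress)], ModelSpec(model_id="1a")))
        pr = gain_profile(fr, "alpha", unit_id=unit.unit_id)
        assert np.all(pr.gain > 0)
        assert np.all((pr.ci_lo <= pr.gain) & (pr.gain <= pr.ci_hi))
        np.testing.assert_allclose(pr.lags_s, 0.25 * np.arange(1, 11))

    def test_exp_transform(self):
        # a log-coefficient of 0.0770 is a spiking gain of 1.080
        assert np.exp(0.0770) == pytest.approx(1.080, abs=5e-4)

    def test_history_free_model_has_no_profile(self, small_cohort):
        unit = small_cohort[0]
        fr = fit(build_design(bin_session(unit.baseline), ModelSpec(model_id="h0")))
        with pytest.raises(ValueError):
            gain_profile(fr, "alpha")


class TestDevianceTest:
    def test_identical_models_give_zero_chi2(self, small_cohort):
        unit = small_cohort[0]
        fr = fit(build_design(bin_session(unit.baseline), ModelSpec(model_id="inhom")))
        chi2, df, p = deviance_test(fr, fr)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_nested_pair_has_five_df(self, small_cohort):
        unit = small_cohort[0]
        series = [bin_session(unit.baseline), bin_session(unit.stress)]
        fa = fit(build_design(series, ModelSpec(model_id="1a")))
        fb = fit(build_design(series, ModelSpec(model_id="1b")))
        chi2, df, p = deviance_test(fa, fb)
        assert df == 5 and chi2 >= 0 and 0 <= p <= 1

    def test_interaction_models_are_not_nested(self, small_cohort):
        unit = small_cohort[0]
        series = [bin_session(unit.baseline), bin_session(unit.stress)]
        f2 = fit(build_design(series, ModelSpec(model_id="2")))
        f3 = fit(build_design(series, ModelSpec(model_id="3")))
        with pytest.raises(ValueError, match="not nested"):
            deviance_test(f2, f3)


class TestBhFdr:
    def test_worked_vector(self):
        rej, _ = bh_fdr([0.001, 0.01, 0.02, 0.9], q=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_all_unit_pvalues_reject_nothing(self):
        rej, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_out_of_range_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_hand_rolled_step_up(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            rej, _ = bh_fdr(p, q=0.1)
            # independent step-up oracle
            order = np.argsort(p)
            m = len(p)
            thresh = 0.1 * np.arange(1, m + 1) / m
            passing = np.nonzero(p[order] <= thresh)[0]
            expect = np.zeros(m, dtype=bool)
            if passing.size:
                expect[order[: passing.max() + 1]] = True
            np.testing.assert_array_equal(rej, expect)

    def test_null_uniform_pvalues_control_fdr(self):
        rng = np.random.default_rng(9)
        false_rates = []
        for _ in range(300):
            p = rng.uniform(size=50)
            rej, _ = bh_fdr(p, q=0.05)
            false_rates.append(rej.any())
        # under the global null, FDR = FWER <= q
        assert np.mean(false_rates) <= 0.05 + 0.03


def test_wald_ci_coverage_is_nominal():
    """True coefficients fall in their 95% CIs at the nominal rate."""
    cfg = GeneratorConfig(n_trials=10, delay_length_s=5.0, n_units=15, seed=17,
                          error_rate={"baseline": 0.0, "stress": 0.0})
    units = simulate_cohort(cfg)
    hits = total = 0
    for u in units:
        series = [bin_session(u.baseline), bin_session(u.stress)]
        fr = fit(build_design(series, ModelSpec(model_id="1a")))
        for which, tru in (("alpha", u.truth.alpha), ("eta", u.truth.eta)):
            pr = gain_profile(fr, which)
            hits += np.sum((pr.ci_lo <= np.exp(tru)) & (np.exp(tru) <= pr.ci_hi))
            total += len(tru)
    assert hits / total > 0.85
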