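import numpy as np
import pytest
from scipy import stats as sps

from timedecode import (
    AnalysisConfig,
    GroupScoreSeries,
    between_condition_test,
    find_clusters,
    max_cluster_mass,
    one_sample_t_series,
    within_condition_test,
)


def _group(ev, times=None):
    ev = np.asarray(ev, dtype=float)
    if times is None:
        times = np.arange(ev.shape[2], dtype=float)
    return GroupScoreSeries(
        participant_means=ev.mean(axis=1), evaluation_scores=ev, times=times
    )


class TestTSeries:
    def test_hand_value(self):
        # means [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641
        t = one_sample_t_series(np.array([[1.0], [2.0], [3.0]]))
        assert t[0] == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert t[0] == pytest.approx(3.4641, abs=1e-4)

    def test_zero_variance_gives_zero(self):
        t = one_sample_t_series(np.zeros((5, 4)))
        assert np.array_equal(t, np.zeros(4))

    def test_odd_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 20))
        assert np.allclose(one_sample_t_series(-x), -one_sample_t_series(x))

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 30)) + 0.3
        ref = sps.ttest_1samp(x, 0.0, axis=0).statistic
        assert np.allclose(one_sample_t_series(x), ref, atol=1e-10)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t_series(np.ones((1, 4)))


class TestFindClusters:
    def test_quantile_oracle_example(self):
        """df=23, alpha=.05: t_crit = 2.0687; run over samples 1-3 of
        [0.5, 2.5, 3.0, 2.2, 0.1] has mass 2.5+3.0+2.2 = 7.7."""
        assert sps.t.ppf(0.975, 23) == pytest.approx(2.0687, abs=1e-4)
        clusters = find_clusters(
            np.array([0.5, 2.5, 3.0, 2.2, 0.1]), df=23, alpha=0.05
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start_idx, c.end_idx) == (1, 3)
        assert c.mass == pytest.approx(7.7, abs=1e-12)

    def test_subthreshold_series_yields_nothing(self):
        assert find_clusters(np.full(10, 0.5), df=23, alpha=0.05) == []
        assert max_cluster_mass([]) == 0.0

    def test_merging_runs_increases_mass(self):
        t = np.array([3.0, 3.0, 0.1, 3.0, 3.0])
        two = find_clusters(t, df=23, alpha=0.05)
        assert len(two) == 2
        t_merged = t.copy()
        t_merged[2] = 2.5
        one = find_clusters(t_merged, df=23, alpha=0.05)
        assert len(one) == 1
        assert one[0].mass >= sum(c.mass for c in two)

    def test_window_restriction(self):
        times = np.arange(-100.0, 150.0, 50.0)
        t = np.full(5, 5.0)
        clusters = find_clusters(t, df=23, alpha=0.05, times=times,
                                 window_ms=(0.0, 2000.0))
        assert len(clusters) == 1
        assert clusters[0].start_ms == 0.0

    def test_matches_run_scan_oracle_on_random_series(self):
        rng = np.random.default_rng(2)
        df, alpha = 23, 0.05
        t_crit = sps.t.ppf(1 - alpha / 2, df)
        for _ in range(200):
            t = rng.normal(scale=2.0, size=50)
            got = find_clusters(t, df=df, alpha=alpha)
            # brute-force scan
            expected = []
            run = None
            for i, v in enumerate(t):
                if v > t_crit:
                    run = [i, i] if run is None else [run[0], i]
                elif run is not None:
                    expected.append(run)
                    run = None
            if run is not None:
                expected.append(run)
            assert [(c.start_idx, c.end_idx) for c in got] == [tuple(r) for r in expected]
            for c in got:
                assert c.mass == pytest.approx(t[c.start_idx:c.end_idx + 1].sum(), abs=1e-10)


class TestWithinConditionTest:
    cfg = AnalysisConfig(n_shuffles=2, analysis_window_ms=(0.0, 2000.0))

    def test_all_zero_scores_accept_null(self):
        g = _group(np.zeros((5, 6, 20)), times=np.arange(0.0, 400.0, 20.0))
        res = within_condition_test(g, self.cfg, seed=0, n_permutations=100)
        assert res.observed_max_mass == 0.0
        assert not res.reject
        assert res.p_value == 1.0

    def test_strong_signal_rejects(self):
        rng = np.random.default_rng(3)
        times = np.arange(0.0, 1000.0, 20.0)
        ev = rng.normal(scale=0.1, size=(24, 12, len(times)))
        ev[:, :, 5:30] += 1.0  # 500 ms of strong signal
        res = within_condition_test(_group(ev, times), self.cfg, seed=1,
                                    n_permutations=200)
        assert res.reject and res.p_value < 0.01

    def test_permutation_determinism(self):
        rng = np.random.default_rng(4)
        ev = rng.normal(size=(6, 4, 15))
        g = _group(ev, np.arange(0.0, 300.0, 20.0))
        a = within_condition_test(g, self.cfg, seed=9, n_permutations=150)
        b = within_condition_test(g, self.cfg, seed=9, n_permutations=150)
        assert np.array_equal(a.null_masses, b.null_masses)
        assert a.p_value == b.p_value

    def test_p_value_never_zero_and_add_one_rule(self):
        rng = np.random.default_rng(5)
        ev = rng.normal(size=(8, 4, 10)) + 5.0  # overwhelming signal
        g = _group(ev, np.arange(0.0, 200.0, 20.0))
        res = within_condition_test(g, self.cfg, seed=0, n_permutations=199)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_null_distribution_symmetric_under_global_negation(self):
        """Sign-flip nulls from x and -x are equal in distribution."""
        rng = np.random.default_rng(6)
        ev = rng.normal(size=(10, 8, 25)) + 0.3
        times = np.arange(0.0, 500.0, 20.0)
        a = within_condition_test(_group(ev, times), self.cfg, seed=11,
                                  n_permutations=2000)
        b = within_condition_test(_group(-ev, times), self.cfg, seed=12,
                                  n_permutations=2000)
        ks = sps.ks_2samp(a.null_masses, b.null_masses).statistic
        assert ks < 0.05

    def test_participant_flip_unit_available(self):
        rng = np.random.default_rng(7)
        ev = rng.normal(size=(6, 4, 10))
        g = _group(ev, np.arange(0.0, 200.0, 20.0))
        res = within_condition_test(g, self.cfg, seed=0, n_permutations=100,
                                    flip_unit="participant")
        assert res.extra["flip_unit"] == "participant"

    def test_single_timepoint_type_one_error_near_alpha(self):
        """With one timepoint the test reduces to a sign-flip location test;
        under the null it must reject at ~alpha."""
        cfg = AnalysisConfig(
            analysis_window_ms=(0.0, 20.0), early_train_window_ms=(0.0, 20.0)
        )
        rng = np.random.default_rng(8)
        rejections = 0
        n_sets = 300
        for s in range(n_sets):
            ev = rng.normal(size=(12, 6, 1))
            g = _group(ev, np.array([0.0]))
            res = within_condition_test(g, cfg, seed=s, n_permutations=200)
            rejections += res.reject
        rate = rejections / n_sets
        # binomial 99.9% band around 0.05 at n=300
        assert 0.01 < rate < 0.10


class TestBetweenConditionTest:
    cfg = AnalysisConfig(analysis_window_ms=(0.0, 2000.0))

    def test_identical_conditions_give_zero_statistic(self):
        rng = np.random.default_rng(9)
        ev = rng.normal(size=(8, 4, 20)) + 0.5
        times = np.arange(0.0, 400.0, 20.0)
        g = _group(ev, times)
        res = between_condition_test(g, g, self.cfg, seed=0, n_permutations=100)
        assert res.observed_max_mass == 0.0
        assert not res.reject

    def test_participant_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        times = np.arange(0.0, 200.0, 20.0)
        a = _group(rng.normal(size=(8, 4, 10)), times)
        b = _group(rng.normal(size=(6, 4, 10)), times)
        with pytest.raises(ValueError, match="paired"):
            between_condition_test(a, b, self.cfg, seed=0, n_permutations=10)

    def test_large_difference_rejects(self):
        rng = np.random.default_rng(11)
        times = np.arange(0.0, 1000.0, 20.0)
        base = rng.normal(scale=0.1, size=(24, 8, len(times)))
        a = base.copy()
        a[:, :, 5:45] += 1.0  # long strong cluster in A only
        b = base + rng.normal(scale=0.1, size=base.shape)
        b[:, :, 5:15] += 1.0  # short cluster in B
        res = between_condition_test(_group(a, times), _group(b, times),
                                     self.cfg, seed=1, n_permutations=200)
        assert res.reject and res.p_value < 0.05

    def test_determinism(self):
        rng = np.random.default_rng(12)
        times = np.arange(0.0, 300.0, 20.0)
        a = _group(rng.normal(size=(6, 4, 15)), times)
        b = _group(rng.normal(size=(6, 4, 15)), times)
        r1 = between_condition_test(a, b, self.cfg, seed=3, n_permutations=100)
        r2 = between_condition_test(a, b, self.cfg, seed=3, n_permutations=100)
        assert np.array_equal(r1.null_masses, r2.null_masses)


def test_group_series_mean_invariant_enforced():
    with pytest.raises(ValueError, match="evaluation average"):
        GroupScoreSeries(
            participant_means=np.ones((2, 3)),
            evaluation_scores=np.zeros((2, 4, 3)),
            times=np.arange(3.0),
        )
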