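import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from renaldwi.stats import (
    bh_adjust,
    egfr_augmented_regression,
    lasso_mixed,
    mixed_corr,
    pearson,
    proteinuria_test,
)


def sim_bilateral(n, r_total, rng, between_frac=0.5):
    """n subjects x 2 kidneys with total correlation r_total, split evenly
    between subject-level and kidney-level covariance."""
    sb = between_frac * np.array([[1, r_total], [r_total, 1]])
    sw = (1 - between_frac) * np.array([[1, r_total], [r_total, 1]])
    u = rng.multivariate_normal([0, 0], sb, n)
    e = rng.multivariate_normal([0, 0], sw, (n, 2))
    x = (u[:, None, 0] + e[:, :, 0]).ravel()
    y = (u[:, None, 1] + e[:, :, 1]).ravel()
    return x, y, np.repeat(np.arange(n), 2)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed(self):
        r, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_null_behavior(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r, _ = pearson(x, y)
        assert abs(r) < 0.05

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestBhAdjust:
    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_test_unchanged(self):
        assert bh_adjust([0.04])[0] == 0.04

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=40)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_stepup_properties(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone along sorted p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestMixedCorr:
    def test_identical_variables(self, rng):
        x, _, s = sim_bilateral(30, 0.5, rng)
        res = mixed_corr(x, x.copy(), s)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-6

    def test_one_kidney_per_subject_equals_pearson(self, rng):
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40) * 0.8
        res = mixed_corr(x, y, np.arange(40))
        r_ref, p_ref = pearson(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-6)
        assert res.p == pytest.approx(p_ref, abs=1e-6)

    def test_estimates_known_total_correlation(self):
        ests = [
            mixed_corr(*sim_bilateral(200, 0.7, np.random.default_rng(100 + i))).r
            for i in range(20)
        ]
        assert np.mean(ests) == pytest.approx(0.7, abs=0.02)

    def test_ci_contains_r(self, rng):
        x, y, s = sim_bilateral(50, 0.6, rng)
        res = mixed_corr(x, y, s)
        assert res.ci_low <= res.r <= res.ci_high

    def test_recovers_structure(self, rng):
        x, y, s = sim_bilateral(400, 0.7, rng, between_frac=0.7)
        res = mixed_corr(x, y, s)
        assert res.between is not None
        b_share = res.between[0, 0] / (res.between[0, 0] + res.within[0, 0])
        assert b_share == pytest.approx(0.7, abs=0.1)


class TestLassoMixed:
    @staticmethod
    def _sim(seed, n=60, p=24, true_idx=(2, 7, 15)):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(n), 2)
        X = rng.normal(size=(2 * n, p))
        u = np.repeat(rng.normal(0, 0.5, n), 2)
        beta = np.zeros(p)
        beta[list(true_idx)] = 1.0
        y = X @ beta + u + rng.normal(0, 1.0, 2 * n)
        return X, y, subj

    def test_full_shrinkage_at_infinite_penalty(self):
        X, y, s = self._sim(0)
        m = lasso_mixed(X, y, s, alphas=[1e12], seed=0)
        assert np.all(m.coef == 0)
        assert m.intercept == pytest.approx(np.mean(y), abs=1e-12)
        assert m.r2_marginal == 0.0

    def test_selects_true_predictors(self):
        X, y, s = self._sim(1)
        m = lasso_mixed(X, y, s, seed=1)
        assert len(set(np.nonzero(m.coef)[0]) & {2, 7, 15}) >= 2

    def test_row_duplication_preserves_signs(self):
        X, y, s = self._sim(2)
        m1 = lasso_mixed(X, y, s, seed=3)
        m2 = lasso_mixed(np.vstack([X, X]), np.hstack([y, y]), np.hstack([s, s]), seed=3)
        sel = np.nonzero(m1.coef)[0]
        assert np.all(np.sign(m2.coef[sel]) >= 0) == np.all(np.sign(m1.coef[sel]) >= 0)
        big = np.abs(m1.coef) > 0.3
        assert np.array_equal(np.sign(m1.coef[big]), np.sign(m2.coef[big]))

    def test_constant_predictor_dropped(self):
        X, y, s = self._sim(4)
        X[:, 5] = 2.0
        m = lasso_mixed(X, y, s, alphas=[0.1], seed=0)
        assert m.dropped == ["x5"]
        assert len(m.coef) == X.shape[1] - 1


class TestEgfrAugmentedRegression:
    def test_exact_identity_gives_null_metric(self, rng):
        egfr = rng.normal(80, 20, 40)
        metric = rng.normal(2, 0.3, 40)
        out = egfr_augmented_regression(egfr, egfr, metric)
        assert out["metric_coef"] == pytest.approx(0.0, abs=1e-8)
        assert out["metric_p"] == pytest.approx(1.0, abs=1e-6)

    def test_informative_metric_detected(self):
        detected = 0
        for i in range(20):
            rng = np.random.default_rng(500 + i)
            egfr = rng.normal(80, 20, 100)
            metric = rng.normal(2, 0.5, 100)
            mgfr = 0.5 * egfr + 20 * metric + rng.normal(0, 5, 100)
            out = egfr_augmented_regression(mgfr, egfr, metric)
            detected += out["metric_p"] < 0.01
        assert detected >= 19

    def test_collinear_predictors_named(self, rng):
        egfr = rng.normal(80, 20, 40)
        with pytest.raises(ValueError, match="collinear"):
            egfr_augmented_regression(rng.normal(size=40), egfr, 2 * egfr)


class TestProteinuriaTest:
    def test_identical_groups(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        lab = np.r_[np.zeros(5), np.ones(5)]
        res = proteinuria_test(v, lab)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_welch_from_printed_summaries(self, rng):
        # groups rebuilt to match published means/SDs (2.34+-0.19 n=22 vs
        # 2.09+-0.16 n=4) give Welch t ~= 2.79, df ~= 4.7
        def exact_sample(n, mean, sd, rng):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        neg = exact_sample(22, 2.34, 0.19, rng)
        pos = exact_sample(4, 2.09, 0.16, rng)
        res = proteinuria_test(np.r_[neg, pos], np.r_[np.zeros(22), np.ones(4)])
        assert res.t == pytest.approx(2.79, abs=0.01)
        assert res.df == pytest.approx(4.7, abs=0.1)
        assert res.p == pytest.approx(0.042, abs=0.005)

    def test_shift_monotonically_decreases_p(self, rng):
        neg = rng.normal(2.0, 0.2, 20)
        pos = rng.normal(2.0, 0.2, 6)
        labels = np.r_[np.zeros(20), np.ones(6)]
        ps = [
            proteinuria_test(np.r_[neg + c, pos], labels).p for c in (0.05, 0.15, 0.3)
        ]
        assert ps[0] > ps[1] > ps[2]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            proteinuria_test([1.0, 2.0, 3.0], [0, 0, 1])
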