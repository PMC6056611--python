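"""Cohort statistics: oracles, exact enumerations, and invariants."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from neopli.pli import PLIMatrix
from neopli.stats import (
    correlate_band, detect_outliers, fit_linear_model,
    hierarchical_regression, longitudinal_trend, mann_whitney,
    spearman_exact, topography_correlations,
)


class TestDetectOutliers:
    def test_single_extreme_value_found(self, rng):
        x = rng.standard_normal(100)
        x[17] = x.mean() + 10 * x.std(ddof=1)
        idx = detect_outliers(x)
        assert idx.tolist() == [17]
        # cross-check by direct z computation
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.flatnonzero(np.abs(z) > 3.29).tolist() == [17]

    def test_constant_list_has_none(self):
        assert detect_outliers([5.0] * 10).size == 0

    def test_moderate_sample_has_none(self):
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0])
        assert detect_outliers(x).size == 0


class TestCorrelateBand:
    def test_collinear_data_pearson_minus_one(self):
        pma = np.linspace(28, 45, 20)
        assert_res = correlate_band(pma, 0.4 - 0.005 * pma)
        assert assert_res.method == "pearson"
        assert assert_res.coefficient == pytest.approx(-1.0)

    def test_outlier_switches_to_spearman(self):
        pma = np.linspace(28, 45, 30)
        mpli = np.exp(-0.2 * (pma - 28))  # monotone nonlinear
        mpli[5] = 50.0                     # gross outlier, breaks monotonicity
        res = correlate_band(pma, mpli)
        assert res.method == "spearman"
        # ranks: one value hugely positive, rest decreasing; spearman on
        # ranks equals pearson of rank vectors
        rho = scipy.stats.spearmanr(pma, mpli).statistic
        assert res.coefficient == pytest.approx(rho)

    def test_monotone_with_outlier_recovers_minus_one(self):
        pma = np.linspace(28, 45, 30)
        mpli = np.exp(-0.2 * (pma - 28))
        mpli[0] = 60.0  # outlier but still the largest -> monotone intact
        res = correlate_band(pma, mpli)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(-1.0)

    def test_too_few_subjects_fatal(self):
        with pytest.raises(ValueError):
            correlate_band([1, 2], [3, 4])


class TestFitLinearModel:
    def test_exact_line_recovers_coefficients(self):
        pma = np.linspace(27.6, 45.3, 131)
        mpli = 0.344 - 0.005 * pma
        res = fit_linear_model(pma, mpli)
        assert res.intercept_b0 == pytest.approx(0.344, abs=1e-10)
        assert res.slope_b1 == pytest.approx(-0.005, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert res.df_resid == 129

    def test_three_point_closed_form(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 3.0])
        # closed-form least squares
        b1 = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean())**2)
        b0 = y.mean() - b1 * x.mean()
        res = fit_linear_model(x, y)
        assert res.slope_b1 == pytest.approx(b1)
        assert res.intercept_b0 == pytest.approx(b0)

    def test_single_predictor_identities(self, rng):
        x = rng.uniform(28, 45, 60)
        y = 0.3 - 0.004 * x + rng.normal(0, 0.02, 60)
        res = fit_linear_model(x, y)
        r_pearson = scipy.stats.pearsonr(x, y).statistic
        assert res.r == pytest.approx(r_pearson, rel=1e-8)
        assert res.f_stat == pytest.approx(res.t_b1**2, rel=1e-8)
        assert res.r_squared == pytest.approx(r_pearson**2, rel=1e-8)

    def test_null_slope_over_replicates(self):
        rng = np.random.default_rng(7)
        slopes, fs = [], []
        for _ in range(200):
            x = rng.uniform(28, 45, 40)
            y = rng.normal(0.2, 0.03, 40)
            res = fit_linear_model(x, y)
            slopes.append(res.slope_b1)
            fs.append(res.p_model < 0.05)
        assert abs(np.mean(slopes)) < 5e-4
        assert np.mean(fs) == pytest.approx(0.05, abs=0.05)

    def test_constant_predictor_fatal(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_model([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestHierarchicalRegression:
    def test_copy_of_predictor_is_fatal_collinearity(self):
        pma = np.linspace(28, 45, 20)
        y = 0.3 - 0.004 * pma
        with pytest.raises(ValueError, match="collinear"):
            hierarchical_regression(pma, y, {"ga": pma.copy()})

    def test_f_change_matches_rss_bruteforce_n6(self):
        pma = np.array([30.0, 32.0, 35.0, 38.0, 41.0, 44.0])
        y = np.array([0.25, 0.22, 0.20, 0.16, 0.15, 0.10])
        cov = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        steps = hierarchical_regression(pma, y, {"c": cov})
        # brute force via residual sums of squares of both fits
        X1 = np.column_stack([np.ones(6), pma])
        X2 = np.column_stack([np.ones(6), pma, cov])
        rss = lambda X: float(
            ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
        )
        rss1, rss2 = rss(X1), rss(X2)
        f_expected = (rss1 - rss2) / 1 / (rss2 / (6 - 2 - 1))
        assert steps[0].f_change == pytest.approx(f_expected, rel=1e-8)
        tss = float(((y - y.mean()) ** 2).sum())
        assert steps[0].r_squared_change == pytest.approx(
            (rss1 - rss2) / tss, rel=1e-8
        )

    def test_independent_covariate_adds_nothing(self):
        rng = np.random.default_rng(11)
        pma = rng.uniform(28, 45, 500)
        y = 0.34 - 0.005 * pma + rng.normal(0, 0.03, 500)
        cov = rng.normal(0, 1, 500)
        steps = hierarchical_regression(pma, y, {"noise": cov})
        assert steps[0].r_squared_change < 0.01

    def test_listwise_deletion_reports_complete_cases(self):
        rng = np.random.default_rng(3)
        pma = rng.uniform(28, 45, 50)
        y = 0.3 - 0.004 * pma + rng.normal(0, 0.02, 50)
        cov = rng.normal(0, 1, 50)
        cov[:6] = np.nan
        steps = hierarchical_regression(pma, y, {"bw": cov})
        assert steps[0].n == 44
        assert steps[0].df2 == 44 - 2 - 1

    def test_nested_r_squared_monotone(self, rng):
        pma = rng.uniform(28, 45, 80)
        y = 0.3 - 0.004 * pma + rng.normal(0, 0.02, 80)
        covs = {"a": rng.normal(size=80), "b": rng.normal(size=80)}
        steps = hierarchical_regression(pma, y, covs)
        assert all(s.r_squared_change >= -1e-12 for s in steps)


class TestMannWhitney:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(30)
        res = mann_whitney(x, x)
        assert res.z == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_fully_separated_3v3_exact_enumeration(self):
        a = [1.0, 2.0, 3.0]
        b = [10.0, 11.0, 12.0]
        res = mann_whitney(a, b)
        assert res.u in (0.0, 9.0)
        # exact two-sided p by enumerating all C(6,3) = 20 rank assignments
        pooled = np.array(a + b)
        ranks = scipy.stats.rankdata(pooled)
        obs_u = res.u
        extreme = 0
        for combo in itertools.combinations(range(6), 3):
            r1 = ranks[list(combo)].sum()
            u1 = r1 - 3 * 4 / 2
            u = min(u1, 9 - u1)
            if u <= min(obs_u, 9 - obs_u):
                extreme += 1
        assert res.p == pytest.approx(extreme / 20)  # = 0.1
        assert res.p == pytest.approx(0.1)

    def test_label_permutation_leaves_u_distribution(self, rng):
        pooled = rng.standard_normal(20)
        u1 = mann_whitney(pooled[:10], pooled[10:]).u
        u2 = mann_whitney(pooled[10:], pooled[:10]).u
        assert u1 + u2 == 100  # U_A + U_B = n1*n2

    def test_tie_corrected_z(self):
        a = [1.0, 1.0, 2.0, 3.0]
        b = [1.0, 2.0, 2.0, 4.0]
        res = mann_whitney(a, b)
        # hand-computed tie correction
        n1 = n2 = 4
        nt = 8
        _, counts = np.unique(a + b, return_counts=True)
        tie = np.sum(counts**3 - counts)
        var = n1 * n2 / 12 * ((nt + 1) - tie / (nt * (nt - 1)))
        assert abs(res.z) == pytest.approx(
            abs(res.u - 8.0) / math.sqrt(var), rel=1e-9
        )


class TestSpearmanExact:
    def test_strictly_decreasing_six_points(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [6, 5, 4, 3, 2, 1]
        res = spearman_exact(x, y)
        assert res.coefficient == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(2 / 720)

    def test_matches_scipy_rho_with_ties(self, rng):
        x = rng.uniform(0, 1, 7)
        y = np.round(rng.uniform(0, 1, 7), 1)  # induce ties
        res = spearman_exact(x, y)
        assert res.coefficient == pytest.approx(
            scipy.stats.spearmanr(x, y).statistic, rel=1e-9
        )

    def test_exact_p_is_permutation_fraction(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0]
        res = spearman_exact(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.array(p))[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(ry)
        )
        assert res.p_value == pytest.approx(count / math.factorial(5))


class TestLongitudinalTrend:
    def test_six_decreasing_points(self):
        pma = [33.1, 36.0, 39.0, 42.0, 45.5, 48.9]
        mpli = [0.30, 0.27, 0.22, 0.19, 0.15, 0.12]
        corr, reg = longitudinal_trend(pma, mpli)
        assert corr.coefficient == pytest.approx(-1.0)
        assert corr.p_value == pytest.approx(2 / 720)
        assert reg.slope_b1 < 0

    def test_slope_recovered_within_ci(self):
        rng = np.random.default_rng(5)
        pma = np.array([33.0, 36.0, 39.0, 42.0, 45.0, 48.0])
        hits = 0
        for _ in range(100):
            y = 0.35 - 0.005 * pma + rng.normal(0, 0.005, 6)
            _, reg = longitudinal_trend(pma, y)
            se = abs(reg.slope_b1 / reg.t_b1)
            hits += abs(reg.slope_b1 + 0.005) < 2.78 * se  # t_{4,0.975}
        assert hits >= 85  # ~95% coverage

    def test_too_few_points_refused(self):
        with pytest.raises(ValueError, match=">= 6"):
            longitudinal_trend([33, 35, 37, 39, 41], [5, 4, 3, 2, 1])


class TestTopography:
    @staticmethod
    def cohort_matrices(rng, pma, planted=(), slope=-0.02):
        mats = []
        for p in pma:
            v = np.zeros((21, 21))
            iu = np.triu_indices(21, k=1)
            tri = 0.2 + 0.01 * rng.standard_normal(210)
            v[iu] = tri
            v += v.T
            np.fill_diagonal(v, 0.0)
            for (i, j) in planted:
                val = 0.8 + slope * (p - 28) + 0.01 * rng.standard_normal()
                v[i, j] = v[j, i] = np.clip(val, 0, 1)
            mats.append(PLIMatrix(values=np.clip(v, 0, 1) * (1 - np.eye(21))))
        return mats

    def test_exactly_210_entries(self, rng):
        pma = np.linspace(28, 45, 10)
        mats = self.cohort_matrices(rng, pma)
        res = topography_correlations(mats, pma)
        assert len(res.coefficients) == 210
        assert len(res.pair_labels) == 210

    def test_planted_pairs_occupy_top_ranks(self, rng):
        pma = np.linspace(28, 45, 40)
        planted = [(0, 5), (3, 11), (10, 20)]
        mats = self.cohort_matrices(rng, pma, planted=planted)
        res = topography_correlations(mats, pma)
        from neopli.montage import Montage
        m = Montage()
        top3 = {tuple(sorted(m.channel_index(ch) for ch in labels))
                for labels, _, _ in res.top(3)}
        assert top3 == {tuple(sorted(p)) for p in planted}

    def test_null_cohort_has_no_significant_pairs(self, rng):
        pma = np.linspace(28, 45, 30)
        total_sig = 0
        for _ in range(20):
            mats = self.cohort_matrices(rng, pma)
            res = topography_correlations(mats, pma)
            total_sig += int(res.significant.sum())
        # expectation ~ 20 * 210 * 1e-4 = 0.42 significant pairs
        assert total_sig <= 4

    def test_zero_variance_pair_excluded_with_warning(self, rng):
        pma = np.linspace(28, 45, 10)
        mats = self.cohort_matrices(rng, pma)
        for m in mats:
            m.values[0, 1] = m.values[1, 0] = 0.5
        with pytest.warns(UserWarning, match="zero variance"):
            res = topography_correlations(mats, pma)
        assert np.isnan(res.coefficients[0])
        assert 0 not in res.ranking.tolist()
        assert len(res.ranking) == 209
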