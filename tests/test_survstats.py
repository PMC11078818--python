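"""Cox fits, Kaplan-Meier, log-rank, cutpoint scan, BH-FDR, gene screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from pairstage import (
    ValidationError,
    bh_fdr,
    fit_cox,
    km_estimate,
    logrank_test,
    max_selected_cutpoint,
    screen_genes,
    univariate_cox_scan,
)
from conftest import exponential_survival


def breslow_negloglik(beta, x, t, e):
    """Independent partial-likelihood oracle (written from the definition)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = x[t >= t[i]]
            ll += beta * x[i] - np.log(np.exp(beta * risk).sum())
    return -ll


class TestFitCox:
    def test_six_observation_fit_matches_brute_force_newton(self):
        # fixed tie-free worked dataset
        t = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
        res = optimize.minimize_scalar(
            breslow_negloglik, bounds=(-10, 10), args=(x, t, e), method="bounded",
            options={"xatol": 1e-12},
        )
        fit = fit_cox(x, t, e)
        assert abs(fit["coef"].iloc[0] - res.x) < 1e-8

    def test_null_covariate_hr_near_one_p_uniform(self, rng):
        n = 1000
        t, e = exponential_survival(rng, np.zeros(n), censor=30)
        hr = fit_cox(rng.normal(size=n), t, e)["hr"].iloc[0]
        assert 0.85 < hr < 1.18
        # p-values across many independent null covariates are ~ Uniform(0,1)
        scan = univariate_cox_scan(rng.normal(size=(n, 150)), t, e)
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_ci_coverage_for_true_log_hazard_ratio(self, rng):
        """95% CI covers the simulated log-HR = 1 in >= 93% of replicates."""
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.integers(0, 2, size=500).astype(float)
            t, e = exponential_survival(rng, 1.0 * x, censor=40)
            scan = univariate_cox_scan(x[:, None], t, e)
            lo = scan["coef"].iloc[0] - 1.96 * scan["se"].iloc[0]
            hi = scan["coef"].iloc[0] + 1.96 * scan["se"].iloc[0]
            covered += lo <= 1.0 <= hi
        assert covered / n_rep >= 0.93

    def test_multivariable_fit_recovers_adjusted_effects(self, rng):
        n = 800
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t, e = exponential_survival(rng, 0.8 * x1 - 0.5 * x2, censor=50)
        fit = fit_cox(pd.DataFrame({"x1": x1, "x2": x2}), t, e)
        assert abs(fit.loc["x1", "coef"] - 0.8) < 0.2
        assert abs(fit.loc["x2", "coef"] + 0.5) < 0.25

    def test_constant_covariate_rejected(self, rng):
        t, e = exponential_survival(rng, np.zeros(20))
        with pytest.raises(ValidationError, match="constant"):
            fit_cox(np.ones(20), t, e)

    def test_separation_reported_explicitly(self):
        t = np.arange(1.0, 11.0)
        e = np.ones(10, dtype=int)
        with pytest.raises(RuntimeError, match="separation|monotone"):
            fit_cox(-t, t, e)


class TestScanMatchesReference:
    def test_scan_agrees_with_lifelines_on_random_features(self, rng):
        n = 250
        eta = rng.normal(size=n)
        t, e = exponential_survival(rng, eta, censor=30)
        X = np.column_stack([eta, rng.normal(size=n), rng.integers(0, 2, n)])
        scan = univariate_cox_scan(X, t, e)
        for j in range(X.shape[1]):
            ref = fit_cox(X[:, j], t, e)
            assert abs(scan["coef"].iloc[j] - ref["coef"].iloc[0]) < 1e-6
            assert abs(scan["se"].iloc[j] - ref["se"].iloc[0]) < 1e-6

    def test_scan_flags_constant_column(self, rng):
        t, e = exponential_survival(rng, np.zeros(50))
        scan = univariate_cox_scan(np.ones((50, 1)), t, e)
        assert np.isnan(scan["p"].iloc[0])
        assert not scan["converged"].iloc[0]


class TestKaplanMeier:
    def test_hand_product_limit_oracle(self):
        s = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert s.loc[0.0] == 1.0
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(2 / 3)  # censoring does not drop S
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=200)
        s = km_estimate(t, np.ones(200, dtype=int))
        grid = np.quantile(t, [0.1, 0.5, 0.9])
        for g in grid:
            emp = (t > g).mean()
            km_at = s[s.index <= g].iloc[-1]
            assert km_at == pytest.approx(emp, abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        s = km_estimate([5.0, 8.0, 2.0], [0, 0, 0])
        assert (s == 1.0).all()

    def test_monotone_non_increasing(self, rng):
        t, e = exponential_survival(rng, np.zeros(150), censor=20)
        s = km_estimate(t, e)
        assert (np.diff(s.to_numpy()) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 3.0, 5.0, 7.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = logrank_test(g, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_matches_direct_observed_minus_expected_accumulation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        g = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        # independent O-E/V accumulation over event times
        o_minus_e, v = 0.0, 0.0
        for ti in np.unique(t[e == 1]):
            at_risk = t >= ti
            n, n1 = at_risk.sum(), (at_risk & (g == 1)).sum()
            d = ((t == ti) & (e == 1)).sum()
            d1 = ((t == ti) & (e == 1) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / v
        res = logrank_test(g, t, e)
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-8)

    def test_power_under_strong_group_effect(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            g = np.repeat([0, 1], 200)
            t, e = exponential_survival(rng, np.log(3.0) * g, censor=55)
            rejections += logrank_test(g, t, e).p < 0.05
        assert rejections / n_rep > 0.9

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.zeros(4), np.arange(1.0, 5.0), np.ones(4, dtype=int))


class TestMaxSelectedCutpoint:
    def test_threshold_recovers_separated_hazard_clusters(self, rng):
        n = 200
        cluster = np.repeat([0, 1], n // 2)
        score = np.where(cluster == 1, rng.normal(5, 0.3, n), rng.normal(0, 0.3, n))
        t, e = exponential_survival(rng, 2.0 * cluster, censor=60)
        cp = max_selected_cutpoint(score, t, e)
        # the induced split must reproduce the true clusters (at most one
        # boundary sample may land on the wrong side of the scanned optimum)
        misclassified = ((score > cp.threshold) != (cluster == 1)).mean()
        assert misclassified <= 0.02

    def test_constant_scores_error(self, rng):
        t, e = exponential_survival(rng, np.zeros(30))
        with pytest.raises(ValidationError, match="admissible"):
            max_selected_cutpoint(np.ones(30), t, e)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_minprop_contract_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        score = rng.normal(size=n)
        t, e = exponential_survival(rng, score, censor=30)
        cp = max_selected_cutpoint(score, t, e, minprop=0.10)
        kmin = int(np.ceil(0.10 * n))
        assert cp.n_low >= kmin and cp.n_high >= kmin
        assert cp.n_low + cp.n_high == n

    def test_matches_independent_exhaustive_scan(self, rng):
        from pairstage.survstats import _two_group_logrank_z

        n = 60
        score = rng.normal(size=n)
        t, e = exponential_survival(rng, score, censor=25)
        cp = max_selected_cutpoint(score, t, e)
        # independent scan: every midpoint, statistic via the public log-rank op
        best_thr, best_stat = None, -1
        uniq = np.unique(score)
        for thr in (uniq[:-1] + uniq[1:]) / 2:
            lo = (score <= thr).sum()
            if min(lo, n - lo) < int(np.ceil(0.1 * n)):
                continue
            chi2 = logrank_test((score > thr).astype(int), t, e).statistic
            if np.sqrt(chi2) > best_stat + 1e-9:
                best_thr, best_stat = thr, np.sqrt(chi2)
        assert cp.threshold == pytest.approx(best_thr)
        assert cp.statistic == pytest.approx(best_stat, rel=1e-6)


class TestBHFDR:
    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_fdr(np.ones(5)), np.ones(5))

    def test_step_up_formula_oracle(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        q_direct = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        unperm = np.empty(40)
        unperm[perm] = q_perm
        np.testing.assert_allclose(q_direct, unperm)

    def test_q_at_least_p_and_discovery_count_monotone_in_alpha(self, rng):
        p = rng.uniform(size=60) ** 2
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        counts = [(q < a).sum() for a in np.linspace(0.01, 0.99, 25)]
        assert (np.diff(counts) >= 0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, np.nan])


class TestScreenGenes:
    def _cohort_with_one_informative_gene(self, rng, beta, n=500, n_noise=5):
        x = rng.normal(size=n)
        t, e = exponential_survival(rng, beta * x, censor=40)
        genes = {"target": x}
        for i in range(n_noise):
            genes[f"noise{i}"] = rng.normal(size=n)
        expr = pd.DataFrame(genes).T
        expr.columns = [f"s{i}" for i in range(n)]
        return expr, t, e

    def test_strong_gene_nearly_always_passes(self, rng):
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            expr, t, e = self._cohort_with_one_informative_gene(rng, beta=1.5)
            res = screen_genes(expr, t, e, p_threshold=0.01)
            hits += bool(res.loc["target", "passed"])
        assert hits / n_rep >= 0.95

    def test_null_gene_rarely_passes_union_rule(self, rng):
        # union of two ~1% tests on the same data: dependent, should stay < 5%
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 200
            x = rng.normal(size=n)
            t, e = exponential_survival(rng, np.zeros(n), censor=30)
            expr = pd.DataFrame({"g": x}).T
            expr.columns = [f"s{i}" for i in range(n)]
            res = screen_genes(expr, t, e, p_threshold=0.01)
            hits += bool(res["passed"].iloc[0])
        assert hits / n_rep < 0.05

    def test_zero_threshold_passes_nothing(self, rng):
        expr, t, e = self._cohort_with_one_informative_gene(rng, beta=2.0)
        res = screen_genes(expr, t, e, p_threshold=0.0)
        assert not res["passed"].any()

    def test_constant_gene_skipped_with_warning(self, rng):
        expr, t, e = self._cohort_with_one_informative_gene(rng, beta=1.0)
        expr.loc["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            res = screen_genes(expr, t, e)
        assert "flat" not in res.index

    def test_intersection_rule_stricter_than_union(self, rng):
        expr, t, e = self._cohort_with_one_informative_gene(rng, beta=0.4, n=300)
        union = screen_genes(expr, t, e, p_threshold=0.2, rule="union")
        inter = screen_genes(expr, t, e, p_threshold=0.2, rule="intersection")
        assert inter["passed"].sum() <= union["passed"].sum()
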