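"""Association engine: null model, score summaries, burden/SKAT/SKAT-O,
single-variant scan, leave-one-out and conditional analyses."""

import numpy as np
import pytest
from scipy import stats

from raremet.assoc import (
    DEFAULT_RHO_GRID,
    _exact_quantile,
    _rho_lambdas,
    beta_maf_weights,
    burden_test,
    conditional_test,
    fit_null,
    leave_one_out,
    score_summary,
    single_variant_scan,
    skat_test,
    skato_test,
)
from raremet.datamodel import CohortDataset, VariantRecord
from raremet.quadform import pvalue_quadform


def _toy_genotypes(rng, n, m, maf_low=0.01, maf_high=0.05):
    maf = rng.uniform(maf_low, maf_high, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    return G, maf


def _summary(U, V):
    from raremet.assoc import ScoreSummary

    m = len(U)
    return ScoreSummary("g", "t", "LoF", [f"v{i}" for i in range(m)], U, V, 100)


class TestFitNull:
    def test_intercept_only_residuals_are_centred(self, rng):
        y = rng.normal(3.0, 1.0, 40)
        null = fit_null(y)
        np.testing.assert_allclose(null.residuals, y - y.mean(), atol=1e-12)

    def test_exact_fit_gives_zero_sigma2(self, rng):
        X = rng.normal(size=(30, 1))
        y = 2.0 + 3.0 * X[:, 0]
        null = fit_null(y, X)
        assert null.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_ols_recovers_coefficients_within_3se(self, rng):
        n = 500
        X = rng.normal(size=(n, 2))
        beta = np.array([0.5, -1.2])
        y = 1.0 + X @ beta + rng.normal(size=n)
        null = fit_null(y, X)
        # independent oracle: lstsq fit with standard errors
        Xf = np.column_stack([np.ones(n), X])
        bhat, res, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        cov = np.linalg.inv(Xf.T @ Xf) * null.sigma2
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(bhat - np.array([1.0, *beta])) < 3 * se)
        np.testing.assert_allclose(
            null.residuals, y - Xf @ bhat, atol=1e-9
        )

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_null(rng.normal(size=3), rng.normal(size=(3, 3)))

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(200, 4))
        null = fit_null(rng.normal(size=200), X)
        assert np.abs(null.design.T @ null.residuals).max() < 1e-8


class TestScoreSummary:
    def test_orthogonal_variant_scores_zero(self, rng):
        n = 50
        null = fit_null(rng.normal(size=n))
        g = np.ones((n, 1))  # collinear with intercept: projects to zero
        s = score_summary(null, g, np.ones(1), ["v0"])
        assert s.U[0] == pytest.approx(0.0, abs=1e-10)

    def test_covariance_matches_permutation_oracle(self, rng):
        """V equals the empirical covariance of U over residual permutations."""
        n, m = 100, 5
        G, maf = _toy_genotypes(rng, n, m, 0.05, 0.2)
        y = rng.normal(size=n)
        null = fit_null(y)
        w = beta_maf_weights(maf)
        s = score_summary(null, G, w, [f"v{i}" for i in range(m)])
        n_perm = 200_000
        R = np.stack([rng.permutation(null.residuals) for _ in range(n_perm)], axis=1)
        Gt = null.project(G)
        Us = (w[:, None] * (Gt.T @ R)) / null.sigma2  # m x n_perm
        V_emp = np.cov(Us)
        se = np.sqrt(
            (np.outer(np.diag(s.V), np.diag(s.V)) + s.V**2) / n_perm
        )
        assert np.all(np.abs(V_emp - s.V) <= 3 * se + 1e-9)

    def test_missing_dosages_mean_imputed(self, rng):
        n = 80
        null = fit_null(rng.normal(size=n))
        g = rng.binomial(2, 0.2, size=(n, 1)).astype(float)
        g_missing = g.copy()
        g_missing[:10, 0] = np.nan
        s = score_summary(null, g_missing, np.ones(1), ["v0"])
        manual = g_missing.copy()
        manual[:10, 0] = np.nanmean(g_missing)
        s2 = score_summary(null, manual, np.ones(1), ["v0"])
        assert s.U[0] == pytest.approx(s2.U[0])


class TestBurden:
    def test_closed_form_identity_V(self):
        res = burden_test(_summary(np.array([1.0, 1.0]), np.eye(2)))
        assert res.q_stat == pytest.approx(2.0)
        assert res.p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
        assert res.p == pytest.approx(0.1573, abs=1e-4)
        assert res.rho_opt == 1.0

    def test_weight_rescaling_leaves_p_unchanged(self, rng):
        n, m = 200, 4
        G, maf = _toy_genotypes(rng, n, m)
        null = fit_null(rng.normal(size=n))
        w = beta_maf_weights(maf)
        p1 = burden_test(score_summary(null, G, w, list("abcd"))).p
        p2 = burden_test(score_summary(null, G, 2.0 * w, list("abcd"))).p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_equals_score_form_of_nested_ols_comparison(self, rng):
        """Burden p equals the score-test p of adding the weighted allele
        count to the covariate regression (restricted-vs-full RSS identity)."""
        n = 300
        X = rng.normal(size=(n, 2))
        G, maf = _toy_genotypes(rng, n, 6)
        w = beta_maf_weights(maf)
        y = rng.normal(size=n) + 0.05 * (G @ w)
        null = fit_null(y, X)
        res = burden_test(score_summary(null, G, w, [f"v{i}" for i in range(6)]))
        burden_score = G @ w
        Xr = np.column_stack([np.ones(n), X])
        Xfull = np.column_stack([Xr, burden_score])
        rss_r = y @ y - y @ Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
        rss_f = y @ y - y @ Xfull @ np.linalg.lstsq(Xfull, y, rcond=None)[0]
        z2 = (rss_r - rss_f) / (rss_r / (n - Xr.shape[1]))
        assert res.q_stat == pytest.approx(z2, abs=1e-6)
        assert res.p == pytest.approx(stats.chi2.sf(z2, 1), abs=1e-9)

    def test_monomorphic_mask_flagged_untestable(self):
        res = burden_test(_summary(np.zeros(2), np.zeros((2, 2))))
        assert np.isnan(res.p)
        assert "untestable" in res.notes


class TestSkat:
    def test_single_variant_equals_burden(self, rng):
        n = 150
        G, maf = _toy_genotypes(rng, n, 1)
        null = fit_null(rng.normal(size=n))
        s = score_summary(null, G, beta_maf_weights(maf), ["v0"])
        assert skat_test(s).p == pytest.approx(burden_test(s).p, abs=1e-12)
        assert skato_test(s).p == pytest.approx(burden_test(s).p, abs=1e-12)

    def test_identity_covariance_closed_form(self):
        res = skat_test(_summary(np.array([1.0, 1.0]), np.eye(2)))
        assert res.p == pytest.approx(stats.chi2.sf(2.0, 2), abs=1e-9)
        assert res.p == pytest.approx(0.3679, abs=1e-4)

    def test_matches_quadratic_form_monte_carlo(self, rng):
        n, m = 250, 4
        G, maf = _toy_genotypes(rng, n, m, 0.02, 0.1)
        y = rng.normal(size=n)
        null = fit_null(y)
        s = score_summary(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        res = skat_test(s)
        lam = np.linalg.eigvalsh(s.V)
        lam = lam[lam > 1e-10 * lam.max()]
        draws = (rng.chisquare(1, size=(10**6, lam.size)) * lam).sum(axis=1)
        mc = float((draws > res.q_stat).mean())
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert abs(res.p - mc) <= 3 * se


class TestSkatO:
    def test_grid_collapse_is_exact(self, rng):
        n, m = 200, 5
        G, maf = _toy_genotypes(rng, n, m)
        null = fit_null(rng.normal(size=n) + 0.2 * G[:, 0])
        s = score_summary(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        assert skato_test(s, rho_grid=[1.0]).p == burden_test(s).p
        assert skato_test(s, rho_grid=[0.0]).p == skat_test(s).p

    def test_omnibus_between_minp_and_bonferroni(self, rng):
        n, m = 300, 5
        G, maf = _toy_genotypes(rng, n, m)
        null = fit_null(rng.normal(size=n) + 0.3 * G @ np.ones(m))
        s = score_summary(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        res = skato_test(s)
        d, E = np.linalg.eigh(s.V)
        Vs = (E * np.sqrt(np.clip(d, 0, None))) @ E.T
        rho_adj = np.minimum(np.array(DEFAULT_RHO_GRID), 0.999)
        q = (1 - rho_adj) * float(s.U @ s.U) + rho_adj * float(s.U.sum()) ** 2
        pmin = min(
            pvalue_quadform(qi, _rho_lambdas(Vs, r)) for qi, r in zip(q, rho_adj)
        )
        assert pmin - 1e-12 <= res.p <= min(pmin * len(DEFAULT_RHO_GRID), 1.0) + 1e-12

    def test_omnibus_matches_parametric_minp_simulation(self, rng):
        """The omnibus p equals the simulated probability that any grid
        statistic exceeds its own level-T quantile (T = observed min p)."""
        rng = np.random.default_rng(7)
        n, m = 300, 5
        G, maf = _toy_genotypes(rng, n, m)
        null = fit_null(rng.normal(size=n) + 0.4 * G[:, 0] + 0.25 * G[:, 1])
        s = score_summary(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        res = skato_test(s)
        d, E = np.linalg.eigh(s.V)
        Vs = (E * np.sqrt(np.clip(d, 0, None))) @ E.T
        rho_adj = np.minimum(np.array(DEFAULT_RHO_GRID), 0.999)
        lam_rho = [_rho_lambdas(Vs, r) for r in rho_adj]
        q_obs = (1 - rho_adj) * float(s.U @ s.U) + rho_adj * float(s.U.sum()) ** 2
        T = min(pvalue_quadform(qi, l) for qi, l in zip(q_obs, lam_rho))
        thresholds = np.array([_exact_quantile(T, l, accuracy=1e-6) for l in lam_rho])
        n_sim = 10**5
        Z = rng.multivariate_normal(np.zeros(m), s.V, size=n_sim)
        Qs = np.stack(
            [(1 - r) * np.sum(Z * Z, axis=1) + r * Z.sum(axis=1) ** 2 for r in rho_adj],
            axis=1,
        )
        mc = float((Qs >= thresholds[None, :]).any(axis=1).mean())
        se = np.sqrt(mc * (1 - mc) / n_sim)
        assert abs(res.p - mc) <= 3 * se

    def test_zero_weight_noise_variant_changes_nothing(self, rng):
        n, m = 200, 4
        G, maf = _toy_genotypes(rng, n, m)
        noise = rng.binomial(2, 0.1, size=(n, 1)).astype(float)
        null = fit_null(rng.normal(size=n) + 0.3 * G[:, 0])
        w = beta_maf_weights(maf)
        ids = [f"v{i}" for i in range(m)]
        base = score_summary(null, G, w, ids)
        ext = score_summary(
            null, np.column_stack([G, noise]), np.append(w, 0.0), ids + ["noise"]
        )
        for test in (burden_test, skat_test, skato_test):
            assert test(ext).p == pytest.approx(test(base).p, abs=1e-12)


class TestPermutationConcordance:
    def test_skat_analytic_vs_permutation_p(self, rng):
        """On a small sample the analytic SKAT p agrees with a residual-
        permutation p within Monte-Carlo error."""
        n, m = 150, 5
        G, maf = _toy_genotypes(rng, n, m, 0.03, 0.15)
        y = rng.normal(size=n) + 0.25 * G[:, 0]
        null = fit_null(y)
        w = beta_maf_weights(maf)
        s = score_summary(null, G, w, [f"v{i}" for i in range(m)])
        res = skat_test(s)
        n_perm = 100_000
        Gt = null.project(G)
        R = np.stack([rng.permutation(null.residuals) for _ in range(n_perm)], axis=1)
        Us = (w[:, None] * (Gt.T @ R)) / null.sigma2
        q_perm = np.sum(Us * Us, axis=0)
        p_perm = float((q_perm >= res.q_stat).mean())
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / n_perm)
        assert abs(res.p - p_perm) <= 3 * se + 1e-4


class TestSingleVariantScan:
    @staticmethod
    def _dataset(G):
        n, m = G.shape
        variants = [VariantRecord(f"1:{j+1}:A:C", "1", j + 1, "A", "C") for j in range(m)]
        ds = CohortDataset("c", [f"S{i}" for i in range(n)], variants, G)
        ds.recompute_allele_stats()
        return ds

    def test_null_pvalues_uniform(self, rng):
        n, m = 500, 1000
        G = rng.binomial(2, 0.2, size=(n, m)).astype(float)
        null = fit_null(rng.normal(size=n))
        res = single_variant_scan(null, self._dataset(G))
        ps = np.array([r.p for r in res if not np.isnan(r.p)])
        stat = stats.kstest(ps, "uniform").statistic
        assert stat < 0.05

    def test_injected_effect_detected(self, rng):
        n = 1000
        ps = []
        for _ in range(30):
            g = rng.binomial(2, 0.05, size=(n, 1)).astype(float)
            y = rng.normal(size=n) + 1.0 * g[:, 0]
            null = fit_null(y)
            ps.append(single_variant_scan(null, self._dataset(g))[0].p)
        assert np.median(ps) < 1e-4

    def test_monomorphic_skipped_and_collinear_p_one(self, rng):
        n = 100
        x = rng.normal(size=(n, 1))
        g_mono = np.zeros((n, 1))
        null = fit_null(rng.normal(size=n), x)
        res = single_variant_scan(null, self._dataset(g_mono))
        assert res[0].flag == "monomorphic" and np.isnan(res[0].p)
        # variant identical to a covariate column
        res2 = single_variant_scan(null, self._dataset(x.copy()))
        assert res2[0].p == pytest.approx(1.0)


class TestLeaveOneOut:
    def test_planted_driver_identified(self):
        rng = np.random.default_rng(2)
        n, m = 600, 6
        G, maf = _toy_genotypes(rng, n, m, 0.02, 0.05)
        y = rng.normal(size=n) + 1.0 * G[:, 2]
        null = fit_null(y)
        res = leave_one_out(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        assert res.driven_by_single
        assert res.driver_id == "v2"

    def test_spread_signal_not_single_driver(self, rng):
        n, m = 800, 8
        G, maf = _toy_genotypes(rng, n, m, 0.03, 0.08)
        y = rng.normal(size=n) + 0.45 * G.sum(axis=1)
        null = fit_null(y)
        res = leave_one_out(null, G, beta_maf_weights(maf), [f"v{i}" for i in range(m)])
        assert not res.driven_by_single

    def test_duplicated_causal_variant_is_redundant(self, rng):
        n = 600
        g = rng.binomial(2, 0.05, size=(n, 1)).astype(float)
        G = np.column_stack([g, g, rng.binomial(2, 0.03, size=(n, 2))]).astype(float)
        y = rng.normal(size=n) + 1.0 * g[:, 0]
        null = fit_null(y)
        res = leave_one_out(null, G, np.ones(4), list("abcd"))
        assert not res.driven_by_single

    def test_single_variant_mask_degenerate(self, rng):
        n = 200
        g = rng.binomial(2, 0.05, size=(n, 1)).astype(float)
        null = fit_null(rng.normal(size=n))
        res = leave_one_out(null, g, np.ones(1), ["only"])
        assert res.degenerate and res.driven_by_single


class TestConditional:
    def test_empty_conditioning_identical(self, rng):
        n, m = 300, 4
        G, maf = _toy_genotypes(rng, n, m)
        y = rng.normal(size=n) + 0.3 * G[:, 0]
        w = beta_maf_weights(maf)
        ids = [f"v{i}" for i in range(m)]
        a = conditional_test(y, None, G, w, ids, None, test="skato")
        null = fit_null(y)
        b = skato_test(score_summary(null, G, w, ids))
        assert a.p == pytest.approx(b.p, rel=1e-10)

    def test_conditioning_on_causal_variant_removes_signal(self, rng):
        n = 800
        g_causal = rng.binomial(2, 0.04, size=n).astype(float)
        G = np.column_stack([g_causal, rng.binomial(2, 0.03, size=(n, 3))]).astype(float)
        y = rng.normal(size=n) + 1.0 * g_causal
        w = np.ones(4)
        ids = list("abcd")
        uncond = conditional_test(y, None, G, w, ids, None, test="burden")
        cond = conditional_test(y, None, G, w, ids, g_causal[:, None], test="burden")
        assert uncond.p < 1e-4
        assert cond.p > 0.05

    def test_conditioning_on_independent_variant_is_mild(self, rng):
        n = 500
        deltas = []
        for _ in range(50):
            G, maf = _toy_genotypes(rng, n, 4)
            extra = rng.binomial(2, 0.1, size=(n, 1)).astype(float)
            y = rng.normal(size=n) + 0.25 * G.sum(axis=1)
            ids = list("abcd")
            p0 = conditional_test(y, None, G, np.ones(4), ids, None, test="burden").p
            p1 = conditional_test(y, None, G, np.ones(4), ids, extra, test="burden").p
            deltas.append(abs(np.log(p1) - np.log(p0)) / abs(np.log(p0)))
        assert np.median(deltas) < 0.10

    def test_collinear_conditioning_column_dropped_with_warning(self, rng):
        n = 200
        G, maf = _toy_genotypes(rng, n, 3)
        y = rng.normal(size=n)
        with pytest.warns(UserWarning, match="collinear"):
            res = conditional_test(
                y, None, G, np.ones(3), list("abc"), np.ones((n, 1)), test="burden"
            )
        assert 0 < res.p <= 1
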