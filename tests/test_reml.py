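"""REML and BLUP: oracle equivalence, ratios, grids, degenerate cases."""

import numpy as np
import pytest
from scipy import stats

from rumenblup import (
    ModelSpec,
    fit_mixed_model,
    model_grid,
    restricted_log_likelihood,
    variance_ratios,
)
from rumenblup.reml import FitResult, estimate_orf_heritabilities

from conftest import random_psd


def contrast_logpdf(y, X, V):
    """Independent oracle: density of error contrasts A'y with A'X=0, A'A=I."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    A = Q[:, p:]  # orthonormal basis of the complement of span(X)
    z = A.T @ y
    return stats.multivariate_normal(mean=np.zeros(n - p), cov=A.T @ V @ A).logpdf(z)


def grid_direction_oracle(y, X, Ks, ngrid=50, return_argmax=False):
    """Direct optimizer: grid over variance-fraction directions with the
    overall scale profiled out in closed form.  The grid coordinates are
    the variance fractions themselves, so the argmax doubles as an
    oracle for the fitted ratios."""
    n, p = X.shape
    best, arg = -np.inf, None
    rs = np.linspace(0.0, 0.98, ngrid)
    for r1 in rs:
        for r2 in rs if len(Ks) > 1 else [0.0]:
            if r1 + r2 >= 0.999:
                continue
            V0 = r1 * Ks[0] + (1 - r1 - r2) * np.eye(n)
            if len(Ks) > 1:
                V0 = V0 + r2 * Ks[1]
            try:
                L = np.linalg.cholesky(V0)
            except np.linalg.LinAlgError:
                continue
            Vinv = np.linalg.inv(V0)
            XtVX = X.T @ Vinv @ X
            beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
            ypy = y @ Vinv @ y - (X.T @ Vinv @ y) @ beta
            s = ypy / (n - p)
            ll = -0.5 * (
                2 * np.log(np.diag(L)).sum()
                + np.linalg.slogdet(XtVX)[1]
                + (n - p) * np.log(s)
                + (n - p)
            )
            if ll > best:
                best, arg = ll, (r1, r2)
    if return_argmax:
        return best, arg
    return best


class TestRestrictedLogLikelihood:
    def test_matches_contrast_density_differences(self, rng):
        # logL differences across component values must match the exact
        # error-contrast density (shared constants cancel)
        n = 8
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        K = random_psd(n, rng, jitter=0.01)
        y = rng.standard_normal(n)
        s_a, s_b = [0.7, 0.5], [1.3, 0.2]
        d_impl = restricted_log_likelihood(y, X, [K], s_a) - restricted_log_likelihood(
            y, X, [K], s_b
        )
        V_a = s_a[0] * K + s_a[1] * np.eye(n)
        V_b = s_b[0] * K + s_b[1] * np.eye(n)
        d_oracle = contrast_logpdf(y, X, V_a) - contrast_logpdf(y, X, V_b)
        assert d_impl == pytest.approx(d_oracle, abs=1e-8)

    def test_scale_equivariance(self, rng):
        # scaling y by c and variances by c^2 shifts logL by -(n-p) log c
        n, c = 10, 3.0
        X = np.ones((n, 1))
        K = random_psd(n, rng, jitter=0.01)
        y = rng.standard_normal(n)
        base = restricted_log_likelihood(y, X, [K], [0.5, 0.8])
        scaled = restricted_log_likelihood(c * y, X, [K], [0.5 * c**2, 0.8 * c**2])
        assert scaled - base == pytest.approx(-(n - 1) * np.log(c), abs=1e-8)

    def test_rank_deficient_design_refused(self, rng):
        n = 6
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank deficient"):
            restricted_log_likelihood(rng.standard_normal(n), X, [np.eye(n)], [1, 1])


class TestFitMixedModel:
    def test_oracle_equivalence_small_instances(self, rng):
        # AI-REML optimum vs a dense direction grid with profiled scale
        for inst in range(10):
            r = np.random.default_rng(500 + inst)
            n = int(r.integers(20, 31))
            n_k = int(r.integers(1, 3))
            Ks = [random_psd(n, r, jitter=0.001) for _ in range(n_k)]
            X = np.column_stack([np.ones(n), r.standard_normal(n)])
            theta = r.uniform(0.2, 1.0, n_k + 1)
            V = sum(t * K for t, K in zip(theta, Ks)) + theta[-1] * np.eye(n)
            y = X @ [1.0, 0.5] + np.linalg.cholesky(V) @ r.standard_normal(n)
            fit = fit_mixed_model(y, X, Ks)
            best = grid_direction_oracle(y, X, Ks)
            assert fit.loglik >= best - 1e-4

    def test_constant_phenotype_hits_zero_boundary(self, rng):
        n = 25
        K = random_psd(n, rng, jitter=0.01)
        y = np.full(n, 3.14)
        fit = fit_mixed_model(y, np.ones((n, 1)), [K])
        assert fit.components["u"] == pytest.approx(0.0, abs=1e-10)
        assert "u" in fit.boundary

    def test_single_component_recovery(self):
        # h2 = 0.5 with a strong kernel: estimate lands near truth
        ests = []
        for seed in range(20):
            r = np.random.default_rng(900 + seed)
            n = 300
            Q = r.binomial(2, r.uniform(0.1, 0.5, 400), size=(n, 400))
            from rumenblup import build_grm, tune

            G = tune(build_grm(Q))
            L = np.linalg.cholesky(G.values)
            u = np.sqrt(0.5) * (L @ r.standard_normal(n))
            y = 2.0 + u + np.sqrt(0.5) * r.standard_normal(n)
            fit = fit_mixed_model(y, np.ones((n, 1)), [G])
            ests.append(fit.ratios["h2"])
            assert abs(ests[-1] - 0.5) < 0.15
        assert abs(np.median(ests) - 0.5) < 0.05

    def test_identity_kernel_flagged_unidentifiable(self, rng):
        n = 15
        y = rng.standard_normal(n)
        fit = fit_mixed_model(y, np.ones((n, 1)), [np.eye(n)])
        assert not fit.identifiable

    def test_blup_matches_conditional_expectation(self, rng):
        # masked animals: BLUP equals K_test,train V_train^-1 (y - X beta)
        N = 20
        K = random_psd(N, rng, jitter=0.01)
        train = np.arange(15)
        X = np.ones((15, 1))
        y = rng.standard_normal(15) + 2.0
        fit = fit_mixed_model(y, X, [K], phenotyped=train)
        s_u, s_e = fit.components["u"], fit.components["e"]
        V = s_u * K[np.ix_(train, train)] + s_e * np.eye(15)
        resid = y - X @ fit.beta
        expected = s_u * K[15:, :15] @ np.linalg.solve(V, resid)
        np.testing.assert_allclose(fit.blup["u"][15:], expected, atol=1e-8)

    def test_aic_ordering_invariant_to_scaling(self, rng):
        n = 40
        K1 = random_psd(n, rng, jitter=0.01)
        K2 = random_psd(n, rng, jitter=0.01)
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        fits = [fit_mixed_model(y, X, [K]) for K in (K1, K2)]
        fits_sc = [fit_mixed_model(5 * y, X, [K]) for K in (K1, K2)]
        d = fits[0].aic - fits[1].aic
        d_sc = fits_sc[0].aic - fits_sc[1].aic
        assert d == pytest.approx(d_sc, abs=1e-4)


class TestVarianceRatios:
    def make_fit(self, comps, names):
        return FitResult(
            components=comps, se={}, beta=np.zeros(1), blup={},
            loglik=0.0, aic=0.0, converged=True, n_iter=1,
            effect_names=names,
        )

    def test_arithmetic(self):
        fit = self.make_fit({"u": 3.0, "m": 1.0, "e": 6.0}, ("u", "m"))
        r = variance_ratios(fit)
        assert r == pytest.approx({"h2": 0.3, "m2": 0.1, "i_a2": 0.4})

    def test_genomic_only_domain(self):
        fit = self.make_fit({"u": 1.0, "e": 1.0}, ("u",))
        r = variance_ratios(fit)
        assert set(r) == {"h2"}

    def test_zero_interaction_collapses(self):
        fit = self.make_fit({"u": 2.0, "m": 1.0, "o": 0.0, "e": 1.0}, ("u", "m", "o"))
        r = variance_ratios(fit)
        assert r["i_i2"] == pytest.approx(r["i_a2"])

    def test_all_zero_refused(self):
        fit = self.make_fit({"u": 0.0, "e": 0.0}, ("u",))
        with pytest.raises(ZeroDivisionError):
            variance_ratios(fit)


class TestModelGrid:
    def test_one_trait_yields_19(self):
        assert len(model_grid(["ADDMI"])) == 19

    def test_two_traits_yield_38(self):
        assert len(model_grid(["ADDMI", "ADG"])) == 38

    def test_naive_only_yields_7(self):
        assert len(model_grid(["ADDMI"], adjustments=("naive",))) == 7

    def test_deterministic_order(self):
        a = [s.label for s in model_grid(["ADDMI", "ADG"])]
        b = [s.label for s in model_grid(["ADDMI", "ADG"])]
        assert a == b

    def test_interaction_requires_both_kernels(self):
        with pytest.raises(ValueError):
            ModelSpec("ADG", "interaction")
        spec = ModelSpec("ADG", "interaction", 1, "naive")
        assert spec.effects == ("u", "m", "o")


class TestORFHeritabilities:
    def test_eigen_path_matches_ai_reml(self, small_study, small_design):
        from rumenblup import build_grm, log_relative_abundance, tune

        G_T = tune(build_grm(small_study.genotypes))
        S = log_relative_abundance(small_study.orf_counts)
        X = small_design.to_numpy(float)
        h2 = estimate_orf_heritabilities(S.iloc[:, :5], G_T, X)
        for j in range(5):
            fit = fit_mixed_model(S.to_numpy()[:, j], X, [G_T])
            h2_ai = fit.components["u"] / (fit.components["u"] + fit.components["e"])
            assert h2[j] == pytest.approx(h2_ai, abs=2e-3)

    def test_null_orf_near_zero(self, rng):
        from rumenblup import build_grm, tune

        ests = []
        for seed in range(10):
            r = np.random.default_rng(700 + seed)
            n = 150
            Q = r.binomial(2, r.uniform(0.1, 0.5, 200), size=(n, 200))
            G_T = tune(build_grm(Q))
            y = r.standard_normal((n, 1))  # no genetic signal
            h2 = estimate_orf_heritabilities(y, G_T, np.ones((n, 1)))
            ests.append(h2[0])
        assert np.median(ests) < 0.05

    def test_heritable_orf_recovered(self):
        from rumenblup import build_grm, tune

        ests = []
        for seed in range(10):
            r = np.random.default_rng(800 + seed)
            n = 400
            Q = r.binomial(2, r.uniform(0.1, 0.5, 500), size=(n, 500))
            G_T = tune(build_grm(Q))
            L = np.linalg.cholesky(G_T.values)
            y = np.sqrt(0.6) * (L @ r.standard_normal(n)) + np.sqrt(0.4) * r.standard_normal(n)
            h2 = estimate_orf_heritabilities(y[:, None], G_T, np.ones((n, 1)))
            ests.append(h2[0])
        assert abs(np.median(ests) - 0.6) < 0.1

    def test_constant_column_zero(self, small_study, small_design):
        from rumenblup import build_grm, tune

        G_T = tune(build_grm(small_study.genotypes))
        col = np.full((len(small_design), 1), 1.5)
        h2 = estimate_orf_heritabilities(col, G_T, small_design.to_numpy(float))
        assert h2[0] == 0.0

    def test_untuned_kernel_refused(self, small_study, small_design):
        from rumenblup import build_grm

        G = build_grm(small_study.genotypes)
        with pytest.raises(ValueError, match="tuned"):
            estimate_orf_heritabilities(
                np.zeros((len(small_design), 1)), G, small_design.to_numpy(float)
            )
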