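"""Two-step polychoric machinery and the DWLS fit."""

import numpy as np
import pytest
from scipy import stats

from ordsem._bvn import bvn_cdf, cell_probs
from ordsem.csa_wlsmv import (
    PAIRS,
    CsaDwls,
    asy_diag,
    estimate_thresholds,
    fit_dwls,
    implied_polychoric_structure,
    polychoric_pair,
    polychoric_summary,
    _DwlsParamMap,
)
from ordsem.model import implied_indicator_cov, truth_table
from ordsem.ordinal import OrdinalDataset, discretize, generate_continuous, threshold_set


class TestBvnCdf:
    def test_against_scipy_oracle(self, rng):
        for rho in (-0.9, -0.3, 0.0, 0.56, 0.95):
            mvn = stats.multivariate_normal(cov=[[1, rho], [rho, 1]])
            pts = rng.normal(scale=1.5, size=(25, 2))
            pts[0] = [0.0, 0.0]
            pts[1] = [0.0, -1.3]
            got = bvn_cdf(pts[:, 0], pts[:, 1], rho)
            want = mvn.cdf(pts)
            assert np.max(np.abs(got - want)) < 1e-10


class TestThresholds:
    def test_quantile_arithmetic(self):
        col = np.repeat([1, 2, 3, 4], 25)
        tau, collapsed = estimate_thresholds(col, 4)
        assert not collapsed
        assert np.allclose(tau, stats.norm.ppf([0.25, 0.5, 0.75]))
        assert tau[1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(tau) > 0)

    def test_empty_extreme_category_collapsed(self):
        col = np.repeat([2, 3, 4], [10, 20, 10])  # category 1 unobserved
        tau, collapsed = estimate_thresholds(col, 4)
        assert collapsed
        assert tau.size == 2
        assert np.all(np.diff(tau) > 0)


class TestPolychoricPair:
    def test_independence_table(self):
        tau = np.array([-0.5, 0.5])
        marg = np.diff(np.concatenate(([0], stats.norm.cdf(tau), [1])))
        table = 1000.0 * np.outer(marg, marg)
        rho, at_bound = polychoric_pair(table, tau, tau)
        assert rho == pytest.approx(0.0, abs=1e-5)
        assert not at_bound

    def test_grid_search_oracle(self):
        """rho-hat equals the brute-force argmax of the likelihood."""
        table = np.array([[40.0, 16, 4], [18, 50, 22], [6, 20, 44]])
        tau = np.array([-0.6, 0.7])
        rho, _ = polychoric_pair(table, tau, tau)
        grid = np.arange(-0.999, 0.999, 1e-4)
        ll = np.empty(grid.size)
        for g, r in enumerate(grid):
            p = np.clip(cell_probs(tau, tau, r), 1e-12, None)
            ll[g] = np.sum(table * np.log(p))
        assert rho == pytest.approx(grid[np.argmax(ll)], abs=2e-4)

    def test_recovers_known_latent_correlation(self):
        """Simulation oracle: 0.56 = 0.8 x 0.7 within-block correlation."""
        rng = np.random.default_rng(12)
        n = 1_000_000
        x = rng.standard_normal(n)
        y = 0.56 * x + np.sqrt(1 - 0.56**2) * rng.standard_normal(n)
        ts = threshold_set(5, "symmetric")
        tau = np.asarray(ts.tau)
        cx = np.searchsorted(tau, x)
        cy = np.searchsorted(tau, y)
        table = np.zeros((5, 5))
        np.add.at(table, (cx, cy), 1.0)
        rho, _ = polychoric_pair(table, tau, tau)
        assert rho == pytest.approx(0.56, abs=0.01)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            polychoric_pair(np.array([[10.0, 0], [0, 0]]), np.zeros(1), np.zeros(1))


class TestAsyDiag:
    def test_variances_shrink_like_one_over_n(self, population):
        _, params = population
        ts = threshold_set(4, "symmetric")
        out = {}
        for n in (2000, 8000):
            ds = discretize(generate_continuous(params, n, seed=21), ts)
            out[n] = asy_diag(ds, polychoric_summary(ds))
        ratio = out[2000] / out[8000]
        assert 3.5 < np.median(ratio) < 4.5
        assert np.all(out[2000] > 0) and np.all(np.isfinite(out[2000]))

    def test_matches_monte_carlo_variability(self, population):
        """Empirical sampling variance of tau-hat and rho-hat over replications."""
        _, params = population
        ts = threshold_set(4, "symmetric")
        taus, rhos = [], []
        for r in range(150):
            ds = discretize(generate_continuous(params, 1500, seed=400 + r), ts)
            tau, _ = estimate_thresholds(ds.values[:, 0], 4)
            taus.append(tau)
            summary = None
            if r < 60:  # full summaries are costlier; 60 suffice for rho
                summary = polychoric_summary(ds)
                rhos.append(summary.rho[0])
        ds = discretize(generate_continuous(params, 1500, seed=999), ts)
        pred = asy_diag(ds, polychoric_summary(ds))
        emp_tau = np.var(np.array(taus), axis=0, ddof=1)
        assert np.all(np.abs(emp_tau / pred[:3] - 1) < 0.35)
        emp_rho = np.var(rhos, ddof=1)
        rho_pred = pred[20 * 3]  # first correlation entry after 20x3 thresholds
        assert emp_rho / rho_pred == pytest.approx(1.0, abs=0.5)


class TestImpliedStructure:
    def test_population_consistency(self, population):
        spec, params = population
        pmap = _DwlsParamMap(spec)
        x = np.empty(pmap.size)
        x[:20] = params.loading_values
        x[20:29] = [params.path_values[e] for e in pmap.edges]
        x[-1] = np.arctanh(params.phi)
        implied = implied_polychoric_structure(x, spec)
        want = implied_indicator_cov(params)[np.triu_indices(20, k=1)]
        assert np.allclose(implied, want, atol=1e-12)

    def test_no_paths_no_cross_block_correlation(self, population):
        spec, _ = population
        pmap = _DwlsParamMap(spec)
        x = np.zeros(pmap.size)
        x[:20] = 0.7
        implied = implied_polychoric_structure(x, spec)
        R = np.eye(20)
        R[np.triu_indices(20, k=1)] = implied
        # endogenous-only blocks are uncorrelated without structural paths
        assert np.allclose(R[8:12, 12:16], 0.0)


class TestFitDwls:
    def test_analytic_input_identity_weights(self, population):
        spec, params = population
        rho_pop = implied_indicator_cov(params)[np.triu_indices(20, k=1)]
        fit = fit_dwls(rho_pop, np.ones(len(PAIRS)), spec)
        assert fit.converged and not fit.improper
        assert fit.fdwls_value < 1e-10
        est = fit.estimates()
        for key, value in truth_table(params).items():
            assert est[key] == pytest.approx(value, abs=1e-3), key

    def test_weight_scale_invariance(self, population):
        spec, params = population
        rng = np.random.default_rng(2)
        ds = discretize(generate_continuous(params, 500, rng), threshold_set(5, "symmetric"))
        summary = polychoric_summary(ds)
        w = asy_diag(ds, summary)[-len(PAIRS):]
        a = fit_dwls(summary.rho, w, spec)
        b = fit_dwls(summary.rho, 7.3 * w, spec)
        assert np.allclose(a.theta_hat, b.theta_hat, atol=1e-5)

    def test_gradient_vanishes_at_optimum(self, population):
        spec, params = population
        rho_pop = implied_indicator_cov(params)[np.triu_indices(20, k=1)]
        fit = fit_dwls(rho_pop, np.ones(len(PAIRS)), spec)
        pmap = _DwlsParamMap(spec)

        def obj(x):
            r = rho_pop - implied_polychoric_structure(x, spec, pmap)
            return float(r @ r)

        from scipy.optimize import approx_fprime

        g = approx_fprime(fit.theta_hat, obj, 1e-7)
        assert np.max(np.abs(g)) < 1e-4


class TestTwoStepInvariants:
    def test_polychoric_matrix_symmetric_unit_diagonal(self, population):
        _, params = population
        ds = discretize(generate_continuous(params, 400, seed=6), threshold_set(4, "symmetric"))
        R = polychoric_summary(ds).corr_matrix()
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.abs(R[np.triu_indices(20, 1)]) < 1)

    def test_row_permutation_invariance(self, population):
        _, params = population
        ds = discretize(generate_continuous(params, 300, seed=7), threshold_set(5, "symmetric"))
        perm = np.random.default_rng(1).permutation(300)
        ds2 = OrdinalDataset(ds.values[perm], ds.category_count, ds.shape_label)
        assert np.allclose(polychoric_summary(ds).rho, polychoric_summary(ds2).rho)

    def test_large_sample_loading_recovery(self, population):
        """Consistency of the full two-step pipeline at n = 100,000."""
        spec, params = population
        rng = np.random.default_rng(31)
        ds = discretize(generate_continuous(params, 100_000, rng), threshold_set(5, "symmetric"))
        model = CsaDwls(spec).fit(ds)
        assert model.status_ == "converged"
        for j, lam in enumerate(params.loading_values, start=1):
            assert model.estimates_[f"lam_i{j}"] == pytest.approx(lam, abs=0.02)
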