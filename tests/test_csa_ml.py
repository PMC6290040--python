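"""Maximum-likelihood engine: fit function, gradient, recovery, diagnostics."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from ordsem.csa_ml import (
    CsaMl,
    MlFit,
    _MlParamMap,
    detect_improper,
    fit_ml,
    fml,
    implied_cov,
    sample_cov,
    standardize_solution,
)
from ordsem.model import build_population_model, implied_indicator_cov, misspecify, truth_table
from ordsem.ordinal import OrdinalDataset, discretize, generate_continuous, threshold_set


class TestSampleCov:
    def test_hand_computed_two_columns(self):
        x = np.array([1.0, 2, 2, 3, 5])
        y = np.array([2.0, 1, 3, 4, 4])
        X = np.column_stack([x, y] + [np.arange(5) + j for j in range(18)])
        S = sample_cov(X)
        # hand arithmetic, denominator n-1 = 4
        sxy = float(((x - x.mean()) * (y - y.mean())).sum() / 4)
        assert S[0, 1] == pytest.approx(sxy)
        assert S[0, 0] == pytest.approx(float(((x - x.mean()) ** 2).sum() / 4))
        assert np.allclose(S, S.T)
        assert np.all(np.diag(S) >= 0)

    def test_constant_column_rejected(self):
        X = np.ones((10, 20))
        with pytest.raises(ValueError):
            sample_cov(X)


class TestFml:
    def test_identity_case_and_nonnegativity(self, rng):
        for _ in range(20):
            A = rng.normal(size=(6, 6))
            S = A @ A.T + 6 * np.eye(6)
            assert fml(S, S) == pytest.approx(0.0, abs=1e-10)
            B = rng.normal(size=(6, 6))
            Sigma = B @ B.T + 6 * np.eye(6)
            assert fml(S, Sigma) >= 0

    def test_two_by_two_hand_value(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        Sigma = np.array([[1.5, 0.2], [0.2, 1.2]])
        det = lambda M: M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        inv = np.array([[Sigma[1, 1], -Sigma[0, 1]], [-Sigma[1, 0], Sigma[0, 0]]]) / det(Sigma)
        hand = (
            np.log(det(Sigma))
            + (S[0, 0] * inv[0, 0] + 2 * S[0, 1] * inv[0, 1] + S[1, 1] * inv[1, 1])
            - np.log(det(S))
            - 2
        )
        assert fml(S, Sigma) == pytest.approx(hand, rel=1e-12)


class TestImpliedCov:
    def test_population_consistency(self, population):
        """Same algebra as the model module when fed the true values."""
        spec, params = population
        pmap = _MlParamMap(spec)
        x = np.empty(pmap.size)
        x[:20] = params.loading_values
        x[20:29] = [params.path_values[e] for e in pmap.edges]
        x[29] = np.arctanh(params.phi)
        x[30:33] = np.log(params.psi)
        x[33:] = np.log(params.uniqueness)
        assert np.allclose(implied_cov(x, spec), implied_indicator_cov(params), atol=1e-12)

    def test_no_structure_is_diagonal(self, population):
        spec, _ = population
        pmap = _MlParamMap(spec)
        x = np.zeros(pmap.size)  # loadings 0, paths 0, phi 0, variances 1
        assert np.allclose(implied_cov(x, spec), np.eye(20))


class TestFitMl:
    def test_analytic_input_recovery(self, population):
        spec, params = population
        S = implied_indicator_cov(params)
        fit = fit_ml(S, spec, n=10_000)
        assert fit.converged and not fit.improper
        assert fit.fml_value < 1e-8
        est = standardize_solution(fit)
        for key, value in truth_table(params).items():
            assert est[key] == pytest.approx(value, abs=1e-3), key

    def test_gradient_vanishes_at_optimum(self, population):
        spec, params = population
        S = implied_indicator_cov(params)
        fit = fit_ml(S, spec, n=10_000)
        pmap = _MlParamMap(spec)
        g = approx_fprime(fit.theta_hat, lambda x: fml(S, implied_cov(x, spec, pmap)), 1e-7)
        assert np.max(np.abs(g)) < 1e-4

    def test_small_sample_admissibility_rule(self, population):
        spec, params = population
        rng = np.random.default_rng(0)
        ds = discretize(generate_continuous(params, 50, rng), threshold_set(4, "symmetric"))
        fit = fit_ml(sample_cov(ds), spec, n=50)
        assert not fit.converged
        assert "exceed" in fit.reason

    def test_monte_carlo_consistency_paths(self, population):
        """Mean path estimates at n=1000 (symmetric, 7 categories) near truth."""
        spec, params = population
        ts = threshold_set(7, "symmetric")
        tt = truth_table(params)
        sums = {e: 0.0 for e in spec.path_edges}
        used = 0
        for r in range(200):
            rng = np.random.default_rng(3_000 + r)
            ds = discretize(generate_continuous(params, 1000, rng), ts)
            model = CsaMl(spec).fit(ds)
            if model.status_ != "converged":
                continue
            used += 1
            for e in spec.path_edges:
                sums[e] += model.estimates_[e]
        assert used > 150
        for e in spec.path_edges:
            assert sums[e] / used == pytest.approx(tt[e], abs=0.03), e


class TestDiagnostics:
    def test_detect_improper_definition(self, population):
        spec, _ = population
        pmap = _MlParamMap(spec)
        x = pmap.start(np.eye(20))
        good = MlFit(x, pmap, 0.0, 1, True, False)
        assert detect_improper(good) is False
        # drive one uniqueness onto the zero boundary (Heywood)
        bad = x.copy()
        bad[-1] = np.log(1e-9)
        assert detect_improper(MlFit(bad, pmap, 0.0, 1, True, False)) is True

    def test_standardization_hand_arithmetic(self, population):
        """Standardized loading = raw loading x latent sd / indicator sd.

        Also exercises the scale-indeterminacy ridge of the raw endogenous
        parameterization: rescaling an endogenous factor leaves the
        standardized solution unchanged.
        """
        spec, params = population
        pmap = _MlParamMap(spec)
        x = np.empty(pmap.size)
        x[:20] = params.loading_values
        x[20:29] = [params.path_values[e] for e in pmap.edges]
        x[29] = np.arctanh(params.phi)
        x[30:33] = np.log(params.psi)
        x[33:] = np.log(params.uniqueness)
        fit = MlFit(x, pmap, 0.0, 1, True, False)
        est = standardize_solution(fit)
        assert est["lam_i1"] == pytest.approx(0.8, abs=1e-12)
        # rescale eta1 by c = 2: loadings /2, incoming paths x2, outgoing /2,
        # psi1 x4 -- same implied covariance, same standardized solution
        c = 2.0
        y = x.copy()
        y[8:12] = x[8:12] / c          # eta1 block loadings
        y[20] = x[20] * c              # gamma11 (into eta1)
        y[21] = x[21] * c              # gamma12 (into eta1)
        y[26] = x[26] / c              # beta21 (eta1 -> eta2)
        y[27] = x[27] / c              # beta31 (eta1 -> eta3)
        y[30] = x[30] + 2 * np.log(c)  # log psi1
        fit2 = MlFit(y, pmap, 0.0, 1, True, False)
        assert np.allclose(implied_cov(y, spec), implied_cov(x, spec), atol=1e-12)
        est2 = standardize_solution(fit2)
        for key, value in est.items():
            assert est2[key] == pytest.approx(value, abs=1e-10), key

    def test_misspecified_fit_keys(self, population):
        spec, params = population
        mis = misspecify(spec)
        rng = np.random.default_rng(8)
        ds = discretize(generate_continuous(params, 500, rng), threshold_set(5, "symmetric"))
        model = CsaMl(mis).fit(ds)
        if model.status_ == "converged":
            paths = [k for k in model.estimates_ if k.startswith(("gamma", "beta"))]
            assert sorted(paths) == sorted(mis.path_edges)
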