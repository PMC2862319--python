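"""Yule-Walker solving, prediction-error covariance, BIC, model correlations."""

import numpy as np
import pytest

from spikemvar.examples import sequential_triple, unidirectional_pair
from spikemvar.lnp_simulator import simulate_gaussian
from spikemvar.mvar_core import (
    CorrSet,
    IllConditionedCorrelationError,
    MVARModel,
    bic_score,
    impulse_response,
    model_correlations,
    residual_covariance,
    select_order,
    solve_yule_walker,
)

from conftest import random_stable_model


def ar1_corrset(phi=0.5, K=5):
    """Exact autocovariance of x(n) = phi x(n-1) + w, unit innovation."""
    v = 1.0 / (1.0 - phi**2)
    return CorrSet(R=(v * phi ** np.arange(K + 1))[:, None, None], kind="gaussian")


class TestSolveYuleWalker:
    def test_ar1_analytic(self):
        model = solve_yule_walker(ar1_corrset(), 1)
        assert model.A[0, 0, 0] == pytest.approx(-0.5, abs=1e-12)
        assert model.Sigma[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_has_no_ar_structure(self):
        R = np.zeros((4, 3, 3))
        R[0] = np.diag([1.0, 2.0, 0.5])
        model = solve_yule_walker(CorrSet(R=R, kind="gaussian"), 1)
        assert np.allclose(model.A, 0.0)
        assert np.allclose(model.Sigma, R[0])

    def test_order_zero_returns_lag_zero_covariance(self):
        corr = ar1_corrset()
        model = solve_yule_walker(corr, 0)
        assert model.m == 0
        assert np.allclose(model.Sigma, corr.lag(0))

    def test_order_beyond_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            solve_yule_walker(ar1_corrset(K=2), 3)

    def test_singular_correlations_reported_with_condition_number(self):
        R = np.ones((3, 2, 2))  # perfectly duplicated channels
        with pytest.raises(IllConditionedCorrelationError, match="condition"):
            solve_yule_walker(CorrSet(R=R, kind="gaussian"), 2)

    @pytest.mark.parametrize("p,m", [(1, 1), (2, 2), (3, 3), (4, 2), (2, 4)])
    def test_round_trip_recovers_coefficients_exactly(self, rng, p, m):
        """model correlations -> Yule-Walker returns the generating model."""
        model = random_stable_model(rng, p, m)
        corr = model_correlations(model, K=m + 4)
        rec = solve_yule_walker(corr, m)
        assert np.allclose(rec.A, model.A, atol=1e-8)
        assert np.allclose(rec.Sigma, model.Sigma, atol=1e-8)

    def test_matches_least_squares_regression_on_simulated_series(self, rng):
        """Sign/orientation cross-check against a direct lag regression."""
        model = unidirectional_pair()
        x = simulate_gaussian(model, 200_000, rng).T  # (n, p)
        Y, Z = x[2:], np.hstack([x[1:-1], x[:-2]])
        beta, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        B_ls = np.stack([beta[:2].T, beta[2:].T])
        corr, _ = _empirical_corr(x.T, 4)
        rec = solve_yule_walker(CorrSet(R=corr, kind="gaussian"), 2)
        assert np.allclose(rec.propagation, B_ls, atol=2e-2)
        assert np.allclose(B_ls, model.propagation, atol=2e-2)

    def test_matches_statsmodels_var(self, rng):
        """Independent oracle: statsmodels VAR fit on the same realization."""
        from statsmodels.tsa.api import VAR

        model = unidirectional_pair()
        x = simulate_gaussian(model, 100_000, rng).T
        sm_fit = VAR(x).fit(maxlags=2, trend="n")
        corr, _ = _empirical_corr(x.T, 4)
        rec = solve_yule_walker(CorrSet(R=corr, kind="gaussian"), 2)
        assert np.allclose(rec.propagation[0], sm_fit.coefs[0], atol=2e-2)
        assert np.allclose(rec.propagation[1], sm_fit.coefs[1], atol=2e-2)
        assert np.allclose(rec.Sigma, sm_fit.sigma_u, atol=5e-2)


def _empirical_corr(x, K):
    p, N = x.shape
    R = np.stack([x[:, : N - k] @ x[:, k:].T / (N - k) for k in range(K + 1)])
    return R, None


class TestResidualCovariance:
    def test_ar1_closed_form(self):
        corr = ar1_corrset()
        model = MVARModel(A=np.array([[[-0.5]]]), Sigma=np.eye(1))
        assert residual_covariance(corr, model)[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_order_zero_full_variance_unexplained(self):
        corr = ar1_corrset()
        model = MVARModel(A=np.zeros((0, 1, 1)), Sigma=np.eye(1))
        assert residual_covariance(corr, model)[0, 0] == pytest.approx(4 / 3)

    def test_monotone_nonincreasing_in_order(self, rng):
        """Extra lags never increase the prediction error (PSD order)."""
        model = random_stable_model(rng, 3, 2)
        corr = model_correlations(model, K=8)
        prev = None
        for m in range(0, 7):
            S = solve_yule_walker(corr, m).Sigma
            if prev is not None:
                assert np.min(np.linalg.eigvalsh(prev - S)) > -1e-10
            prev = S


class TestBICAndOrderSelection:
    def test_unit_variance_reduces_to_penalty(self):
        corr = CorrSet(R=np.concatenate([np.eye(1)[None], np.zeros((3, 1, 1))]),
                       kind="gaussian")
        assert bic_score(corr, 1, 10_000) == pytest.approx(2 * np.log(10_000) / 10_000)

    def test_formula_direct_evaluation(self):
        # white bivariate noise: Sigma~ = I at any order, det = 1
        R = np.zeros((4, 2, 2))
        R[0] = np.eye(2)
        corr = CorrSet(R=R, kind="gaussian")
        assert bic_score(corr, 3, 10_000) == pytest.approx(24 * np.log(10_000) / 10_000)

    def test_true_order_recovered_from_long_simulation(self, rng):
        model = unidirectional_pair()
        x = simulate_gaussian(model, 600_000, rng)
        R, _ = _empirical_corr(x, 10)
        corr = CorrSet(R=R, kind="gaussian")
        best, trace = select_order(corr, 8, 600_000)
        assert best == 2
        assert set(trace) == set(range(1, 9))

    def test_single_candidate(self):
        best, _ = select_order(ar1_corrset(), 1, 1000)
        assert best == 1


class TestModelCorrelations:
    def test_ar1_closed_form(self):
        model = MVARModel.from_propagation([[[0.5]]], [[1.0]])
        corr = model_correlations(model, 5)
        expect = (4 / 3) * 0.5 ** np.arange(6)
        assert np.allclose(corr.R[:, 0, 0], expect, atol=1e-12)

    def test_order_zero_white(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        corr = model_correlations(MVARModel(A=np.zeros((0, 2, 2)), Sigma=S), 3)
        assert np.allclose(corr.lag(0), S)
        assert np.allclose(corr.R[1:], 0.0)

    def test_unstable_model_rejected(self):
        model = MVARModel.from_propagation([[[1.01]]], [[1.0]])
        with pytest.raises(ValueError, match="stable"):
            model_correlations(model, 3)

    def test_matches_long_simulation(self, rng):
        model = sequential_triple()
        corr = model_correlations(model, 6)
        x = simulate_gaussian(model, 1_000_000, rng)
        R, _ = _empirical_corr(x, 6)
        se = 4.0 / np.sqrt(1_000_000 / 10)  # generous 4-SE band
        assert np.max(np.abs(R - corr.R)) < se

    def test_negative_lag_is_transpose(self):
        corr = model_correlations(unidirectional_pair(), 4)
        assert np.allclose(corr.lag(-2), corr.lag(2).T)


class TestImpulseResponse:
    def test_ar1_geometric(self):
        model = MVARModel.from_propagation([[[0.5]]], [[1.0]])
        h = impulse_response(model, 5)
        assert np.allclose(h[:, 0, 0], 0.5 ** np.arange(1, 6))

    def test_chain_has_zero_reverse_kernels(self):
        h = impulse_response(sequential_triple(), 20)
        energy = np.linalg.norm(h, axis=0)
        assert energy[0, 1] == 0.0 and energy[0, 2] == 0.0 and energy[1, 2] == 0.0
        assert energy[1, 0] > 0 and energy[2, 1] > 0 and energy[2, 0] > 0
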