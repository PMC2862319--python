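"""Time-domain Granger causality: exact-correlation identities and surrogates."""

import numpy as np
import pytest

from spikemvar.examples import (
    common_input_triple,
    sequential_triple,
    unidirectional_pair,
)
from spikemvar.granger import (
    GrangerConfig,
    analyze_connectivity,
    causality_index,
    conditional_granger,
    empirical_p_value,
    nullified_model,
    pairwise_granger,
    surrogate_test,
)
from spikemvar.estimation import fit_mvar_np
from spikemvar.lnp_simulator import LNPModel, calibrate_rate, simulate_spikes
from spikemvar.mvar_core import MVARModel, model_correlations

from conftest import random_stable_model


class TestExactCorrelationIdentities:
    def test_independent_channels_zero_causality(self):
        uncoupled = MVARModel.from_propagation(
            [np.diag([0.5, 0.3])], np.eye(2)
        )
        corr = model_correlations(uncoupled, 8)
        assert pairwise_granger(corr, 0, 1, 2) == pytest.approx(0.0, abs=1e-10)
        assert pairwise_granger(corr, 1, 0, 2) == pytest.approx(0.0, abs=1e-10)

    def test_unidirectional_pair_forward_positive_reverse_zero(self):
        corr = model_correlations(unidirectional_pair(), 10)
        assert pairwise_granger(corr, 0, 1, 2) > 0.1
        assert pairwise_granger(corr, 1, 0, 2) == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_coupling_gives_equal_indices(self):
        B = np.array([[[0.3, 0.2], [0.2, 0.3]]])
        corr = model_correlations(MVARModel.from_propagation(B, np.eye(2)), 8)
        f01 = pairwise_granger(corr, 0, 1, 1)
        f10 = pairwise_granger(corr, 1, 0, 1)
        assert f01 == pytest.approx(f10, rel=1e-9)
        assert f01 > 0

    def test_chain_conditional_separates_direct_from_indirect(self):
        """In a 0 -> 1 -> 2 chain the 0 -> 2 route is indirect only."""
        corr = model_correlations(sequential_triple(), 10)
        assert pairwise_granger(corr, 0, 2, 3) > 0.05  # indirect still visible
        assert conditional_granger(corr, 0, 2, 3) == pytest.approx(0.0, abs=1e-10)
        assert conditional_granger(corr, 0, 1, 3) > 0.1
        assert conditional_granger(corr, 1, 2, 3) > 0.1

    def test_common_input_conditional_rejects_spurious_edges(self):
        corr = model_correlations(common_input_triple(), 10)
        assert conditional_granger(corr, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)
        assert conditional_granger(corr, 2, 1, 3) == pytest.approx(0.0, abs=1e-10)
        assert conditional_granger(corr, 0, 1, 3) > 0.1
        assert conditional_granger(corr, 0, 2, 3) > 0.1

    def test_latent_common_input_induces_weak_reverse_pairwise_index(self):
        """Unobserved common input makes pairwise causality bidirectional.

        In the common-input fork the later-driven channel carries independent
        information about the hidden driver, so its past weakly improves
        prediction of the earlier-driven channel: the exact index is small
        but strictly positive, unlike the chain model's reverse edges.
        """
        fork = model_correlations(common_input_triple(), 12)
        f_rev = pairwise_granger(fork, 2, 1, 3)
        assert 0.01 < f_rev < 0.05
        chain = model_correlations(sequential_triple(), 12)
        assert pairwise_granger(chain, 2, 1, 3) < 0.005

    def test_bivariate_conditional_reduces_to_pairwise(self):
        corr = model_correlations(unidirectional_pair(), 8)
        assert conditional_granger(corr, 0, 1, 2) == pytest.approx(
            pairwise_granger(corr, 0, 1, 2)
        )

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_causality_never_negative_on_exact_correlations(self, seed):
        local = np.random.default_rng(seed)
        model = random_stable_model(local, 3, 2)
        corr = model_correlations(model, 8)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert pairwise_granger(corr, i, j, 2) >= -1e-9
                    assert conditional_granger(corr, i, j, 2) >= -1e-9

    def test_self_edge_rejected(self):
        corr = model_correlations(unidirectional_pair(), 8)
        with pytest.raises(ValueError, match="differ"):
            pairwise_granger(corr, 1, 1, 2)


class TestSurrogates:
    def test_p_value_formula_observed_above_all_nulls(self):
        nulls = np.linspace(0, 0.1, 19)
        assert empirical_p_value(0.5, nulls) == pytest.approx(1 / 20)  # = 0.05
        assert empirical_p_value(-1.0, nulls) == pytest.approx(1.0)

    def test_nullified_model_zeros_all_lags_of_one_edge(self):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        null = nullified_model(LNPModel(mvar=mvar, nl=nl), 0, 1)
        assert np.allclose(null.mvar.propagation[:, 1, 0], 0.0)
        # everything else untouched
        assert np.allclose(null.mvar.propagation[:, 0, 0], mvar.propagation[:, 0, 0])

    def _feedback_model(self):
        # removing the 1 -> 0 negative feedback destabilizes channel 0
        B = np.array([[[1.02, -0.3], [0.3, 0.5]]])
        mvar = MVARModel.from_propagation(B, np.eye(2))
        assert mvar.is_stable()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        return LNPModel(mvar=mvar, nl=nl)

    def test_unstable_null_raises_without_stabilization(self):
        with pytest.raises(ValueError, match="unstable"):
            nullified_model(self._feedback_model(), 1, 0, stabilize=False)

    def test_stabilized_null_respects_radius_cap(self):
        null = nullified_model(self._feedback_model(), 1, 0, radius_cap=0.95)
        assert null.mvar.spectral_radius() <= 0.95 + 1e-9
        assert np.allclose(null.mvar.propagation[:, 0, 1], 0.0)

    def test_true_edge_detected_on_short_data(self):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        spikes = simulate_spikes(LNPModel(mvar=mvar, nl=nl), 120.0, 8)
        fit = fit_mvar_np(spikes, "exponential", order=2)
        f = causality_index(fit.corr, 0, 1, 2, "pairwise")
        nulls, p = surrogate_test(
            fit.model, (0, 1), f, mode="pairwise",
            n_surrogates=19, duration=120.0, seed=1,
        )
        assert nulls.shape == (19,)
        assert p <= 0.1

    def test_minimum_surrogate_count_enforced(self):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        with pytest.raises(ValueError, match="19"):
            surrogate_test(LNPModel(mvar=mvar, nl=nl), (0, 1), 0.1,
                           n_surrogates=5, duration=60.0)


class TestAnalyzeConnectivity:
    def test_pair_graph_recovered_end_to_end(self):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        spikes = simulate_spikes(LNPModel(mvar=mvar, nl=nl), 300.0, 17)
        report = analyze_connectivity(
            spikes, GrangerConfig(order=2, mode="pairwise", n_surrogates=19)
        )
        assert report.significant_edges() == {(0, 1)}
        d = report.to_dict()
        assert d["significant_edges"] == [[0, 1]] or d["significant_edges"] == [(0, 1)]
        assert len(d["edges"]) == 2

    def test_bonferroni_divides_alpha(self):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        spikes = simulate_spikes(LNPModel(mvar=mvar, nl=nl), 120.0, 3)
        report = analyze_connectivity(
            spikes,
            GrangerConfig(order=2, mode="pairwise", n_surrogates=19, bonferroni=True),
        )
        assert report.alpha == pytest.approx(0.05 / 2)
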