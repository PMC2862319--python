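"""Spike binning, raw correlation estimation, zero-lag correction, regularization."""

import numpy as np
import pytest

from spikemvar.correlation import (
    bin_spikes,
    estimate_spike_correlation,
    regularize_correlation,
    remove_zero_lag_delta,
)
from spikemvar.examples import unidirectional_pair
from spikemvar.lnp_simulator import LNPModel, SpikeTrainSet, calibrate_rate, simulate_counts
from spikemvar.mvar_core import CorrSet
from spikemvar.nonlinearity import MomentSet


class TestBinSpikes:
    def test_empty_train_all_zero(self):
        s = SpikeTrainSet((np.empty(0),), duration=1.0)
        assert bin_spikes(s, 0.1).sum() == 0

    def test_single_spike_at_zero_lands_in_first_bin(self):
        s = SpikeTrainSet((np.array([0.0]),), duration=1.0)
        counts = bin_spikes(s, 0.1)
        assert counts[0, 0] == 1 and counts.sum() == 1

    def test_boundary_spike_goes_to_later_bin(self):
        s = SpikeTrainSet((np.array([0.1]),), duration=1.0)
        counts = bin_spikes(s, 0.1)
        assert counts[0, 1] == 1 and counts[0, 0] == 0

    def test_total_count_preserved(self, rng):
        times = np.sort(rng.uniform(0, 10, size=500))
        s = SpikeTrainSet((times,), duration=10.0)
        assert bin_spikes(s, 0.0073).sum() == 500


class TestEstimateSpikeCorrelation:
    def test_homogeneous_poisson_moments(self, rng):
        """Raw correlations: diag r + r^2 at zero lag, r^2 elsewhere."""
        r = 0.2
        counts = rng.poisson(r, size=(2, 400_000))
        corr, means = estimate_spike_correlation(counts, 5)
        se = 4 * np.sqrt(r / 400_000)
        assert np.allclose(means, r, atol=3 * se)
        assert corr.lag(0)[0, 0] == pytest.approx(r + r**2, abs=5 * se)
        assert corr.lag(0)[0, 1] == pytest.approx(r**2, abs=5 * se)
        assert corr.lag(3)[0, 0] == pytest.approx(r**2, abs=5 * se)

    def test_all_zero_counts(self):
        corr, means = estimate_spike_correlation(np.zeros((2, 1000)), 3)
        assert np.allclose(corr.R, 0.0) and np.allclose(means, 0.0)

    def test_duplicated_channel(self, rng):
        c = rng.poisson(0.3, size=(1, 50_000))
        counts = np.vstack([c, c])
        corr, _ = estimate_spike_correlation(counts, 2)
        assert corr.lag(0)[0, 1] == pytest.approx(corr.lag(0)[0, 0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            estimate_spike_correlation(np.zeros((1, 10)), 10)


class TestRemoveZeroLagDelta:
    def test_poisson_delta_removed(self, rng):
        r = 0.25
        counts = rng.poisson(r, size=(1, 500_000))
        corr, means = estimate_spike_correlation(counts, 4)
        rate_corr, moments = remove_zero_lag_delta(corr, means)
        assert rate_corr.kind == "rate"
        # corrected zero-lag diagonal equals the off-lag level r^2
        assert rate_corr.lag(0)[0, 0] == pytest.approx(r**2, abs=0.003)
        assert moments.m1[0] == pytest.approx(r, abs=0.003)

    def test_rate_kind_input_rejected(self):
        corr = CorrSet(R=np.ones((2, 1, 1)), kind="rate")
        with pytest.raises(TypeError, match="spike"):
            remove_zero_lag_delta(corr, np.array([0.5]))

    def test_sub_poisson_errors_without_floor(self):
        counts = np.zeros((1, 5000), dtype=int)
        counts[0, ::10] = 1  # perfectly regular, strongly sub-Poisson
        corr, means = estimate_spike_correlation(counts, 3)
        with pytest.raises(ValueError, match="min_rate_cv"):
            remove_zero_lag_delta(corr, means)
        _, moments = remove_zero_lag_delta(corr, means, min_rate_cv=0.3)
        assert np.all(moments.m2 >= moments.m1**2 * 1.09)

    def test_lnp_counts_match_rate_moments(self, rng):
        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        model = LNPModel(mvar=mvar, nl=nl)
        counts = simulate_counts(model, 400_000, rng)
        corr, means = estimate_spike_correlation(counts, 4)
        _, moments = remove_zero_lag_delta(corr, means)
        target = 20.0 * model.bin_width
        assert np.allclose(moments.m1, target, rtol=0.05)
        # generator rate CV is 2.0: E[lam^2] = 5 E[lam]^2
        assert np.allclose(moments.m2, 5 * target**2, rtol=0.2)


class TestRegularize:
    def moments(self):
        return MomentSet(np.array([0.2, 0.3]), np.array([0.05, 0.1]))

    def test_negative_covariance_floored_and_counted(self):
        m = self.moments()
        R = np.tile(np.outer(m.m1, m.m1), (3, 1, 1))
        R[0][np.diag_indices(2)] = m.m2
        R[1, 0, 1] = 0.0  # a clear dip below independence
        corr = CorrSet(R=R, kind="rate")
        reg, report = regularize_correlation(corr, m)
        assert report.n_truncated == 1
        assert reg.R[1, 0, 1] == pytest.approx(m.m1[0] * m.m1[1])

    def test_noise_level_negatives_left_alone_with_gate(self):
        m = self.moments()
        R = np.tile(np.outer(m.m1, m.m1), (3, 1, 1))
        R[0][np.diag_indices(2)] = m.m2
        R[1, 0, 1] -= 1e-4  # well within sampling noise for n=1000
        corr = CorrSet(R=R, kind="rate")
        _, report = regularize_correlation(corr, m, n_samples=1000)
        assert report.n_truncated == 0

    def test_truncation_idempotent(self):
        m = self.moments()
        R = np.zeros((3, 2, 2))
        R[0][np.diag_indices(2)] = m.m2
        corr = CorrSet(R=R, kind="rate")
        once, _ = regularize_correlation(corr, m)
        twice, report = regularize_correlation(once, m)
        assert report.n_truncated == 0
        assert np.allclose(once.R, twice.R)

    def test_psd_input_unchanged(self):
        R = np.zeros((3, 2, 2))
        R[0] = np.eye(2)
        corr = CorrSet(R=R, kind="gaussian")
        reg, report = regularize_correlation(corr)
        assert report.loading == 0.0
        assert np.allclose(reg.R, corr.R)

    def test_indefinite_input_loaded_to_psd(self):
        R = np.zeros((2, 1, 1))
        R[0, 0, 0] = 1.0
        R[1, 0, 0] = 1.2  # |r(1)| > r(0): impossible, indefinite Toeplitz
        corr = CorrSet(R=R, kind="gaussian")
        reg, report = regularize_correlation(corr)
        assert report.loading > 0
        T = reg.block_toeplitz()
        assert np.linalg.eigvalsh(T).min() >= 0
        # idempotent
        _, again = regularize_correlation(reg)
        assert again.loading == 0.0


class TestConvergence:
    def test_error_shrinks_when_duration_quadruples(self, rng):
        """Estimated rate correlations converge to the analytic values in N."""
        from spikemvar.mvar_core import model_correlations
        from spikemvar.nonlinearity import NonlinearitySpec, distort_correlation

        mvar = unidirectional_pair()
        nl = calibrate_rate(mvar, "exponential", 20.0)
        model = LNPModel(mvar=mvar, nl=nl)
        corr = model_correlations(mvar, 3)
        d = np.sqrt(np.diag(corr.lag(0)))
        rn = corr.R / np.outer(d, d)
        unit = NonlinearitySpec("exponential", nl.mu, nl.sigma * d)
        expect = np.empty_like(rn[:4])
        for k in range(4):
            for i in range(2):
                for j in range(2):
                    expect[k, i, j] = distort_correlation(
                        unit.channel(i), unit.channel(j), rn[k, i, j]
                    )

        def max_err(n):
            counts = simulate_counts(model, n, rng)
            sc, means = estimate_spike_correlation(counts, 3)
            rc, _ = remove_zero_lag_delta(sc, means)
            return np.max(np.abs(rc.R - expect) / expect)

        err_small = np.median([max_err(30_000) for _ in range(3)])
        err_large = np.median([max_err(120_000) for _ in range(3)])
        assert err_large < err_small  # ~halving expected, direction asserted
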