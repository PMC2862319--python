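"""Spike-train correlation estimation, zero-lag correction, regularization.

Raw (non mean-subtracted) lag correlations of binned spike counts are the
package's measurement stage.  For a doubly-stochastic Poisson process the
count correlation equals the rate correlation plus a zero-lag delta term,
``R_dN(k) = R_lambda(k) + delta(k) diag(E[lambda])``, so subtracting the mean
count from the zero-lag diagonal recovers the rate correlations — and the
corrected zero-lag diagonal is exactly the rate second moment used by moment
inversion.

Real (non-Poisson) spike trains show refractory dips: sharp negative peaks in
the auto-/cross-covariance that the hidden-Gaussian model cannot represent.
The regularization stage optionally floors negative covariances at the
independence level and, after predistortion, adds a diagonal loading chosen
from the minimum eigenvalue of the block-Toeplitz correlation matrix so that
downstream Yule-Walker systems are well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lnp_simulator import SpikeTrainSet
from .mvar_core import CorrSet
from .nonlinearity import MomentSet

__all__ = [
    "RegularizationReport",
    "bin_spikes",
    "estimate_spike_correlation",
    "remove_zero_lag_delta",
    "regularize_correlation",
]

#: eigenvalue margin added on top of |lambda_min| when loading the diagonal
LOADING_EPS = 1e-3


@dataclass(frozen=True)
class RegularizationReport:
    """What regularization did: truncated entries and diagonal loading applied."""

    n_truncated: int = 0
    loading: float = 0.0


def bin_spikes(spikes: SpikeTrainSet, bin_width: float) -> np.ndarray:
    """Spike counts over half-open bins ``[n*D, (n+1)*D)``, shape ``(p, n_bins)``.

    A spike exactly on a boundary belongs to the later bin; total counts are
    preserved exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(int(np.ceil(spikes.duration / bin_width - 1e-12)), 1)
    counts = np.zeros((spikes.p, n_bins), dtype=np.int64)
    for i, t in enumerate(spikes.trains):
        if t.size:
            idx = np.floor(t / bin_width).astype(np.int64)
            counts[i] = np.bincount(np.minimum(idx, n_bins - 1), minlength=n_bins)
    return counts


def estimate_spike_correlation(
    counts: np.ndarray, K: int, *, bin_width: float = 1.0
) -> tuple[CorrSet, np.ndarray]:
    """Raw lag correlations ``R(k)[i, j] = mean_n[c_i(n) c_j(n+k)]``, ``k=0..K``.

    Normalized by ``1/(N-k)`` per lag.  Returns the spike-kind correlation set
    and the per-channel mean counts.
    """
    counts = np.asarray(counts, dtype=float)
    p, N = counts.shape
    if N <= K:
        raise ValueError(f"need more than K={K} samples, got N={N}")
    if N <= 10 * K:
        import warnings

        warnings.warn(
            f"only {N} samples for K={K} lags; correlation estimates will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    R = np.empty((K + 1, p, p))
    for k in range(K + 1):
        R[k] = counts[:, : N - k] @ counts[:, k:].T / (N - k)
    return CorrSet(R=R, kind="spike", bin_width=bin_width), counts.mean(axis=1)


def remove_zero_lag_delta(
    corr: CorrSet, mean_counts: np.ndarray, *, min_rate_cv: float = 0.0
) -> tuple[CorrSet, MomentSet]:
    """Subtract the Poisson delta term from the zero-lag diagonal.

    Converts spike-count correlations to rate correlations and extracts the
    rate moments: ``E[lambda_i]`` is the mean count and ``E[lambda_i^2]`` the
    corrected zero-lag diagonal.

    Doubly-stochastic Poisson counts are always over-dispersed, so the
    corrected second moment exceeds the squared mean.  Sub-Poisson data
    (refractory spike trains) violate that; with ``min_rate_cv > 0`` the
    implied rate CV is floored there instead of failing, which is the
    zero-lag analogue of covariance truncation.
    """
    if corr.kind != "spike":
        raise TypeError(f"expected spike-kind correlations, got {corr.kind!r}")
    mean_counts = np.asarray(mean_counts, dtype=float)
    R = corr.R.copy()
    R[0] -= np.diag(mean_counts)
    diag = np.diag(R[0]).copy()
    if min_rate_cv > 0:
        floor = mean_counts**2 * (1.0 + min_rate_cv**2)
        low = diag < floor
        if np.any(low):
            import warnings

            warnings.warn(
                f"{int(low.sum())} channel(s) at or below Poisson dispersion; "
                f"rate CV floored at {min_rate_cv}",
                RuntimeWarning,
                stacklevel=2,
            )
            diag = np.where(low, floor, diag)
            R[0][np.diag_indices(corr.p)] = diag
    elif np.any(diag <= 0):
        raise ValueError(
            "corrected zero-lag variance non-positive: insufficient data or "
            "zero-variance rate (set min_rate_cv > 0 to floor the dispersion "
            "for refractory data)"
        )
    return (
        CorrSet(R=R, kind="rate", bin_width=corr.bin_width),
        MomentSet(m1=mean_counts, m2=diag.copy()),
    )


def regularize_correlation(
    corr: CorrSet,
    moments: MomentSet | None = None,
    *,
    truncate: bool = True,
    psd_max_lag: int | None = None,
    n_samples: int | None = None,
) -> tuple[CorrSet, RegularizationReport]:
    """Regularize a correlation set into a usable estimation input.

    For ``rate``-kind input (requires ``moments``): wherever the covariance
    ``R(k)[i, j] - E[lambda_i] E[lambda_j]`` dips below zero, floor it at the
    independence level (covariance zero).  Refractory dips in non-Poisson data
    are the motivating case; pass ``truncate=False`` to skip.  When
    ``n_samples`` is given, only dips beyond three standard errors of the
    covariance estimate are floored — flooring noise-level negatives would
    bias every pair toward positive coupling.

    For ``gaussian``-kind input: if the block-Toeplitz matrix over lags
    ``0..psd_max_lag`` (default: all stored lags) has a negative minimum
    eigenvalue, add ``(|lambda_min| + 1e-3) I`` to the zero-lag block.  The
    window should cover the lags the downstream Yule-Walker solve consumes;
    restricting it there keeps sampling noise at long, unused lags from
    inflating the loading.  Idempotent in both modes.
    """
    if corr.kind == "rate":
        if not truncate:
            return corr, RegularizationReport()
        if moments is None:
            raise ValueError("rate-kind truncation requires the rate moments")
        floor = np.outer(moments.m1, moments.m1)
        if n_samples:
            # SE of the raw lag-correlation estimate between channels i, j is
            # ~ sqrt(E[dN_i^2] E[dN_j^2] / N); count second moment = m2 + m1
            count_m2 = moments.m2 + moments.m1
            gate = floor - 3.0 * np.sqrt(np.outer(count_m2, count_m2) / n_samples)
        else:
            gate = floor
        R = corr.R.copy()
        n_trunc = 0
        for k in range(R.shape[0]):
            mask = R[k] < gate
            if k == 0:
                np.fill_diagonal(mask, False)  # zero-lag variance is never a dip
            n_trunc += int(np.count_nonzero(mask))
            R[k] = np.where(mask, floor, R[k])
        return replace(corr, R=R), RegularizationReport(n_truncated=n_trunc)
    if corr.kind == "gaussian":
        T = corr.block_toeplitz(psd_max_lag)
        lam_min = float(np.linalg.eigvalsh((T + T.T) / 2).min())
        if lam_min >= 0:
            return corr, RegularizationReport()
        loading = abs(lam_min) + LOADING_EPS
        R = corr.R.copy()
        R[0] = R[0] + loading * np.eye(corr.p)
        return replace(corr, R=R), RegularizationReport(loading=loading)
    raise TypeError(f"cannot regularize correlations of kind {corr.kind!r}")
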