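"""The spike-trains-to-hidden-MVAR estimation pipeline.

From multichannel spike trains the pipeline proceeds: bin into counts;
estimate raw lag correlations; remove the zero-lag Poisson delta; invert the
rate moments to get the nonlinearity parameters; predistort each lag/pair of
rate correlations back to hidden Gaussian correlations; normalize the
Gaussian zero-lag diagonal to one (the scale non-identifiability is resolved
by convention — all scale lives in the nonlinearity); regularize; solve the
Yule-Walker equations at a fixed or BIC-selected order; and read off the
innovation covariance from the prediction-error relation.

The fit report carries the method's failure-mode telemetry: predistortion
clip counts, covariance truncations, diagonal loading, BIC trace, condition
number of the Yule-Walker system, and a post-fit stability flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .correlation import (
    RegularizationReport,
    bin_spikes,
    estimate_spike_correlation,
    regularize_correlation,
    remove_zero_lag_delta,
)
from .lnp_simulator import DEFAULT_BIN_WIDTH, LNPModel, SpikeTrainSet
from .mvar_core import (
    CorrSet,
    MVARModel,
    impulse_response,
    residual_covariance,
    select_order,
    solve_yule_walker,
)
from .nonlinearity import MomentSet, NonlinearitySpec, invert_moments, predistort_correlation

__all__ = [
    "FitReport",
    "FitResult",
    "fit_mvar_np",
    "fit_mvar_np_counts",
    "predistort_corrset",
    "mismatch_kernel_similarity",
    "DEFAULT_M_MAX",
]

logger = logging.getLogger(__name__)

#: default upper bound of the BIC order scan
DEFAULT_M_MAX = 10


def default_max_lag(m_max: int = DEFAULT_M_MAX) -> int:
    """Default correlation window: enough lags for the order scan and PSD check."""
    return max(5 * m_max, 50)


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of one pipeline run."""

    order: int
    n_bins: int
    n_clipped: int
    n_truncated: int
    loading: float
    stable: bool
    bic_trace: dict = field(default_factory=dict)
    spectral_radius: float = 0.0


@dataclass(frozen=True)
class FitResult:
    """Fitted model plus the Gaussian correlations and diagnostics behind it."""

    model: LNPModel
    corr: CorrSet
    moments: MomentSet
    report: FitReport


def predistort_corrset(
    rate_corr: CorrSet, nl: NonlinearitySpec
) -> tuple[CorrSet, int]:
    """Predistort every lag and channel pair of a rate correlation set.

    Returns the hidden-Gaussian correlation candidate and the number of
    clipped (out-of-image) entries.
    """
    if rate_corr.kind != "rate":
        raise TypeError(f"expected rate-kind correlations, got {rate_corr.kind!r}")
    p, K = rate_corr.p, rate_corr.K
    R = np.empty_like(rate_corr.R)
    n_clipped = 0
    specs = [nl.channel(i) for i in range(p)]
    for i in range(p):
        for j in range(p):
            r, nc = predistort_correlation(
                specs[i], specs[j], rate_corr.R[:, i, j], warn=False
            )
            R[:, i, j] = r
            n_clipped += nc
    return CorrSet(R=R, kind="gaussian", bin_width=rate_corr.bin_width), n_clipped


def _normalize_diagonal(corr: CorrSet) -> CorrSet:
    """Rescale channels so the zero-lag diagonal is exactly one."""
    d = np.sqrt(np.diag(corr.lag(0)))
    scale = np.outer(d, d)
    return CorrSet(R=corr.R / scale, kind=corr.kind, bin_width=corr.bin_width)


def _extrapolate_rate_dispersion(
    rate_corr: CorrSet, moments: MomentSet, min_rate_cv: float
) -> tuple[CorrSet, MomentSet]:
    """Rate second moment for refractory data, from short-lag autocovariances.

    For a doubly-stochastic process the rate variance bounds the
    autocovariance from above at every lag, and equals its limit at zero lag
    — but refractoriness corrupts the zero-lag bin and its immediate
    neighbors.  Reconstruct the rate variance as three times the peak
    positive autocovariance over lags 1..30, falling back to the
    ``min_rate_cv`` floor when no positive short-lag covariance exists, and
    rewrite the zero-lag diagonal for consistency.

    The factor deliberately errs toward over-estimating the variance: an
    under-estimate pushes the implied Gaussian correlations against the unit
    circle and destabilizes every downstream solve, while an over-estimate
    only shrinks all correlations through a common monotone map — which the
    scale-free surrogate significance test absorbs.  The measured count
    dispersion stays authoritative whenever it exceeds the reconstruction
    (over-dispersed data needs none).
    """
    m1 = moments.m1
    p = rate_corr.p
    R = rate_corr.R.copy()
    m2 = np.empty(p)
    k_hi = min(rate_corr.K, 30)
    for i in range(p):
        cov = rate_corr.R[1 : k_hi + 1, i, i] - m1[i] ** 2
        c0 = 3.0 * float(cov.max()) if cov.size and cov.max() > 0 else 0.0
        m2[i] = max(
            moments.m2[i], m1[i] ** 2 + c0, m1[i] ** 2 * (1.0 + min_rate_cv**2)
        )
        R[0, i, i] = m2[i]
    return (
        CorrSet(R=R, kind="rate", bin_width=rate_corr.bin_width),
        MomentSet(m1=m1, m2=m2),
    )


def fit_mvar_np_counts(
    counts: np.ndarray,
    kind: str = "exponential",
    *,
    bin_width: float = DEFAULT_BIN_WIDTH,
    order: int | str = "auto",
    K: int | None = None,
    m_max: int = DEFAULT_M_MAX,
    truncate: bool = False,
    min_rate_cv: float | None = None,
) -> FitResult:
    """Fit the hidden MVAR-nonlinearity-Poisson model from binned counts.

    ``order="auto"`` selects the order by BIC over ``1..m_max``.  ``truncate``
    enables the negative-covariance truncation intended for non-Poisson
    (e.g. refractory) data; for such data the implied rate dispersion is also
    floored at ``min_rate_cv`` (default 0.25 when truncation is on, else 0).
    """
    counts = np.asarray(counts)
    if K is None:
        K = default_max_lag(m_max)
    if min_rate_cv is None:
        min_rate_cv = 0.25 if truncate else 0.0
    spike_corr, means = estimate_spike_correlation(counts, K, bin_width=bin_width)
    rate_corr, moments = remove_zero_lag_delta(
        spike_corr, means, min_rate_cv=min_rate_cv
    )
    if truncate:
        # refractoriness corrupts the zero-lag count dispersion, so the rate
        # second moment is recovered from the short-lag autocovariance peak
        rate_corr, moments = _extrapolate_rate_dispersion(
            rate_corr, moments, min_rate_cv
        )
    nl = invert_moments(kind, moments)
    rate_corr, trunc_report = regularize_correlation(
        rate_corr, moments, truncate=truncate, n_samples=counts.shape[1]
    )
    gauss, n_clipped = predistort_corrset(rate_corr, nl)
    if truncate and kind == "exponential":
        # refractory data can still exceed the Gaussian-correlation domain;
        # inflating every sigma_i by a common factor rescales all predistorted
        # entries except the fixed zero-lag diagonal, so apply the smallest
        # rescaling that brings the candidate inside the domain
        off = np.abs(gauss.R.copy())
        off[0][np.diag_indices(off.shape[1])] = 0.0
        peak = float(off.max()) if off.size else 0.0
        if peak > 0.95:
            scale = peak / 0.95
            Rs = gauss.R / scale
            idx = np.diag_indices(gauss.p)
            Rs[0][idx] = gauss.R[0][idx]
            gauss = CorrSet(R=Rs, kind="gaussian", bin_width=gauss.bin_width)
            nl = NonlinearitySpec(nl.kind, nl.mu, nl.sigma * np.sqrt(scale))
    if n_clipped:
        logger.warning("predistortion clipped %d out-of-image entries", n_clipped)
    if trunc_report.n_truncated:
        logger.warning(
            "truncated %d negative covariance entries", trunc_report.n_truncated
        )
    gauss = _normalize_diagonal(gauss)
    # PSD-enforce the lag window the Yule-Walker equations consume (0..m);
    # loading on the larger window leaves the inverted submatrix with slack
    psd_lag = m_max if order == "auto" else int(order)
    gauss, load_report = regularize_correlation(gauss, psd_max_lag=psd_lag)
    if load_report.loading:
        logger.warning("diagonal loading %.3e applied", load_report.loading)
    n_bins = counts.shape[1]
    bic_trace: dict = {}
    if order == "auto":
        order, bic_trace = select_order(gauss, m_max, n_bins)
    mvar = solve_yule_walker(gauss, int(order))
    stable = mvar.is_stable()
    if not stable:
        logger.error(
            "fitted MVAR stage is unstable (spectral radius %.4f); downstream "
            "simulation-based steps will fail",
            mvar.spectral_radius(),
        )
    report = FitReport(
        order=int(order),
        n_bins=n_bins,
        n_clipped=n_clipped,
        n_truncated=trunc_report.n_truncated,
        loading=load_report.loading,
        stable=stable,
        bic_trace=bic_trace,
        spectral_radius=mvar.spectral_radius(),
    )
    model = LNPModel(mvar=mvar, nl=nl, bin_width=bin_width)
    return FitResult(model=model, corr=gauss, moments=moments, report=report)


def fit_mvar_np(
    spikes: SpikeTrainSet,
    kind: str = "exponential",
    *,
    bin_width: float | None = None,
    order: int | str = "auto",
    K: int | None = None,
    m_max: int = DEFAULT_M_MAX,
    truncate: bool = False,
    min_rate_cv: float | None = None,
) -> FitResult:
    """Fit the hidden MVAR-N-P model directly from spike times."""
    bw = spikes.bin_width if bin_width is None else bin_width
    counts = bin_spikes(spikes, bw)
    per_channel = counts.sum(axis=1)
    if np.any(per_channel < 100):
        raise ValueError(
            f"too few spikes per channel (min {int(per_channel.min())}); need >= 100"
        )
    if np.any(per_channel < 1000):
        import warnings

        warnings.warn(
            "fewer than 1000 spikes on some channel; estimates will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit_mvar_np_counts(
        counts, kind, bin_width=bw, order=order, K=K, m_max=m_max,
        truncate=truncate, min_rate_cv=min_rate_cv,
    )


def mismatch_kernel_similarity(
    modelA: LNPModel | MVARModel,
    modelB: LNPModel | MVARModel,
    horizon: int = 20,
) -> np.ndarray:
    """Pearson correlation between two models' matrix impulse responses.

    Entry ``(i, j)`` correlates the two models' responses of channel ``i`` to
    a unit impulse on channel ``j`` over ``t = 1..horizon``.  Kernels that are
    identically zero in both models correlate to 1 by convention.
    """
    ma = modelA.mvar if isinstance(modelA, LNPModel) else modelA
    mb = modelB.mvar if isinstance(modelB, LNPModel) else modelB
    if ma.p != mb.p:
        raise ValueError("models must have the same channel count")
    for m in (ma, mb):
        if not m.is_stable():
            raise ValueError("impulse-response comparison requires stable models")
    hA = impulse_response(ma, horizon)
    hB = impulse_response(mb, horizon)
    p = ma.p
    rho = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            a = hA[:, i, j] - hA[:, i, j].mean()
            b = hB[:, i, j] - hB[:, i, j].mean()
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0.0 or nb == 0.0:
                rho[i, j] = 1.0 if np.allclose(hA[:, i, j], hB[:, i, j]) else 0.0
            else:
                rho[i, j] = float(a @ b / (na * nb))
    return rho
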