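"""Vector autoregressive (MVAR) models and Yule-Walker estimation.

The central object is a stationary order-``m`` vector autoregression on ``p``
channels,

    x(n) = -sum_{k=1..m} A(k) x(n-k) + w(n),      w(n) ~ N(0, Sigma),

written in "innovation form": the coefficient matrices ``A(k)`` carry a minus
sign, so the familiar propagation matrices are ``B(k) = -A(k)``.  All of the
generative examples shipped with this package are specified in propagation
form (``x(n) = sum_k B(k) x(n-k) + w(n)``) and converted at the boundary.

Model coefficients are recovered from the autocorrelation sequence
``R(k) = E[x(n) x^T(n+k)]`` by solving the multivariate Yule-Walker equations
exactly (one stacked linear solve over the block-Toeplitz covariance of the
lagged state), and the innovation covariance follows from the prediction-error
relation ``Sigma~ = R(0) + sum_k A(k) R(k)``.  Model order is selected by
minimizing a BIC built from ``log det Sigma~``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "MVARModel",
    "CorrSet",
    "IllConditionedCorrelationError",
    "solve_yule_walker",
    "residual_covariance",
    "bic_score",
    "select_order",
    "model_correlations",
    "impulse_response",
]

#: eigenvalue-modulus margin used by the stability check
STABILITY_MARGIN = 1e-9


class IllConditionedCorrelationError(np.linalg.LinAlgError):
    """Raised when the block-Toeplitz Yule-Walker system is numerically singular."""


@dataclass(frozen=True)
class MVARModel:
    """Order-``m`` vector autoregression on ``p`` channels.

    Parameters
    ----------
    A : ndarray, shape (m, p, p)
        Coefficient matrices in innovation form, ``x(n) = -sum A(k) x(n-k) + w``.
    Sigma : ndarray, shape (p, p)
        Innovation (driving noise) covariance; symmetric positive semidefinite.
    """

    A: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_3d(np.asarray(self.A, dtype=float))
        Sigma = np.asarray(self.Sigma, dtype=float)
        if A.ndim != 3 or (A.shape[0] > 0 and A.shape[1] != A.shape[2]):
            raise ValueError("A must have shape (m, p, p)")
        if Sigma.shape != (A.shape[1], A.shape[1]) and A.shape[0] > 0:
            raise ValueError("Sigma must be p x p")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.min(np.linalg.eigvalsh((Sigma + Sigma.T) / 2)) < -1e-10:
            raise ValueError("Sigma must be positive semidefinite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "Sigma", (Sigma + Sigma.T) / 2)

    # -- basic descriptors -------------------------------------------------
    @property
    def p(self) -> int:
        return self.Sigma.shape[0]

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def propagation(self) -> np.ndarray:
        """Propagation matrices ``B(k) = -A(k)`` (shape ``(m, p, p)``)."""
        return -self.A

    @classmethod
    def from_propagation(cls, B: Sequence[np.ndarray], Sigma: np.ndarray) -> "MVARModel":
        """Build a model from propagation form ``x(n) = sum B(k) x(n-k) + w``."""
        B = np.asarray(B, dtype=float)
        if B.size == 0:
            B = np.zeros((0, np.asarray(Sigma).shape[0], np.asarray(Sigma).shape[0]))
        return cls(A=-B, Sigma=np.asarray(Sigma, dtype=float))

    def companion(self) -> np.ndarray:
        """Companion matrix of the propagation form (shape ``(pm, pm)``)."""
        p, m = self.p, self.m
        if m == 0:
            return np.zeros((0, 0))
        F = np.zeros((p * m, p * m))
        F[:p, :] = np.concatenate(list(self.propagation), axis=1)
        if m > 1:
            F[p:, :-p] = np.eye(p * (m - 1))
        return F

    def spectral_radius(self) -> float:
        if self.m == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self) -> bool:
        """All companion-matrix eigenvalues strictly inside the unit circle."""
        return self.spectral_radius() < 1.0 - STABILITY_MARGIN


@dataclass(frozen=True)
class CorrSet:
    """Lag-indexed sequence of ``p x p`` correlation matrices.

    ``R[k]`` stores the raw (non mean-subtracted) second moment
    ``R(k) = E[x(n) x^T(n+k)]`` for lags ``k = 0..K``; negative lags follow
    from stationarity, ``R(-k) = R(k)^T``.  ``kind`` tags which stage of the
    pipeline the correlations describe: the hidden Gaussian process
    (``gaussian``), the nonlinearly transformed firing rates (``rate``), or
    the binned spike counts (``spike``).
    """

    R: np.ndarray
    kind: str
    bin_width: float = 1.0

    _KINDS = ("gaussian", "rate", "spike")

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 3 or R.shape[1] != R.shape[2]:
            raise ValueError("R must have shape (K+1, p, p)")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.kind in ("gaussian", "rate") and np.any(np.diag(R[0]) < 0):
            raise ValueError("zero-lag diagonal must be non-negative")
        object.__setattr__(self, "R", R)

    @property
    def p(self) -> int:
        return self.R.shape[1]

    @property
    def K(self) -> int:
        return self.R.shape[0] - 1

    def lag(self, k: int) -> np.ndarray:
        """``R(k)`` for any lag ``-K <= k <= K`` (negative lags transposed)."""
        if abs(k) > self.K:
            raise ValueError(f"lag {k} outside stored range 0..{self.K}")
        return self.R[k] if k >= 0 else self.R[-k].T

    def submatrix(self, channels: Sequence[int]) -> "CorrSet":
        """Restrict to a channel subset (order preserved)."""
        idx = np.asarray(channels, dtype=int)
        return replace(self, R=self.R[:, idx[:, None], idx[None, :]])

    def block_toeplitz(self, K: int | None = None) -> np.ndarray:
        """Symmetric block-Toeplitz matrix with blocks ``R(j-i)``, ``i,j = 0..K``."""
        K = self.K if K is None else K
        p = self.p
        T = np.empty(((K + 1) * p, (K + 1) * p))
        for i in range(K + 1):
            for j in range(K + 1):
                T[i * p:(i + 1) * p, j * p:(j + 1) * p] = self.lag(j - i)
        return T


def _lagged_state_covariance(corr: CorrSet, m: int) -> np.ndarray:
    """Covariance of the stacked lag vector ``[x(n-1); ...; x(n-m)]``.

    Block ``(a, b)`` equals ``E[x(n-a-1) x^T(n-b-1)] = R(a-b)`` — a symmetric
    ``pm x pm`` block-Toeplitz matrix built from ``R(0..m-1)``.
    """
    p = corr.p
    T = np.empty((m * p, m * p))
    for a in range(m):
        for b in range(m):
            T[a * p:(a + 1) * p, b * p:(b + 1) * p] = corr.lag(a - b)
    return T


def solve_yule_walker(corr: CorrSet, m: int, *, cond_limit: float = 1e12) -> MVARModel:
    """Solve the multivariate Yule-Walker equations for an order-``m`` model.

    The coefficients satisfy ``sum_k A(k) G(i-k) = -G(i)`` for ``i = 1..m``
    where ``G(k) = E[x(n+k) x^T(n)] = R(k)^T`` — the orthogonality of the
    innovation to the lagged state.  The stacked system is solved exactly;
    the innovation covariance is then filled in via :func:`residual_covariance`.

    Raises
    ------
    IllConditionedCorrelationError
        If the block-Toeplitz system's condition number exceeds ``cond_limit``.
    """
    if m < 0:
        raise ValueError("order m must be non-negative")
    if m > corr.K:
        raise ValueError(f"order m={m} exceeds available lags K={corr.K}")
    p = corr.p
    if m == 0:
        model = MVARModel(A=np.zeros((0, p, p)), Sigma=corr.lag(0))
        return model
    T = _lagged_state_covariance(corr, m)
    cond = np.linalg.cond(T)
    if not np.isfinite(cond) or cond > cond_limit:
        raise IllConditionedCorrelationError(
            "ill-conditioned correlation structure: block-Toeplitz condition "
            f"number {cond:.3e} exceeds {cond_limit:.1e}; regularize the "
            "correlations (diagonal loading) or reduce the model order"
        )
    # right-hand side: -[G(1) ... G(m)] with G(k) = R(k)^T
    C = np.concatenate([corr.lag(k).T for k in range(1, m + 1)], axis=1)
    # A_row @ T = -C  with A_row = [A(1) ... A(m)]; T is symmetric
    A_row = np.linalg.solve(T, -C.T).T
    A = np.stack([A_row[:, k * p:(k + 1) * p] for k in range(m)])
    model = MVARModel(A=A, Sigma=np.eye(p))
    S = residual_covariance(corr, model)
    # sampling noise at unenforced lags can leave Sigma~ marginally indefinite
    w, V = np.linalg.eigh(S)
    if w.min() < 0:
        S = (V * np.maximum(w, 0.0)) @ V.T
        S = (S + S.T) / 2
    return MVARModel(A=A, Sigma=S)


def residual_covariance(corr: CorrSet, model: MVARModel) -> np.ndarray:
    """Prediction-error covariance ``Sigma~ = R(0) + sum_k A(k) R(k)``.

    Symmetrized before return; on exact model correlations this equals the
    generating innovation covariance.
    """
    if model.m > corr.K:
        raise ValueError("correlation set does not cover the model order")
    S = corr.lag(0).copy()
    for k in range(1, model.m + 1):
        S = S + model.A[k - 1] @ corr.lag(k)
    return (S + S.T) / 2


def bic_score(corr: CorrSet, m: int, n_total: int) -> float:
    """Bayesian Information Criterion for an order-``m`` fit.

    ``BIC(m) = 2 log det(Sigma~) + 2 p^2 m log(N) / N`` with ``N = n_total``
    the number of time points.  Returns ``+inf`` (with a warning) when the
    prediction-error covariance has a non-positive determinant, so that order
    scans can proceed past degenerate candidates.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    model = solve_yule_walker(corr, m)
    sign, logdet = np.linalg.slogdet(model.Sigma)
    if sign <= 0:
        warnings.warn(
            f"non-positive prediction-error determinant at order m={m}; "
            "BIC set to +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf
    p = corr.p
    return float(2.0 * logdet + 2.0 * p * p * m * np.log(n_total) / n_total)


def select_order(
    corr: CorrSet, m_max: int, n_total: int
) -> tuple[int, dict[int, float]]:
    """Pick the order minimizing :func:`bic_score` over ``m = 1..m_max``.

    Ties break toward the smaller order.  Returns ``(order, bic_trace)``.
    """
    if m_max < 1:
        raise ValueError("m_max must be at least 1")
    if m_max > corr.K:
        raise ValueError(f"m_max={m_max} exceeds available lags K={corr.K}")
    trace: dict[int, float] = {}
    for m in range(1, m_max + 1):
        try:
            trace[m] = bic_score(corr, m, n_total)
        except IllConditionedCorrelationError:
            trace[m] = np.inf
    if not np.isfinite(min(trace.values())):
        raise RuntimeError("no stable order: all BIC scores are infinite")
    best = min(trace, key=lambda m: (trace[m], m))
    return best, trace


def model_correlations(model: MVARModel, K: int) -> CorrSet:
    """Model-implied correlations ``R(0..K)`` of a stable MVAR model.

    The stationary covariance of the companion state solves the discrete
    Lyapunov equation ``P = F P F^T + Q``; lags propagate as
    ``E[z(n+k) z^T(n)] = F^k P`` and the top-left ``p x p`` block of that
    product is ``R(k)^T``.
    """
    p = model.p
    if model.m == 0:
        R = np.zeros((K + 1, p, p))
        R[0] = model.Sigma
        return CorrSet(R=R, kind="gaussian")
    if not model.is_stable():
        raise ValueError(
            f"model is not stable (spectral radius {model.spectral_radius():.6f})"
        )
    F = model.companion()
    Q = np.zeros_like(F)
    Q[:p, :p] = model.Sigma
    P = linalg.solve_discrete_lyapunov(F, Q)
    P = (P + P.T) / 2
    R = np.zeros((K + 1, p, p))
    R[0] = P[:p, :p]
    M = P
    for k in range(1, K + 1):
        M = F @ M
        R[k] = M[:p, :p].T  # E[x(n+k) x^T(n)]^T = E[x(n) x^T(n+k)]
    return CorrSet(R=R, kind="gaussian")


def impulse_response(model: MVARModel, horizon: int) -> np.ndarray:
    """Matrix impulse responses ``H(1..horizon)`` of the deterministic skeleton.

    ``H(t)[i, j]`` is the response of channel ``i`` at time ``t`` to a unit
    impulse applied to channel ``j`` at time 0, propagated through
    ``H(t) = sum_k B(k) H(t-k)`` with ``H(0) = I``.
    """
    p, m = model.p, model.m
    B = model.propagation
    H = np.zeros((horizon + 1, p, p))
    H[0] = np.eye(p)
    for t in range(1, horizon + 1):
        for k in range(1, min(t, m) + 1):
            H[t] += B[k - 1] @ H[t - k]
    return H[1:]
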