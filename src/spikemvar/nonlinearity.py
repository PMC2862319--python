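"""Static nonlinearities linking hidden Gaussian processes to firing rates.

A per-channel memoryless nonlinearity maps the hidden Gaussian process to a
non-negative firing rate, ``lambda_i(n) = f(mu_i + sigma_i x_i(n))``, with
``f`` one of ``exp(.)``, ``(.)^2`` or ``|.|``.  Because the input is Gaussian,
the first two moments of the rate and the lag-wise rate correlations are
available in closed form for the exponential and square kinds — and those
relations invert:

* moment inversion recovers ``(mu_i, sigma_i)`` from ``E[lambda_i]`` and
  ``E[lambda_i^2]``;
* correlation "predistortion" recovers the hidden Gaussian correlation
  ``r_x`` at each lag from the observed rate correlation ``R_lambda``.

All closed forms assume the hidden channels have unit variance; any process
scale is absorbed into ``sigma_i``.  The absolute-value kind is supported in
the forward direction (generation, closed-form moments, quadrature
correlations); its inversion is intentionally not provided — data generated
with it are analyzed under an exponential assumption, which is the package's
nonlinearity-mismatch experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import special

__all__ = [
    "NonlinearitySpec",
    "MomentSet",
    "MomentDomainError",
    "apply_nonlinearity",
    "forward_moments",
    "invert_moments",
    "distort_correlation",
    "predistort_correlation",
]

KINDS = ("exponential", "square", "absolute")
INVERTIBLE_KINDS = ("exponential", "square")

#: margin used when clipping out-of-domain predistortion inputs
CLIP_EPS = 1e-9


class MomentDomainError(ValueError):
    """Raised when rate moments are incompatible with the requested nonlinearity."""


@dataclass(frozen=True)
class NonlinearitySpec:
    """Per-channel offset/scale for one of the supported static nonlinearities."""

    kind: str
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have the same shape")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive for every channel")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def channel(self, i: int) -> "NonlinearitySpec":
        return NonlinearitySpec(self.kind, self.mu[i : i + 1], self.sigma[i : i + 1])


@dataclass(frozen=True)
class MomentSet:
    """First two raw moments of the per-channel rates (events per bin)."""

    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        m1 = np.atleast_1d(np.asarray(self.m1, dtype=float))
        m2 = np.atleast_1d(np.asarray(self.m2, dtype=float))
        if m1.shape != m2.shape:
            raise ValueError("m1 and m2 must have the same shape")
        if np.any(m1 <= 0):
            raise ValueError("mean rates must be strictly positive")
        if np.any(m2 < m1**2 - 1e-12):
            raise ValueError("E[lambda^2] >= E[lambda]^2 violated (Cauchy-Schwarz)")
        object.__setattr__(self, "m1", m1)
        object.__setattr__(self, "m2", m2)


def apply_nonlinearity(spec: NonlinearitySpec, x: np.ndarray) -> np.ndarray:
    """Elementwise rate ``lambda_i(n) = f(mu_i + sigma_i x_i(n))``.

    ``x`` has shape ``(p, n)`` (one row per channel).
    """
    x = np.asarray(x, dtype=float)
    z = spec.mu[:, None] + spec.sigma[:, None] * x
    if spec.kind == "exponential":
        return np.exp(z)
    if spec.kind == "square":
        return z**2
    return np.abs(z)


def _folded_normal_mean(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """``E|mu + sigma x|`` for standard-normal ``x`` (folded-normal mean)."""
    h = mu / sigma
    return sigma * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * h**2) + mu * special.erf(
        h / np.sqrt(2.0)
    )


def forward_moments(spec: NonlinearitySpec) -> MomentSet:
    """Closed-form ``E[lambda_i]`` and ``E[lambda_i^2]`` under unit-variance input."""
    mu, s = spec.mu, spec.sigma
    if spec.kind == "exponential":
        return MomentSet(np.exp(mu + s**2 / 2), np.exp(2 * mu + 2 * s**2))
    if spec.kind == "square":
        return MomentSet(mu**2 + s**2, mu**4 + 6 * mu**2 * s**2 + 3 * s**4)
    # absolute value: folded-normal mean; |z|^2 = z^2 so E[lambda^2] = mu^2+sigma^2
    return MomentSet(_folded_normal_mean(mu, s), mu**2 + s**2)


def invert_moments(kind: str, moments: MomentSet) -> NonlinearitySpec:
    """Recover ``(mu_i, sigma_i)`` from the first two rate moments.

    Exponential (lognormal rates):
        ``sigma = sqrt(ln(E[l^2]/E[l]^2))``, ``mu = ln(E[l]^2 / sqrt(E[l^2]))``.
    Square (scaled noncentral chi-square rates): with
    ``a = sqrt((3 E[l]^2 - E[l^2]) / 2)``, ``mu = sqrt(a)``,
    ``sigma = sqrt(E[l] - a)``.

    Both maps are exact inverses of :func:`forward_moments`.
    """
    if kind not in INVERTIBLE_KINDS:
        raise MomentDomainError(
            f"moment inversion is only available for {INVERTIBLE_KINDS}, not {kind!r}"
        )
    m1, m2 = moments.m1, moments.m2
    if kind == "exponential":
        ratio = m2 / m1**2
        if np.any(ratio <= 1.0):
            raise MomentDomainError(
                "exponential inversion requires E[lambda^2] > E[lambda]^2 "
                "(strictly overdispersed rates); got a degenerate channel"
            )
        sigma = np.sqrt(np.log(ratio))
        mu = np.log(m1**2 / np.sqrt(m2))
        return NonlinearitySpec("exponential", mu, sigma)
    # square
    disc = (3 * m1**2 - m2) / 2
    if np.any(disc < 0):
        raise MomentDomainError(
            "moments incompatible with square nonlinearity: "
            "3 E[lambda]^2 >= E[lambda^2] violated"
        )
    a = np.sqrt(disc)
    if np.any(m1 - a <= 0):
        raise MomentDomainError(
            "moments incompatible with square nonlinearity: "
            "E[lambda] > sqrt((3 E[lambda]^2 - E[lambda^2])/2) violated "
            "(sigma would not be positive)"
        )
    return NonlinearitySpec("square", np.sqrt(a), np.sqrt(m1 - a))


def _check_r(r_x: np.ndarray) -> np.ndarray:
    r = np.asarray(r_x, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r_x| must not exceed 1 for unit-variance channels")
    return np.clip(r, -1.0, 1.0)


def _abs_distort(mi, si, mj, sj, r):
    """``E[|mi+si u| |mj+sj v|]`` for standard bivariate normal ``(u, v)`` with
    correlation ``r``.

    The inner expectation over ``v | u`` is a closed-form folded-normal mean;
    the outer integral is one-dimensional with a single kink, integrated
    adaptively with the kink as a breakpoint.
    """
    from scipy import integrate, stats

    rf = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.empty(rf.shape)
    kink = -mi / si
    for idx, rv in np.ndenumerate(rf):
        cond_sd = sj * np.sqrt(max(1.0 - rv**2, 0.0))

        def integrand(u):
            mean_j = mj + sj * rv * u
            if cond_sd > 0:
                inner = _folded_normal_mean(np.array([mean_j]), np.array([cond_sd]))[0]
            else:
                inner = abs(mean_j)
            return abs(mi + si * u) * inner * stats.norm.pdf(u)

        pts = [kink] if -12 < kink < 12 else None
        out[idx], _ = integrate.quad(integrand, -12, 12, points=pts, limit=200)
    return out.reshape(np.shape(r)) if np.ndim(r) else float(out[0])


def distort_correlation(
    spec_i: NonlinearitySpec, spec_j: NonlinearitySpec, r_x
) -> np.ndarray | float:
    """Forward map: hidden Gaussian correlation -> raw rate correlation.

    ``r_x`` is the raw covariance ``E[x_i(n) x_j(n+k)]`` of the unit-variance
    hidden channels at one lag.  Exponential:
    ``R_lambda = E[l_i] E[l_j] exp(sigma_i sigma_j r_x)``; square: the Wick
    expansion of ``E[(mu_i+s_i u)^2 (mu_j+s_j v)^2]``; absolute value:
    Gauss-Hermite quadrature.
    """
    if spec_i.kind != spec_j.kind:
        raise ValueError("channel specs must share the same nonlinearity kind")
    r = _check_r(r_x)
    mi, si = float(spec_i.mu[0]), float(spec_i.sigma[0])
    mj, sj = float(spec_j.mu[0]), float(spec_j.sigma[0])
    if spec_i.kind == "exponential":
        Ei = np.exp(mi + si**2 / 2)
        Ej = np.exp(mj + sj**2 / 2)
        return Ei * Ej * np.exp(si * sj * r)
    if spec_i.kind == "square":
        return (
            mi**2 * mj**2
            + mi**2 * sj**2
            + mj**2 * si**2
            + si**2 * sj**2 * (1 + 2 * r**2)
            + 4 * mi * mj * si * sj * r
        )
    return _abs_distort(mi, si, mj, sj, r)


def predistort_correlation(
    spec_i: NonlinearitySpec,
    spec_j: NonlinearitySpec,
    r_lambda,
    *,
    warn: bool = True,
):
    """Inverse map: raw rate correlation -> hidden Gaussian correlation.

    Exponential: ``r_x = ln(R_lambda / (E[l_i] E[l_j])) / (sigma_i sigma_j)``.
    Square: ``r_x = (-mu_i mu_j + sqrt((R_lambda - E[l_i]E[l_j])/2
    + mu_i^2 mu_j^2)) / (sigma_i sigma_j)`` on the non-negative root branch.

    Finite-sample rate correlations can fall outside the image of
    :func:`distort_correlation`; such inputs are clipped to the nearest valid
    value and counted.  Returns ``(r_x, n_clipped)``.
    """
    if spec_i.kind != spec_j.kind:
        raise ValueError("channel specs must share the same nonlinearity kind")
    if spec_i.kind not in INVERTIBLE_KINDS:
        raise ValueError(
            "no closed-form predistortion for the absolute-value nonlinearity; "
            "analyze such data under the exponential assumption"
        )
    R = np.asarray(r_lambda, dtype=float)
    scalar = R.ndim == 0
    R = np.atleast_1d(R)
    mi, si = float(spec_i.mu[0]), float(spec_i.sigma[0])
    mj, sj = float(spec_j.mu[0]), float(spec_j.sigma[0])
    n_clipped = 0
    if spec_i.kind == "exponential":
        Ei = np.exp(mi + si**2 / 2)
        Ej = np.exp(mj + sj**2 / 2)
        lo = Ei * Ej * np.exp(-si * sj)
        hi = Ei * Ej * np.exp(si * sj)
        clipped = (R < lo * (1.0 - 1e-9)) | (R > hi * (1.0 + 1e-9))
        n_clipped = int(np.count_nonzero(clipped))
        Rc = np.clip(R, lo * (1.0 - CLIP_EPS) + np.finfo(float).tiny, hi)
        r = np.clip(np.log(Rc / (Ei * Ej)) / (si * sj), -1.0, 1.0)
    else:
        Ei, Ej = mi**2 + si**2, mj**2 + sj**2
        inner = (R - Ei * Ej) / 2 + mi**2 * mj**2
        neg = inner < 0
        n_clipped += int(np.count_nonzero(neg))
        inner = np.maximum(inner, 0.0)
        r = (-mi * mj + np.sqrt(inner)) / (si * sj)
        out = np.abs(r) > 1.0 + 1e-9
        n_clipped += int(np.count_nonzero(out))
        r = np.clip(r, -1.0, 1.0)
    if n_clipped and warn:
        warnings.warn(
            f"{n_clipped} rate-correlation value(s) outside the nonlinearity's "
            "image were clipped during predistortion",
            RuntimeWarning,
            stacklevel=2,
        )
    if scalar:
        return float(r[0]), n_clipped
    return r, n_clipped
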