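"""Doubly-stochastic Poisson (MVAR-N-P) spike-train generation.

The generative chain is: a stable hidden MVAR produces correlated Gaussian
channels; a per-channel static nonlinearity turns them into non-negative
firing rates; spike counts are drawn Poisson per time bin conditional on the
rate.  Because the rate itself is stochastic the resulting point processes
are Cox (doubly-stochastic) processes with larger-than-Poisson dispersion.

Rate calibration works backwards through the same closed forms: given a
target mean rate (Hz) and a coefficient of variation of the rate process,
the first two rate moments are fixed and the nonlinearity parameters follow
from moment inversion, with the hidden process's actual stationary variance
absorbed into the per-channel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from ._kernels import mvar_recursion
from .mvar_core import CorrSet, MVARModel, model_correlations
from .nonlinearity import (
    MomentSet,
    NonlinearitySpec,
    _folded_normal_mean,
    apply_nonlinearity,
    invert_moments,
)

__all__ = [
    "SpikeTrainSet",
    "LNPModel",
    "simulate_gaussian",
    "simulate_counts",
    "simulate_spikes",
    "calibrate_rate",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_RATE_CV",
]

#: default discretization of the hidden process (seconds per bin)
DEFAULT_BIN_WIDTH = 2e-2
#: default coefficient of variation of the rate process lambda_i(t), per kind.
#: Predistortion SNR grows with the effective nonlinearity scale, so each
#: generator sits near the top of its kind's feasible CV range: the square
#: kind requires CV < sqrt(2) and the folded normal caps the absolute kind
#: at CV < sqrt(pi/2 - 1) ~ 0.755.
DEFAULT_RATE_CV = {"exponential": 2.0, "square": 1.3, "absolute": 0.7}
#: per-bin Poisson means above this indicate a discretization problem
MAX_RATE_PER_BIN = 100.0


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-channel spike-time sequences over a common observation window."""

    trains: tuple
    duration: float
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        trains = tuple(np.asarray(t, dtype=float) for t in self.trains)
        for i, t in enumerate(trains):
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError(f"channel {i}: spike times must lie in [0, duration)")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"channel {i}: spike times must be non-decreasing")
        object.__setattr__(self, "trains", trains)

    @property
    def p(self) -> int:
        return len(self.trains)

    @property
    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def mean_rates(self) -> np.ndarray:
        """Empirical mean firing rate per channel (Hz)."""
        return np.array([t.size / self.duration for t in self.trains])


@dataclass(frozen=True)
class LNPModel:
    """Hidden MVAR + static nonlinearity + per-bin Poisson emission."""

    mvar: MVARModel
    nl: NonlinearitySpec
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if self.nl.p != self.mvar.p:
            raise ValueError("nonlinearity and MVAR channel counts differ")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def _burn_in(mvar: MVARModel) -> int:
    return 10 * max(mvar.m, 1) * mvar.p


def simulate_gaussian(
    mvar: MVARModel, n_steps: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Seeded realization of the hidden Gaussian MVAR, shape ``(p, n_steps)``.

    A burn-in of ``10 m p`` steps from a zero initial state is discarded.
    """
    if not mvar.is_stable():
        raise ValueError(
            f"cannot simulate an unstable model (spectral radius "
            f"{mvar.spectral_radius():.6f})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    burn = _burn_in(mvar)
    chol = np.linalg.cholesky(
        mvar.Sigma + 1e-12 * np.eye(mvar.p) * max(np.trace(mvar.Sigma), 1.0)
    )
    e = rng.standard_normal((n_steps + burn, mvar.p)) @ chol.T
    if mvar.m == 0:
        return e[burn:].T
    x = mvar_recursion(np.ascontiguousarray(mvar.propagation), e)
    return x[burn:].T


def simulate_counts(
    model: LNPModel, n_steps: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-bin Poisson spike counts, shape ``(p, n_steps)``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = simulate_gaussian(model.mvar, n_steps, rng)
    lam = apply_nonlinearity(model.nl, x)
    over = lam > MAX_RATE_PER_BIN
    n_over = int(np.count_nonzero(over))
    if n_over:
        # isolated tail bins of a heavy-tailed rate are clipped; a persistent
        # excess means the discretization is wrong
        if n_over > max(1e-4 * lam.size, 2):
            raise ValueError(
                f"per-bin Poisson mean exceeds {MAX_RATE_PER_BIN} in {n_over} "
                f"bins (max {lam.max():.1f}); use a smaller bin_width"
            )
        lam = np.minimum(lam, MAX_RATE_PER_BIN)
    return rng.poisson(lam)


def counts_to_spikes(
    counts: np.ndarray, bin_width: float, rng: np.random.Generator
) -> SpikeTrainSet:
    """Place each counted event uniformly at random inside its bin and sort."""
    p, n = counts.shape
    trains = []
    for i in range(p):
        idx = np.nonzero(counts[i])[0]
        reps = counts[i, idx]
        starts = np.repeat(idx, reps) * bin_width
        times = np.sort(starts + rng.uniform(0.0, bin_width, size=starts.size))
        trains.append(times)
    return SpikeTrainSet(tuple(trains), duration=n * bin_width, bin_width=bin_width)


def simulate_spikes(model: LNPModel, duration: float, seed: int) -> SpikeTrainSet:
    """Simulate a spike-train set of the given duration (seconds)."""
    n_steps = int(round(duration / model.bin_width))
    if n_steps == 0:
        return SpikeTrainSet(tuple(np.empty(0) for _ in range(model.mvar.p)),
                             duration=0.0, bin_width=model.bin_width)
    rng = np.random.default_rng(seed)
    counts = simulate_counts(model, n_steps, rng)
    return counts_to_spikes(counts, model.bin_width, rng)


def _calibrate_absolute(m1_target: np.ndarray, m2_target: np.ndarray) -> NonlinearitySpec:
    """Numerically invert the folded-normal moments for the absolute-value kind.

    With ``h = mu/sigma`` the ratio ``E[l]^2 / E[l^2]`` depends on ``h`` alone
    and is strictly increasing, so ``h`` is found by bracketing and the scale
    follows from ``E[l^2] = mu^2 + sigma^2``.
    """
    mus, sigmas = [], []
    for m1, m2 in zip(np.atleast_1d(m1_target), np.atleast_1d(m2_target)):
        target = m1**2 / m2
        if not (2.0 / np.pi) - 1e-9 <= target <= 1.0 - 1e-12:
            raise ValueError(
                "moments incompatible with absolute-value nonlinearity: "
                "E[l]^2/E[l^2] must lie in [2/pi, 1)"
            )

        def ratio(h):
            return _folded_normal_mean(np.array([h]), np.array([1.0]))[0] ** 2 / (
                h**2 + 1.0
            ) - target

        h = optimize.brentq(ratio, 0.0, 50.0, xtol=1e-12)
        sigma = np.sqrt(m2 / (h**2 + 1.0))
        mus.append(h * sigma)
        sigmas.append(sigma)
    return NonlinearitySpec("absolute", np.array(mus), np.array(sigmas))


def calibrate_rate(
    mvar: MVARModel,
    kind: str,
    target_rate: float,
    *,
    rate_cv: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> NonlinearitySpec:
    """Choose nonlinearity parameters hitting a target mean rate (Hz).

    The per-bin mean is fixed at ``E[lambda_i] = target_rate * bin_width`` and
    the second moment by the rate process's coefficient of variation,
    ``E[lambda_i^2] = E[lambda_i]^2 (1 + rate_cv^2)``; moment inversion then
    yields ``(mu_i, sigma_i)``.  The hidden channels' actual stationary
    variances are absorbed into the returned ``sigma`` so that the closed
    forms (which assume unit variance) apply exactly.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rate_cv is None:
        if kind not in DEFAULT_RATE_CV:
            raise ValueError(f"unknown nonlinearity kind {kind!r}")
        rate_cv = DEFAULT_RATE_CV[kind]
    if rate_cv <= 0:
        raise ValueError("rate_cv must be positive (a zero-variance rate is degenerate)")
    mean_per_bin = target_rate * bin_width
    if mean_per_bin >= 1.0:
        raise ValueError("target_rate * bin_width must be < 1 event per bin")
    if mean_per_bin > 0.5:
        import warnings

        warnings.warn(
            f"target rate of {mean_per_bin:.2f} events/bin is high; consider a "
            "smaller bin_width",
            RuntimeWarning,
            stacklevel=2,
        )
    p = mvar.p
    m1 = np.full(p, mean_per_bin)
    m2 = m1**2 * (1.0 + rate_cv**2)
    if kind == "absolute":
        unit = _calibrate_absolute(m1, m2)
    else:
        unit = invert_moments(kind, MomentSet(m1, m2))
    # absorb the hidden process scale: sigma_eff * std(x_i) == sigma_unit
    var = np.diag(model_correlations(mvar, 0).lag(0))
    return NonlinearitySpec(unit.kind, unit.mu, unit.sigma / np.sqrt(var))
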