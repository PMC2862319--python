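"""Small Izhikevich spiking networks: realistic, non-Poisson fixture data.

These networks provide spike trains that are *not* generated by any
rate-modulated Poisson mechanism — membrane dynamics impose refractoriness
and millisecond-precise synaptic interactions — which is exactly the regime
that stresses the hidden-MVAR estimator and motivates its correlation
regularization.

Each neuron follows the two-variable quadratic model

    v' = 0.04 v^2 + 5 v + 140 - u + I,      u' = a (b v - u),

with the reset ``v <- c``, ``u <- u + d`` on ``v >= 30 mV``, integrated by
forward Euler at 0.5 ms.  Synapses are delayed delta jumps of the
postsynaptic membrane potential; background drive is a constant bias,
Gaussian current noise and per-neuron Poisson pulse trains.

Three observed-motif builders mirror the package's reference architectures
(unidirectional pair, sequential triple, common-input triple).  Each observed
neuron additionally receives one unobserved excitatory and one unobserved
inhibitory "balancing" neuron so that its net background drive is roughly
balanced; the observed subset defines the exported channels and the motif
adjacency is the ground truth for structure-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import izhikevich_step_loop
from .lnp_simulator import SpikeTrainSet

__all__ = ["IFNetworkSpec", "simulate_if_network", "motif_architecture", "MOTIFS"]

#: Euler step of the membrane integration (ms)
DT_MS = 0.5

#: regular-spiking Izhikevich constants
RS = dict(a=0.02, b=0.2, c=-65.0, d=8.0)
#: fast-spiking constants for inhibitory balancing neurons
FS = dict(a=0.1, b=0.2, c=-65.0, d=2.0)

MOTIFS = ("unidirectional_pair", "sequential_triple", "common_input_triple")


@dataclass(frozen=True)
class IFNetworkSpec:
    """Izhikevich network: per-neuron constants, synapses, drive, observation."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    weights: np.ndarray  # [post, pre] membrane jump (mV) per presynaptic spike
    delays_ms: np.ndarray  # [post, pre] conduction delay, >= 1 ms where connected
    bias: np.ndarray  # constant drive current per neuron
    noise_sigma: np.ndarray  # std of Gaussian current noise per step
    pulse_rate_hz: np.ndarray  # rate of background Poisson pulses
    pulse_amp: np.ndarray  # membrane jump (mV) per background pulse
    ou_sigma: np.ndarray | None = None  # std of slow excitability current
    ou_tau_ms: float = 25.0  # time constant of the slow current
    observed: tuple = ()
    edges: frozenset = frozenset()  # ground-truth observed motif, channel indices

    def __post_init__(self) -> None:
        n = self.n_neurons
        if self.ou_sigma is None:
            object.__setattr__(self, "ou_sigma", np.zeros(n))
        for name in ("a", "b", "c", "d", "bias", "noise_sigma", "pulse_rate_hz",
                     "pulse_amp", "ou_sigma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            object.__setattr__(self, name, arr)
        W = np.asarray(self.weights, dtype=float)
        D = np.asarray(self.delays_ms, dtype=float)
        if W.shape != (n, n) or D.shape != (n, n):
            raise ValueError("weights and delays must be n x n")
        if np.any(D[W != 0] < 1.0):
            raise ValueError("conduction delays must be >= 1 ms on existing connections")
        signs = np.sign(W)
        for j in range(n):
            col = signs[:, j][signs[:, j] != 0]
            if col.size and not (np.all(col > 0) or np.all(col < 0)):
                raise ValueError(
                    f"neuron {j} violates Dale's principle (mixed-sign outputs)"
                )
        if any(o < 0 or o >= n for o in self.observed):
            raise ValueError("observed indices out of range")
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "delays_ms", D)
        object.__setattr__(self, "observed", tuple(self.observed))

    @property
    def n_neurons(self) -> int:
        return np.asarray(self.a).shape[0]


def simulate_if_network(
    spec: IFNetworkSpec, duration: float, seed: int
) -> SpikeTrainSet:
    """Simulate the network and return spike trains of the observed subset.

    ``duration`` in seconds.  Deterministic under ``seed``.  Raises on
    numerical blow-up (|v| > 1000 mV), naming the neuron and time.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    dt = DT_MS
    n_steps = int(round(duration * 1000.0 / dt))
    delay_steps = np.maximum(np.round(spec.delays_ms / dt), 1).astype(np.int64)
    pulse_prob = spec.pulse_rate_hz * dt / 1000.0
    steps, ids, ns, bad, bad_t = izhikevich_step_loop(
        spec.a,
        spec.b,
        spec.c,
        spec.d,
        np.ascontiguousarray(spec.weights),
        delay_steps,
        spec.bias,
        spec.noise_sigma,
        pulse_prob,
        spec.pulse_amp,
        spec.ou_tau_ms / dt,
        spec.ou_sigma,
        n_steps,
        dt,
        int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )
    if bad >= 0:
        raise FloatingPointError(
            f"membrane potential blew up on neuron {bad} at "
            f"t = {bad_t * dt / 1000.0:.3f} s; reduce weights or drive"
        )
    trains = []
    for ch in spec.observed:
        t = steps[ids == ch] * (dt / 1000.0)
        trains.append(np.asarray(t, dtype=float))
    return SpikeTrainSet(tuple(trains), duration=max(duration, 1e-9),
                         bin_width=dt / 1000.0)


def _motif_edges(name: str) -> set[tuple[int, int]]:
    if name == "unidirectional_pair":
        return {(0, 1)}
    if name == "sequential_triple":
        return {(0, 1), (1, 2)}
    if name == "common_input_triple":
        return {(0, 1), (0, 2)}
    raise ValueError(f"unknown motif {name!r}; choose one of {MOTIFS}")


def motif_architecture(
    name: str,
    *,
    coupling_mv: float = 11.0,
    delay_ms: float = 10.0,
) -> IFNetworkSpec:
    """Build one of the reference observed motifs with balancing neurons.

    Observed neurons are regular-spiking and wired per the motif with
    excitatory synapses of ``coupling_mv`` at ``delay_ms`` (the common-input
    motif uses distinct delays for its two branches).  Each observed neuron
    receives one unobserved excitatory (regular-spiking) and one unobserved
    inhibitory (fast-spiking) balancing neuron; balancing neurons fire on
    background drive only, so they add uncorrelated input.
    """
    edges = _motif_edges(name)
    n_obs = max(max(e) for e in edges) + 1
    n = 3 * n_obs  # observed + one excitatory + one inhibitory balancer each
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    d = np.empty(n)
    for i in range(n_obs):
        for k, params in ((i, RS), (n_obs + 2 * i, RS), (n_obs + 2 * i + 1, FS)):
            a[k], b[k], c[k], d[k] = params["a"], params["b"], params["c"], params["d"]
    W = np.zeros((n, n))
    D = np.ones((n, n))
    for src, dst in edges:
        W[dst, src] = coupling_mv
        D[dst, src] = delay_ms
    if name == "common_input_triple":
        D[2, 0] = 1.5 * delay_ms  # the two branches act at different latencies
    for i in range(n_obs):
        exc, inh = n_obs + 2 * i, n_obs + 2 * i + 1
        W[i, exc] = 6.0
        W[i, inh] = -6.0
        D[i, exc] = D[i, inh] = 2.0
    # fluctuation-driven regime: slightly hyperpolarizing bias, diffusive
    # pulse background, and strong slow excitability fluctuations that give
    # the firing rates genuine variability on the ~25 ms scale
    bias = np.full(n, -2.0)
    noise_sigma = np.full(n, 3.0)
    pulse_rate = np.full(n, 600.0)
    pulse_amp = np.full(n, 2.5)
    ou_sigma = np.full(n, 12.0)
    return IFNetworkSpec(
        a=a, b=b, c=c, d=d,
        weights=W, delays_ms=D,
        bias=bias, noise_sigma=noise_sigma,
        pulse_rate_hz=pulse_rate, pulse_amp=pulse_amp,
        ou_sigma=ou_sigma,
        observed=tuple(range(n_obs)),
        edges=frozenset(edges),
    )
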