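"""Numba-compiled inner loops for the simulators.

The recursions here are sequential in time and dominate simulation cost, so
they are the only parts of the package that are JIT-compiled.  Everything
around them (noise generation, Poisson draws, correlation estimation) is
plain vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def mvar_recursion(B: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Run x(n) = sum_k B[k] x(n-k) + e(n) over rows of ``e`` (shape (n, p))."""
    m, p = B.shape[0], B.shape[1]
    n = e.shape[0]
    x = np.zeros((n, p))
    for t in range(n):
        acc = e[t].copy()
        kmax = m if t >= m else t
        for k in range(1, kmax + 1):
            acc += B[k - 1] @ x[t - k]
        x[t] = acc
    return x


@njit(cache=True)
def izhikevich_step_loop(
    a,
    b,
    c,
    d,
    weights,
    delay_steps,
    bias,
    noise_sigma,
    pulse_prob,
    pulse_amp,
    ou_tau_steps,
    ou_sigma,
    n_steps,
    dt,
    seed,
):
    """Euler integration of an Izhikevich network with delayed delta synapses.

    ``weights[i, j]`` is the membrane-potential jump (mV) of postsynaptic
    neuron ``i`` per spike of presynaptic ``j``; ``delay_steps[i, j]`` the
    conduction delay in integration steps.  Background drive is a constant
    bias current, Gaussian current noise, per-neuron Poisson pulse trains and
    a slow Ornstein-Uhlenbeck current (stationary std ``ou_sigma``, time
    constant ``ou_tau_steps`` integration steps) emulating slow excitability
    fluctuations.

    Returns ``(spike_steps, spike_ids, n_spikes, blowup_neuron, blowup_step)``;
    ``blowup_neuron >= 0`` signals |v| > 1000 mV at that neuron/step.
    """
    np.random.seed(seed)
    n = a.shape[0]
    v = np.full(n, -65.0)
    u = b * v
    ou = np.zeros(n)
    ou_decay = np.exp(-1.0 / ou_tau_steps) if ou_tau_steps > 0 else 0.0
    ou_drive = np.sqrt(max(1.0 - ou_decay * ou_decay, 0.0))
    L = int(delay_steps.max()) + 1 if delay_steps.size else 1
    buf = np.zeros((n, L))
    cap = max(64, int(n_steps * n // 8))
    spike_steps = np.empty(cap, np.int64)
    spike_ids = np.empty(cap, np.int64)
    ns = 0
    for t in range(n_steps):
        slot = t % L
        for i in range(n):
            if ou_sigma[i] > 0.0:
                ou[i] = ou_decay * ou[i] + ou_sigma[i] * ou_drive * np.random.normal()
            I = bias[i] + ou[i] + noise_sigma[i] * np.random.normal()
            if pulse_prob[i] > 0.0 and np.random.random() < pulse_prob[i]:
                I += pulse_amp[i] / dt  # pulse delivered as current over one step
            v[i] += dt * (0.04 * v[i] * v[i] + 5.0 * v[i] + 140.0 - u[i] + I)
            v[i] += buf[i, slot]
            u[i] += dt * a[i] * (b[i] * v[i] - u[i])
            if abs(v[i]) > 1000.0:
                return spike_steps[:ns], spike_ids[:ns], ns, i, t
        for i in range(n):
            buf[i, slot] = 0.0
        for i in range(n):
            if v[i] >= 30.0:
                if ns >= cap:
                    tmp_s = np.empty(cap * 2, np.int64)
                    tmp_i = np.empty(cap * 2, np.int64)
                    tmp_s[:ns] = spike_steps[:ns]
                    tmp_i[:ns] = spike_ids[:ns]
                    spike_steps = tmp_s
                    spike_ids = tmp_i
                    cap *= 2
                spike_steps[ns] = t
                spike_ids[ns] = i
                ns += 1
                v[i] = c[i]
                u[i] += d[i]
                for post in range(n):
                    w = weights[post, i]
                    if w != 0.0:
                        buf[post, (t + delay_steps[post, i]) % L] += w
    return spike_steps[:ns], spike_ids[:ns], ns, -1, -1
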