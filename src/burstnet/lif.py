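"""Leaky integrate-and-fire network with short-term synaptic depression.

The model follows the classic recurrent network of depressing synapses:
each neuron is a leaky integrator (membrane time constant ``tau_m``) driven
by exponentially decaying synaptic currents and a stochastic membrane
drive that makes isolated neurons fire spontaneously at a low rate.  The
white-noise term enters through the synaptic current variable (so the
noise the membrane sees is low-pass filtered at ``tau_syn``), which keeps
the spontaneous firing rate stable under refinement of the time step.
Excitatory synapses carry Tsodyks-Markram two-state depression (resource
``x`` with recovery time ``tau_rec``, utilization ``U``); inhibitory
synapses are facilitating.  Depletion of the excitatory resource is what
terminates a network burst, so the model bursts in both excitatory-only
and excitatory-inhibitory networks.

Voltages are in mV relative to rest (threshold 15 mV, reset 13.5 mV),
times in ms.  The synaptic weight ``j_syn`` is the tunable scalar that the
bisection calibration adjusts to a target bursting rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from ._rng import fill_normals, seed_state
from .graph import DirectedGraph
from .spikes import SpikeTrain

__all__ = ["LIFParams", "simulate_lif"]


@dataclass(frozen=True)
class LIFParams:
    """Reference parameter set for the depressing-synapse LIF network."""

    tau_m: float = 30.0  # ms, membrane time constant
    r_in: float = 1.0  # M-ohm-like lumped input resistance (R*I in mV)
    threshold: float = 15.0  # mV above rest
    reset: float = 13.5  # mV
    refractory: float = 3.0  # ms
    tau_syn: float = 3.0  # ms, synaptic current decay
    # short-term plasticity, excitatory (depressing)
    tau_rec: float = 800.0  # ms
    u_exc: float = 0.5
    # short-term plasticity, inhibitory (facilitating)
    tau_rec_inh: float = 100.0  # ms
    tau_facil: float = 1000.0  # ms
    u_inh: float = 0.04
    j_syn: float = 65.0  # mV per (fully recovered) synaptic release
    g_inh: float = 3.0  # inhibitory weight = -g_inh * j_syn
    noise_amplitude: float = 14.0  # mV / sqrt(ms) white noise into the synaptic drive
    dt: float = 0.1  # ms

    def __post_init__(self):
        for name in ("tau_m", "tau_syn", "tau_rec", "tau_rec_inh", "tau_facil"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > 0.1:
            raise ValueError("dt must be at most 0.1 ms")

    def with_weight(self, j: float) -> "LIFParams":
        return replace(self, j_syn=j)


@njit(cache=True, fastmath=True)
def _lif_kernel(
    n, n_steps, dt, tau_m, thresh, reset, refr, tau_syn,
    tau_rec, u_exc, tau_rec_inh, tau_facil, u_inh,
    noise, indptr, targets, weight, is_inh, seed, max_spikes,
):  # pragma: no cover - exercised via simulate_lif
    rng_state = seed_state(seed)
    noise_buf = np.empty(n)
    v = np.zeros(n)
    c = np.zeros(n)  # synaptic drive, mV
    x = np.ones(n)  # recovered resource per presynaptic neuron
    u = np.empty(n)  # utilization (facilitating for inhibitory)
    for i in range(n):
        u[i] = u_inh if is_inh[i] else u_exc
    refr_until = np.full(n, -1.0)
    sp_t = np.empty(max_spikes)
    sp_i = np.empty(max_spikes, dtype=np.int64)
    n_sp = 0
    x_min, x_max = 1.0, 1.0
    sq = np.sqrt(dt)
    for step in range(n_steps):
        t = step * dt
        fill_normals(rng_state, noise_buf)
        for i in range(n):
            # resource recovery / facilitation decay
            if is_inh[i]:
                x[i] += dt * (1.0 - x[i]) / tau_rec_inh
                u[i] += dt * (u_inh - u[i]) / tau_facil
            else:
                x[i] += dt * (1.0 - x[i]) / tau_rec
            c[i] += -dt * c[i] / tau_syn + noise * sq * noise_buf[i]
            if t >= refr_until[i]:
                v[i] += dt * (-v[i] + c[i]) / tau_m
        for i in range(n):
            if v[i] >= thresh and t >= refr_until[i]:
                if n_sp >= max_spikes:
                    n_sp = -1
                    return sp_t[:0], sp_i[:0], n_sp, x_min, x_max
                sp_t[n_sp] = t
                sp_i[n_sp] = i
                n_sp += 1
                v[i] = reset
                refr_until[i] = t + refr
                if is_inh[i]:
                    u[i] += u_inh * (1.0 - u[i])
                rel = u[i] * x[i]
                x[i] -= rel
                if x[i] < x_min:
                    x_min = x[i]
                if x[i] > x_max:
                    x_max = x[i]
                for e in range(indptr[i], indptr[i + 1]):
                    c[targets[e]] += weight[i] * rel
            if not np.isfinite(v[i]):
                n_sp = -2
                return sp_t[:0], sp_i[:0], n_sp, x_min, x_max
    return sp_t[:n_sp], sp_i[:n_sp], n_sp, x_min, x_max


def _out_csr(graph: DirectedGraph) -> tuple[np.ndarray, np.ndarray]:
    """Flattened out-edge lists: (indptr, targets) per presynaptic neuron."""
    adj = graph.adjacency
    indptr = np.zeros(graph.n_nodes + 1, dtype=np.int64)
    indptr[1:] = adj.sum(axis=1).cumsum()
    targets = np.nonzero(adj)[1].astype(np.int64)
    return indptr, targets


def simulate_lif(
    graph: DirectedGraph,
    params: LIFParams = LIFParams(),
    duration: float = 61_000.0,
    rng_seed: int = 0,
) -> SpikeTrain:
    """Simulate spontaneous activity; returns the full spike train in ms.

    The first second of a recording is a transient; analysis code removes
    it with :meth:`SpikeTrain.drop_transient`.  Raises ``FloatingPointError``
    on numerical blow-up.
    """
    if duration < 1000.0:
        raise ValueError("duration must be at least 1000 ms")
    n = graph.n_nodes
    is_inh = np.zeros(n, dtype=np.bool_)
    is_inh[graph.inhibitory_ids()] = True
    weight = np.where(is_inh, -params.g_inh * params.j_syn, params.j_syn)
    weight = weight * params.r_in
    indptr, targets = _out_csr(graph)
    n_steps = int(round(duration / params.dt))
    max_spikes = max(200_000, int(n * duration / 1000.0 * 400))
    sp_t, sp_i, status, x_min, x_max = _lif_kernel(
        n, n_steps, params.dt, params.tau_m, params.threshold, params.reset,
        params.refractory, params.tau_syn, params.tau_rec, params.u_exc,
        params.tau_rec_inh, params.tau_facil, params.u_inh,
        params.noise_amplitude, indptr, targets, weight, is_inh,
        int(rng_seed) % (2**31), max_spikes,
    )
    if status == -2:
        raise FloatingPointError("LIF integration diverged (non-finite membrane potential)")
    if status == -1:
        raise FloatingPointError("LIF spike buffer overflow: runaway activity")
    return SpikeTrain(
        sp_t.copy(), sp_i.copy(), duration, n,
        graph.inhibitory_ids(),
        meta={"model": "lif", "j_syn": params.j_syn, "seed": int(rng_seed),
              "stp_range": (float(x_min), float(x_max))},
    )
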