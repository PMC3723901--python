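"""Fast in-kernel Gaussian noise for the simulation loops.

The simulators draw one standard normal per neuron per time step — tens of
millions per minute of simulated activity — so the generator is inlined
into the numba kernels: xorshift128+ uniforms (seeded through splitmix64)
turned into normal pairs by the Box-Muller transform.  The stream is fully
determined by the integer seed, independent of library versions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_state", "fill_normals"]

_TWO_PI = 6.283185307179586
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def seed_state(seed):  # pragma: no cover - exercised via the simulators
    """Initialize the two-word xorshift128+ state from an integer seed."""
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = t ^ (t >> np.uint64(31))
    return state


@njit(inline="always")
def _next_uniform(state):  # pragma: no cover
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 = s1 ^ (s1 << np.uint64(23))
    s1 = s1 ^ (s1 >> np.uint64(17))
    s1 = s1 ^ s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return np.float64((s1 + s0) >> np.uint64(11)) * _INV_2_53


@njit(inline="always")
def fill_normals(state, buf):  # pragma: no cover
    """Fill ``buf`` with independent standard normals (Box-Muller pairs)."""
    n = buf.shape[0]
    i = 0
    while i + 1 < n:
        u1 = _next_uniform(state) + 1e-300  # guard log(0)
        u2 = _next_uniform(state)
        r = np.sqrt(-2.0 * np.log(u1))
        a = _TWO_PI * u2
        buf[i] = r * np.cos(a)
        buf[i + 1] = r * np.sin(a)
        i += 2
    if i < n:
        u1 = _next_uniform(state) + 1e-300
        u2 = _next_uniform(state)
        buf[i] = np.sqrt(-2.0 * np.log(u1)) * np.cos(_TWO_PI * u2)
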