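"""Deterministic pseudo-random streams for the simulation kernels.

Each :class:`~synapse_abm.lattice_core.SimulationState` carries its own
xorshift64* generator state (a one-element ``uint64`` array), so trajectories
are reproducible bit-for-bit from the seed alone, independent of global numpy
state and of how many other simulations run in the same process.  Seeds are
expanded with splitmix64, the standard seeding scheme for xorshift-family
generators.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK64 = (1 << 64) - 1
_XS_MULT = np.uint64(0x2545F4914F6CDD1D)


def splitmix64(seed: int, stream: int = 0) -> int:
    """Expand ``(seed, stream)`` into a well-mixed 64-bit generator seed."""
    z = (int(seed) + stream * 0x9E3779B97F4A7C15 + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z = z ^ (z >> 31)
    return z if z != 0 else 0x9E3779B97F4A7C15  # xorshift state must be nonzero


def make_stream(seed: int, stream: int = 0) -> np.ndarray:
    """One-element uint64 array holding the generator state."""
    return np.array([splitmix64(seed, stream)], dtype=np.uint64)


@njit(cache=True, inline="always")
def next_u64(state):
    s = state[0]
    s ^= s << np.uint64(12)
    s ^= s >> np.uint64(25)
    s ^= s << np.uint64(27)
    state[0] = s
    return s * _XS_MULT


@njit(cache=True, inline="always")
def rand_f64(state):
    """Uniform in [0, 1) with 53 random bits."""
    return (next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def rand_below(state, n):
    """Uniform integer in [0, n).  n is small; modulo bias is < 2**-59."""
    return int(next_u64(state) % np.uint64(n))
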