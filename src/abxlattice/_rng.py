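"""Deterministic xorshift64* streams used by the sweep kernel.

A hand-rolled generator (rather than ``numpy.random.Generator``) keeps
the site-update stream bit-reproducible across numba versions and lets
the jitted kernel and Python-level helpers share state.  The kernel uses
three independent streams (site shuffle, event draw, placement draw) so
the serial dependency chains stay short.
"""
from __future__ import annotations

import numpy as np
from numba import njit, uint64

_MASK64 = (1 << 64) - 1
_MULT = np.uint64(2685821657736338717)  # xorshift64* output multiplier
_INV53 = 1.1102230246251565e-16  # 2**-53


def splitmix64(x: int) -> int:
    """One splitmix64 step; used to expand integer seeds into states."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (x ^ (x >> 31)) & _MASK64


@njit(inline="always", cache=True)
def _step(s):
    s ^= s >> uint64(12)
    s ^= s << uint64(25)
    s ^= s >> uint64(27)
    return s


@njit(cache=True)
def _rand_f64(state, k):
    s = _step(state[k])
    state[k] = s
    return ((s * _MULT) >> uint64(11)) * _INV53


class SweepRng:
    """Seeded pseudo-random stream bundle for one simulation run.

    Identical seed implies a bit-identical draw sequence, hence a
    bit-identical lattice trajectory.  ``state`` holds the three
    xorshift64* stream states consumed (and advanced in place) by the
    sweep kernel.
    """

    __slots__ = ("seed", "state")

    N_STREAMS = 3

    def __init__(self, seed: int):
        self.seed = int(seed)
        words = []
        x = self.seed
        for _ in range(self.N_STREAMS):
            x = splitmix64(x)
            words.append(x if x != 0 else 0x9E3779B97F4A7C15)
        self.state = np.array(words, dtype=np.uint64)

    def random(self, stream: int = 0) -> float:
        """Uniform double in [0, 1) from the given stream."""
        return float(_rand_f64(self.state, stream))

    def randint(self, n: int, stream: int = 0) -> int:
        """Uniform integer in [0, n)."""
        return int(self.random(stream) * n)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SweepRng(seed={self.seed})"
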