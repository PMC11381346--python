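"""Seedable 64-bit hashing primitives.

All sketching algorithms draw their randomness from a splitmix64-style
counter-based mixer applied to packed k-mer tokens.  The same token always
produces the same stream for a given seed, which is what makes register
collisions between two genomes' sketches meaningful.  Both a vectorized
numpy version (array pipelines) and numba-inlinable scalar versions
(tight sketching loops) are provided.
"""

from __future__ import annotations

import numba as nb
import numpy as np

GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
# 2^-53; uniforms are built from the top 53 bits so they lie in (0, 1)
_INV53 = 1.0 / 9007199254740992.0

_U64 = np.uint64


def mix64(x: np.ndarray | int) -> np.ndarray | np.uint64:
    """Vectorized splitmix64 finalizer (a bijection on uint64)."""
    x = np.asarray(x, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = (x ^ (x >> _U64(30))) * _MIX1
        x = (x ^ (x >> _U64(27))) * _MIX2
        return x ^ (x >> _U64(31))


def seed_stream(tokens: np.ndarray, seed: int, salt: int = 0) -> np.ndarray:
    """Per-token stream seeds: mix(token XOR mix(seed XOR salt))."""
    s = mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) ^ np.uint64(salt))
    return mix64(np.asarray(tokens, dtype=np.uint64) ^ s)


def to_unit(h: np.ndarray) -> np.ndarray:
    """Map uint64 hashes to uniforms in the open interval (0, 1)."""
    return (np.asarray(h >> _U64(11), dtype=np.float64) + 0.5) * _INV53


@nb.njit(nb.uint64(nb.uint64), cache=True, inline="always")
def mix64_scalar(x):  # pragma: no cover - exercised through kernels
    x = (x ^ (x >> 30)) * nb.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> 27)) * nb.uint64(0x94D049BB133111EB)
    return x ^ (x >> 31)


@nb.njit(nb.float64(nb.uint64), cache=True, inline="always")
def unit_scalar(h):  # pragma: no cover
    return (nb.float64(h >> 11) + 0.5) * _INV53
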