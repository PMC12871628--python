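"""64-bit mixing primitives used for the random minimizer order and MPHF hashing.

All hashing in the package is seeded and deterministic: the same (seed, key)
pair always yields the same value, across runs and platforms.
"""

from __future__ import annotations

import numpy as np

MASK64 = (1 << 64) - 1

_C1 = 0x9E3779B97F4A7C15
_C2 = 0xBF58476D1CE4E5B9
_C3 = 0x94D049BB133111EB


def splitmix64(x: int) -> int:
    """Finalizer of the splitmix64 generator: a fast, well-mixing 64-bit hash."""
    x = (x + _C1) & MASK64
    z = x
    z ^= z >> 30
    z = (z * _C2) & MASK64
    z ^= z >> 27
    z = (z * _C3) & MASK64
    z ^= z >> 31
    return z


def fold64(x: int) -> int:
    """Reduce a nonnegative integer of any width to 64 bits, deterministically.

    Needed because k-mer codes may span up to 126 bits (k <= 63).
    """
    r = x & MASK64
    x >>= 64
    while x:
        r = splitmix64(r ^ (x & MASK64))
        x >>= 64
    return r


# numpy constants for the vectorized variant (wrapping uint64 arithmetic)
_N1 = np.uint64(_C1)
_N2 = np.uint64(_C2)
_N3 = np.uint64(_C3)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)


def splitmix64_vec(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 over a uint64 array (values wrap modulo 2^64)."""
    z = x + _N1
    z = z ^ (z >> _S30)
    z = z * _N2
    z = z ^ (z >> _S27)
    z = z * _N3
    z = z ^ (z >> _S31)
    return z
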