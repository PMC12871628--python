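"""Elias-Fano encoding of sorted integer arrays with access and successor.

Each value is split into ``ell = max(0, floor(log2(U/n)))`` low bits, stored
in a fixed-width array, and a high part coded in unary in a bit vector (for
high value g, the ones of the elements with that high part are followed by a
zero).  The logical payload is ``n*ell + len(high)`` bits, which is within
the classic ``n*log2(U/n) + 3n`` bound; the select helpers built on top are
an o(n)-style acceleration and their cost is reported separately.

Successor is select-then-scan: jump to the first element whose high part can
reach the query, then scan forward.  Duplicate values are allowed and the
leftmost qualifying index is returned.
"""

from __future__ import annotations

import numpy as np


class EliasFanoArray:
    def __init__(self, n: int, U: int, ell: int, low: np.ndarray, high: np.ndarray):
        self.n = n
        self.U = U
        self.ell = ell
        self.low = low  # uint64[n]
        self.high = high  # uint8[...] of 0/1
        self._sel1 = np.flatnonzero(high == 1)
        self._sel0 = np.flatnonzero(high == 0)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_sorted(cls, A, U: int | None = None) -> "EliasFanoArray":
        A = np.asarray(A, dtype=np.int64)
        n = len(A)
        if n < 1:
            raise ValueError("empty array")
        if np.any(A < 0):
            raise ValueError("negative values not representable")
        if np.any(np.diff(A) < 0):
            raise ValueError("input is not sorted non-decreasingly")
        last = int(A[-1])
        if U is None:
            U = last
        if U < last:
            raise ValueError(f"universe U={U} < max element {last}")
        ratio = U // n if U >= n else 0
        ell = ratio.bit_length() - 1 if ratio >= 1 else 0
        low_mask = (1 << ell) - 1
        low = (A.astype(np.uint64) & np.uint64(low_mask)) if ell else np.zeros(n, np.uint64)
        hp = (A >> ell).astype(np.int64)
        high = np.zeros(n + int(hp[-1]) + 1, dtype=np.uint8)
        high[hp + np.arange(n)] = 1
        return cls(n, U, ell, low, high)

    # -- queries ---------------------------------------------------------
    def access(self, i: int) -> int:
        """The i-th element, 1-based."""
        if not 1 <= i <= self.n:
            raise IndexError(f"index {i} out of range [1..{self.n}]")
        hp = int(self._sel1[i - 1]) - (i - 1)
        return (hp << self.ell) | int(self.low[i - 1])

    def successor(self, x: int) -> tuple[int, int]:
        """(leftmost index i, value y) with y = min{a in A : a >= x}."""
        if x > self.access(self.n):
            raise ValueError(f"successor({x}) undefined: x exceeds max element")
        hx = x >> self.ell
        if hx == 0:
            i0 = 0
        elif hx - 1 < len(self._sel0):
            i0 = int(self._sel0[hx - 1]) - (hx - 1)
        else:  # no zero group that far: all remaining elements qualify
            i0 = self.n
        for i in range(i0, self.n):
            v = self.access(i + 1)
            if v >= x:
                return i + 1, v
        raise AssertionError("unreachable: guarded by the max-element check")

    # -- accounting & serialization --------------------------------------
    def size_bits(self) -> int:
        """Logical payload bits (low array + unary high bit vector)."""
        return self.n * self.ell + len(self.high)

    def select_overhead_bits(self) -> int:
        """Bits spent by the select acceleration, reported separately."""
        return 64 * (len(self._sel0) + len(self._sel1))

    def to_list(self) -> list[int]:
        return [self.access(i) for i in range(1, self.n + 1)]


def ef_build(A, U: int | None = None) -> EliasFanoArray:
    return EliasFanoArray.from_sorted(A, U)


def ef_access(E: EliasFanoArray, i: int) -> int:
    return E.access(i)


def ef_successor(E: EliasFanoArray, x: int) -> tuple[int, int]:
    return E.successor(x)
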