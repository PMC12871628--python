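"""Minimizers, canonical minimizers, super-k-mer parsing, and incremental
(window-by-window) minimizer maintenance.

A sampling scheme is the triple (m, k, order): the minimizer MINI(x) of a
k-mer x is the leftmost m-mer of x that is minimal under a total order on
m-mers.  The order is either "lexicographic" (useful for small worked
examples) or "random", a seeded 64-bit hash of the m-mer code; ties between
hash values are broken by the m-mer code itself so that the order is total
either way.

The canonical minimizer is CMINI(x) = min{MINI(x), MINI(rc(x))}, and its
occurrence position inside x is

    pos(CMINI(x), x) = pos(MINI(x), x)            if MINI(x) <= MINI(rc(x))
                       pos(rc(MINI(rc(x))), x)    otherwise,

where the second branch uses the position-mirroring identity
``pos(rc(phi), rc(x)) = k - m - pos(phi, x) + 2``.

Super-k-mer boundaries are placed where the *occurrence position* of the
minimizer changes (not merely its value): each stored occurrence must reach
every k-mer of its run, and the occurrence-based rule is the one that keeps
the <= k-m+1 span bound intact when the same m-mer value recurs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from ._hash import splitmix64
from .kmer import EncodedKmer, encode_to_codes, rc_code

Mode = Literal["regular", "canonical"]


@dataclass(frozen=True)
class MinimizerScheme:
    k: int
    m: int
    order: Literal["random", "lexicographic"] = "random"
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.m < self.k:
            raise ValueError(f"need 1 <= m < k, got m={self.m}, k={self.k}")
        if self.order not in ("random", "lexicographic"):
            raise ValueError(f"unknown order {self.order!r}")

    def key(self, mcode: int) -> int:
        """Rank of an m-mer under the scheme's order (smaller = preferred)."""
        if self.order == "lexicographic":
            # the packed code stores position 1 in the low pair, so reverse
            # the digit significance to compare first-character-first
            out = 0
            c = mcode
            for _ in range(self.m):
                out = (out << 2) | (c & 3)
                c >>= 2
            return out
        return splitmix64(mcode ^ (self.seed & 0xFFFFFFFFFFFFFFFF))

    def order_pair(self, mcode: int) -> tuple[int, int]:
        """Total-order sort key: hash rank with the code as the tie key."""
        return (self.key(mcode), mcode)


@dataclass(frozen=True)
class MinimizerHit:
    """A minimizer value and the 1-based start of its chosen occurrence."""

    mmer: EncodedKmer
    pos: int


@dataclass(frozen=True)
class SuperKmer:
    """A maximal run of consecutive k-mers sharing one minimizer occurrence.

    ``win_start``/``win_end`` are the 1-based start positions, within the
    string, of the first and last k-mer of the run; ``occ`` is the absolute
    position of the shared minimizer occurrence in the concatenation S.
    """

    string_id: int
    win_start: int
    win_end: int
    occ: int

    @property
    def n_kmers(self) -> int:
        return self.win_end - self.win_start + 1

    @property
    def length(self) -> int:
        # characters covered: from win_start to win_end + k - 1 (k supplied
        # by context); length in k-mers is what the invariants constrain
        return self.n_kmers


def rc_position(k: int, m: int, pos: int) -> int:
    """Position of rc(phi) in rc(x), given phi at ``pos`` in the k-mer x."""
    if not 1 <= pos <= k - m + 1:
        raise ValueError(f"pos must be in [1..{k - m + 1}]")
    return k - m - pos + 2


def _mmer_codes(code: int, k: int, m: int) -> list[int]:
    mask = (1 << (2 * m)) - 1
    return [(code >> (2 * p)) & mask for p in range(k - m + 1)]


def mini(x: EncodedKmer, scheme: MinimizerScheme) -> MinimizerHit:
    """Leftmost order-minimal m-mer of x."""
    if x.k != scheme.k:
        raise ValueError(f"k-mer length {x.k} != scheme k {scheme.k}")
    best = None
    best_pos = 0
    for i, mc in enumerate(_mmer_codes(x.code, scheme.k, scheme.m)):
        pair = scheme.order_pair(mc)
        if best is None or pair < best:
            best = pair
            best_pos = i + 1
    return MinimizerHit(EncodedKmer(scheme.m, best[1]), best_pos)


def cmini(x: EncodedKmer, scheme: MinimizerScheme) -> MinimizerHit:
    """Canonical minimizer with its occurrence position inside x (forward)."""
    f = mini(x, scheme)
    r = mini(EncodedKmer(x.k, rc_code(x.code, x.k)), scheme)
    if scheme.order_pair(f.mmer.code) <= scheme.order_pair(r.mmer.code):
        return f
    return MinimizerHit(r.mmer, rc_position(scheme.k, scheme.m, r.pos))


def streaming_minimizer_pairs(
    codes: np.ndarray, scheme: MinimizerScheme
) -> Iterator[tuple[int, int, int, int]]:
    """Yield, per k-window of ``codes``, the forward and reverse-strand
    minimizers: ``(fwd_code, fwd_pos, rcs_code, rcs_pos)``.

    ``fwd_pos`` is the 1-based occurrence position within the window;
    ``rcs_pos`` is the occurrence position of ``rcs_code`` within the
    *reverse complement* of the window (i.e. what ``mini(rc(window))``
    reports).  Amortized O(1) work per window via monotone deques.
    """
    k, m = scheme.k, scheme.m
    L = len(codes)
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    n_mmers = L - m + 1
    mmask = (1 << (2 * m)) - 1
    mshift = 2 * (m - 1)

    # forward deque: min (pair, pos)  -> leftmost tie wins
    # reverse deque: min pair, rightmost occurrence wins (leftmost in rc)
    fdq: deque[tuple[int, tuple[int, int]]] = deque()
    rdq: deque[tuple[int, tuple[int, int]]] = deque()

    fcode = 0
    rcode = 0
    nxt = 0  # next m-mer position (0-based) to ingest

    def ingest(p0: int) -> None:
        nonlocal fcode, rcode
        b = int(codes[p0 + m - 1]) if p0 > 0 else None
        if p0 == 0:
            fc = 0
            rc = 0
            for j in range(m):
                d = int(codes[j])
                fc |= d << (2 * j)
                rc = (rc << 2) | (3 - d)
            fcode, rcode = fc, rc
        else:
            fcode = ((fcode >> 2) | (b << mshift)) & mmask
            rcode = ((rcode << 2) | (3 - b)) & mmask
        fpair = scheme.order_pair(fcode)
        rpair = scheme.order_pair(rcode)
        while fdq and fdq[-1][1] > fpair:
            fdq.pop()
        fdq.append((p0, fpair))
        while rdq and rdq[-1][1] >= rpair:
            rdq.pop()
        rdq.append((p0, rpair))

    for ws in range(L - k + 1):  # 0-based window start
        hi = ws + k - m  # last m-mer position in this window
        while nxt <= hi:
            ingest(nxt)
            nxt += 1
        while fdq[0][0] < ws:
            fdq.popleft()
        while rdq[0][0] < ws:
            rdq.popleft()
        fp, fpair = fdq[0]
        rp, rpair = rdq[0]
        fwd_pos = fp - ws + 1
        rcs_pos = k - m - (rp - ws + 1) + 2
        yield fpair[1], fwd_pos, rpair[1], rcs_pos


def canonical_hit(
    scheme: MinimizerScheme,
    fwd_code: int,
    fwd_pos: int,
    rcs_code: int,
    rcs_pos: int,
) -> tuple[int, int]:
    """Resolve a (forward, reverse) minimizer pair into the canonical
    minimizer code and its occurrence position on the forward strand."""
    if scheme.order_pair(fwd_code) <= scheme.order_pair(rcs_code):
        return fwd_code, fwd_pos
    return rcs_code, rc_position(scheme.k, scheme.m, rcs_pos)


def streaming_minimizers(
    seq: str | np.ndarray, scheme: MinimizerScheme, mode: Mode = "regular"
) -> Iterator[MinimizerHit]:
    """Per-window minimizer hits, equal to ``mini``/``cmini`` from scratch."""
    codes = encode_to_codes(seq) if isinstance(seq, str) else seq
    for fc, fp, rc, rp in streaming_minimizer_pairs(codes, scheme):
        if mode == "regular":
            yield MinimizerHit(EncodedKmer(scheme.m, fc), fp)
        else:
            c, p = canonical_hit(scheme, fc, fp, rc, rp)
            yield MinimizerHit(EncodedKmer(scheme.m, c), p)


def window_occurrences(
    codes: np.ndarray, scheme: MinimizerScheme, mode: Mode, offset: int = 0
) -> Iterator[tuple[int, int]]:
    """Per k-window: (minimizer code, absolute occurrence position in S).

    ``offset`` is p_i - 1 for the string's start in the concatenation.
    """
    for ws, (fc, fp, rc, rp) in enumerate(
        streaming_minimizer_pairs(codes, scheme), start=1
    ):
        if mode == "regular":
            code, pos = fc, fp
        else:
            code, pos = canonical_hit(scheme, fc, fp, rc, rp)
        yield code, offset + ws + pos - 1


def parse_super_kmers(
    s: str | np.ndarray,
    scheme: MinimizerScheme,
    mode: Mode = "regular",
    string_id: int = 1,
    offset: int = 0,
) -> list[SuperKmer]:
    """Tile the k-mers of a string into super-k-mers.

    A new super-k-mer opens whenever the minimizer occurrence position
    changes.  The k-mer counts of the result sum to |s| - k + 1 exactly.
    """
    codes = encode_to_codes(s) if isinstance(s, str) else s
    out: list[SuperKmer] = []
    cur_occ = None
    cur_start = 1
    last_ws = 0
    for ws, (code, j) in enumerate(
        window_occurrences(codes, scheme, mode, offset), start=1
    ):
        if cur_occ is None:
            cur_occ, cur_start = j, ws
        elif j != cur_occ:
            out.append(SuperKmer(string_id, cur_start, ws - 1, cur_occ))
            cur_occ, cur_start = j, ws
        last_ws = ws
    out.append(SuperKmer(string_id, cur_start, last_ws, cur_occ))
    return out
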