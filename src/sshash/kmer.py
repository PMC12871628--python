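"""DNA alphabet handling: 2-bit k-mer codes, reverse complements, and the
packed concatenation of a spectrum-preserving string set (SPSS).

Coding convention: A=0, C=1, G=2, T=3, with the base at (1-based) position 1
stored in the least-significant 2-bit pair of the integer code.  With this
convention the complement of a base code ``c`` is ``3 - c``, which makes the
reverse complement cheap.  All public coordinates are 1-based and windows are
half-open, ``[q .. q+w)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_K = 63

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEC = "ACGT"

# powers of 4 for turning a run of base codes into one integer (<=32 bases
# fit in uint64: the top term 3 * 4^31 < 2^64)
_POW4 = (np.uint64(4) ** np.arange(32, dtype=np.uint64))


class AlphabetError(ValueError):
    """A symbol outside {A, C, G, T} was encountered."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"non-ACGT symbol {symbol!r} at position {position} (1-based)"
        )


@dataclass(frozen=True)
class EncodedKmer:
    """A k-mer as a 2-bit packed integer.

    ``code < 4**k``; base at position 1 lives in the least-significant pair.
    """

    k: int
    code: int

    def __post_init__(self):
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1..{MAX_K}], got {self.k}")
        if not 0 <= self.code < (1 << (2 * self.k)):
            raise ValueError("code out of range for k")

    def __str__(self) -> str:
        return decode_kmer(self)


def encode_kmer(s: str, k: int | None = None) -> EncodedKmer:
    """Encode a DNA string into an :class:`EncodedKmer` (case-insensitive)."""
    if k is None:
        k = len(s)
    if len(s) != k:
        raise ValueError(f"expected a string of length {k}, got {len(s)}")
    code = 0
    for i, ch in enumerate(s.upper()):
        try:
            d = _ENC[ch]
        except KeyError:
            raise AlphabetError(s[i], i + 1) from None
        code |= d << (2 * i)
    return EncodedKmer(k, code)


def decode_kmer(x: EncodedKmer) -> str:
    return decode_code(x.code, x.k)


def decode_code(code: int, k: int) -> str:
    return "".join(_DEC[(code >> (2 * i)) & 3] for i in range(k))


def rc_code(code: int, k: int) -> int:
    """Reverse complement of a 2-bit packed code."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def reverse_complement(x: EncodedKmer) -> EncodedKmer:
    return EncodedKmer(x.k, rc_code(x.code, x.k))


def canonical_code(code: int, k: int) -> int:
    """The smaller (as an integer) of a code and its reverse complement."""
    rc = rc_code(code, k)
    return code if code <= rc else rc


def encode_to_codes(s: str) -> np.ndarray:
    """DNA string -> uint8 array of base codes; raises AlphabetError."""
    out = np.empty(len(s), dtype=np.uint8)
    for i, ch in enumerate(s.upper()):
        d = _ENC.get(ch)
        if d is None:
            raise AlphabetError(s[i], i + 1)
        out[i] = d
    return out


def codes_to_int(codes: np.ndarray) -> int:
    """Base-code array (position 1 first) -> packed integer code."""
    w = len(codes)
    if w <= 32:
        return int(np.dot(codes.astype(np.uint64), _POW4[:w]))
    lo = int(np.dot(codes[:32].astype(np.uint64), _POW4))
    hi = codes_to_int(codes[32:])
    return lo | (hi << 64)


def codes_to_str(codes: np.ndarray) -> str:
    return "".join(_DEC[c] for c in codes)


def pack_2bit(codes: np.ndarray) -> bytes:
    """Pack base codes 4-per-byte (serialization helper)."""
    n = len(codes)
    pad = (-n) % 4
    c = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    c = c.reshape(-1, 4)
    packed = c[:, 0] | (c[:, 1] << 2) | (c[:, 2] << 4) | (c[:, 3] << 6)
    return packed.astype(np.uint8).tobytes()


def unpack_2bit(data: bytes, n: int) -> np.ndarray:
    packed = np.frombuffer(data, dtype=np.uint8)
    out = np.empty(len(packed) * 4, dtype=np.uint8)
    out[0::4] = packed & 3
    out[1::4] = (packed >> 2) & 3
    out[2::4] = (packed >> 4) & 3
    out[3::4] = (packed >> 6) & 3
    return out[:n].copy()


class PackedSequence:
    """The concatenation S[1..N] of the SPSS strings, 2 bits per base.

    ``extract(q, w)`` returns the substring ``S[q..q+w)`` as an
    :class:`EncodedKmer`; out-of-range coordinates raise ``IndexError``
    (distinct from a dictionary "not found" answer).
    """

    def __init__(self, codes: np.ndarray):
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)

    @property
    def N(self) -> int:
        return len(self.codes)

    @property
    def size_bits(self) -> int:
        return 2 * self.N

    def _check(self, q: int, w: int) -> None:
        if w < 1 or q < 1 or q + w - 1 > self.N:
            raise IndexError(
                f"window [{q}..{q + w}) out of range for N={self.N}"
            )

    def window_codes(self, q: int, w: int) -> np.ndarray:
        self._check(q, w)
        return self.codes[q - 1 : q - 1 + w]

    def window_int(self, q: int, w: int) -> int:
        return codes_to_int(self.window_codes(q, w))

    def extract(self, q: int, w: int) -> EncodedKmer:
        if w > MAX_K:
            raise ValueError(f"extract width {w} exceeds {MAX_K}; use decode()")
        return EncodedKmer(w, self.window_int(q, w))

    def decode(self, q: int, w: int) -> str:
        return codes_to_str(self.window_codes(q, w))


@dataclass
class Spss:
    """A packed spectrum-preserving string set.

    ``starts`` holds p_1=1 < p_2 < ... < p_{|S|} plus the sentinel
    p_{|S|+1} = N+1; string i is ``S[p_i .. p_{i+1})`` and has length >= k.
    """

    packed: PackedSequence
    starts: np.ndarray  # int64, |S|+1 entries
    k: int

    @property
    def N(self) -> int:
        return self.packed.N

    @property
    def num_strings(self) -> int:
        return len(self.starts) - 1

    @property
    def n_kmers(self) -> int:
        lens = np.diff(self.starts)
        return int(np.sum(lens - self.k + 1))

    def string_bounds(self, i: int) -> tuple[int, int]:
        """(p_i, p_{i+1}) for the 1-based string id i."""
        return int(self.starts[i - 1]), int(self.starts[i])


def pack_spss(strings: list[str], k: int, canonical: bool = False) -> Spss:
    """Concatenate SPSS strings (input order preserved) and validate them.

    Every string must be >= k long and no k-mer may occur twice across the
    set.  In canonical mode the duplicate check compares canonical forms,
    since a k-mer and its reverse complement are considered identical there.
    """
    if not strings:
        raise ValueError("empty SPSS")
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1..{MAX_K}]")
    parts = []
    starts = [1]
    seen: dict[int, tuple[int, int]] = {}
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    for sid, s in enumerate(strings, start=1):
        if len(s) < k:
            raise ValueError(
                f"string {sid} has length {len(s)} < k={k}"
            )
        codes = encode_to_codes(s)
        fwd = 0
        rev = 0
        for pos0 in range(len(codes)):
            b = int(codes[pos0])
            fwd = ((fwd >> 2) | (b << shift)) & mask
            rev = ((rev << 2) | (3 - b)) & mask
            if pos0 >= k - 1:
                key = min(fwd, rev) if canonical else fwd
                here = (sid, pos0 - k + 2)
                prev = seen.get(key)
                if prev is not None:
                    raise ValueError(
                        f"duplicated k-mer: string {prev[0]} position {prev[1]}"
                        f" and string {here[0]} position {here[1]}"
                    )
                seen[key] = here
        parts.append(codes)
        starts.append(starts[-1] + len(codes))
    packed = PackedSequence(np.concatenate(parts))
    return Spss(packed, np.asarray(starts, dtype=np.int64), k)
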