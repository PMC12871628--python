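"""Synthetic SPSS and read-set generation for tests and benchmarks.

The SPSS generator emulates the shape of the unitig/eulertig inputs a k-mer
dictionary is built from: a set of strings of length >= k over {A,C,G,T}
with no k-mer repeated anywhere (canonical forms compared, so the output is
a valid SPSS in both index modalities).  Uniqueness is enforced during
generation — each appended base is rejected if it would close a window whose
canonical k-mer has been seen — rather than by graph compaction.

The read generator emulates a sequencing-read workload over that SPSS:
reads are windows sampled from the strings, reverse-complemented with
probability 1/2, with independent per-base substitution errors; a configured
fraction of reads is uniformly random ("foreign").  Each read carries
per-window truth labels (is the window's k-mer in the index?) so that query
results can be checked against ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .kmer import canonical_code, encode_kmer, rc_code

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


@dataclass(frozen=True)
class SyntheticSpssSpec:
    total_bases: int
    n_strings: int
    k: int
    seed: int = 0
    rc_fraction: float = 0.0
    lengths: tuple[int, ...] | None = None  # explicit per-string lengths


@dataclass
class SpssData:
    strings: list[str]
    k: int
    # k-mer code -> (1-based string id, 1-based position within the string)
    truth: dict[int, tuple[int, int]]

    @property
    def n_kmers(self) -> int:
        return len(self.truth)

    def canonical_set(self) -> set[int]:
        k = self.k
        return {canonical_code(c, k) for c in self.truth}


def _plan_lengths(spec: SyntheticSpssSpec) -> list[int]:
    if spec.lengths is not None:
        lengths = list(spec.lengths)
        if sum(lengths) != spec.total_bases:
            raise ValueError("explicit lengths must sum to total_bases")
    else:
        base, rem = divmod(spec.total_bases, spec.n_strings)
        lengths = [base + (1 if i < rem else 0) for i in range(spec.n_strings)]
    if any(ln < spec.k for ln in lengths):
        raise ValueError(
            f"cannot fit {spec.n_strings} strings of length >= k={spec.k} "
            f"into {spec.total_bases} bases"
        )
    return lengths


def gen_spss(spec: SyntheticSpssSpec) -> SpssData:
    """Deterministically generate a duplicate-free SPSS."""
    rng = random.Random(spec.seed)
    k = spec.k
    lengths = _plan_lengths(spec)
    seen: set[int] = set()
    strings: list[str] = []
    kmask = (1 << (2 * k)) - 1
    kshift = 2 * (k - 1)

    for ln in lengths:
        for _attempt in range(64):
            chars: list[int] = []
            fwd = rev = 0
            fresh: set[int] = set()
            ok = True
            while len(chars) < ln:
                order = rng.sample(range(4), 4)
                placed = False
                for b in order:
                    nf = ((fwd >> 2) | (b << kshift)) & kmask
                    nr = ((rev << 2) | (3 - b)) & kmask
                    if len(chars) + 1 >= k:
                        key = min(nf, nr)
                        if key in seen or key in fresh:
                            continue
                        fresh.add(key)
                    chars.append(b)
                    fwd, rev = nf, nr
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                seen.update(fresh)
                strings.append("".join(_BASES[c] for c in chars))
                break
        else:
            raise ValueError(
                f"could not generate a duplicate-free string of length {ln} "
                f"for k={k}: the k-mer space is too saturated"
            )

    # optionally store some strings reverse-complemented (the spectrum is
    # unchanged; forward coordinates in the truth table follow the stored
    # orientation)
    if spec.rc_fraction > 0:
        n_rc = round(spec.rc_fraction * len(strings))
        for idx in rng.sample(range(len(strings)), n_rc):
            strings[idx] = revcomp(strings[idx])

    truth: dict[int, tuple[int, int]] = {}
    for sid, s in enumerate(strings, start=1):
        for pos in range(len(s) - k + 1):
            code = encode_kmer(s[pos : pos + k]).code
            truth[code] = (sid, pos + 1)
    return SpssData(strings, k, truth)


@dataclass(frozen=True)
class ReadSetSpec:
    n_reads: int
    read_length: int
    substitution_rate: float = 0.0
    foreign_fraction: float = 0.0
    seed: int = 0


@dataclass
class Read:
    name: str
    seq: str
    labels: list[bool]  # one per k-window: k-mer present in the SPSS?


def gen_reads(spec: ReadSetSpec, spss: SpssData) -> list[Read]:
    """Sample a labelled read set from an SPSS (deterministic given seed)."""
    rng = random.Random(spec.seed)
    k = spss.k
    L = spec.read_length
    if L < k:
        raise ValueError(f"read length {L} < k={k}")
    canon = spss.canonical_set()
    eligible = [
        (sid, s) for sid, s in enumerate(spss.strings, start=1) if len(s) >= L
    ]
    if not eligible and spec.foreign_fraction < 1.0:
        raise ValueError("no SPSS string is long enough to sample reads from")

    reads: list[Read] = []
    for ridx in range(spec.n_reads):
        foreign = rng.random() < spec.foreign_fraction
        if foreign:
            seq = "".join(rng.choice(_BASES) for _ in range(L))
        else:
            _, s = eligible[rng.randrange(len(eligible))]
            start = rng.randrange(len(s) - L + 1)
            seq = s[start : start + L]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if spec.substitution_rate > 0:
                chars = list(seq)
                for i in range(L):
                    if rng.random() < spec.substitution_rate:
                        chars[i] = rng.choice(
                            [b for b in _BASES if b != chars[i]]
                        )
                seq = "".join(chars)
        labels = []
        for w in range(L - k + 1):
            code = encode_kmer(seq[w : w + k]).code
            labels.append(canonical_code(code, k) in canon)
        reads.append(Read(f"read{ridx}", seq, labels))
    return reads
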