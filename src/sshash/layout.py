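"""Cache-conscious storage of minimizer locate sets: tags + three stores.

Minimizers are typed by their occurrence count z in the concatenation S:

* singleton (z = 1): the single position is inlined in the tag itself;
* light (2 <= z <= 2^l): positions live in an array L, grouped by set size,
  with a small directory G[z] giving each size group's start;
* heavy (z > 2^l): positions live in an array H and a *skew index* — one
  (MPHF f_i, vector V_i) pair per size class K_i with
  2^i < z <= min(2^{i+1}, max) — resolves a k-mer of such a minimizer to a
  single position with one probe of V_i and one of H.

One tag word per minimizer, indexed by the minimizer MPHF.  Tag layout
(least-significant bits first; W = position width + 1, widened if a field
would not fit, which only happens for tiny inputs):

    singleton: [0 | position]
    light:     [1 0 | z-2 (l bits) | index within the size-z group]
    heavy:     [1 1 | partition id (3 bits) | offset of the set in H]

The stores keep probe counters so tests can assert the per-type access
contract (singleton: no L/H reads; light: <= 2^l reads of L; heavy: exactly
one read of H plus one of V_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mphf import Mphf

MAX_PARTITIONS = 8  # partition id must fit in 3 bits


def skew_partition_of(z: int, l: int, r: int) -> int:
    """The size class i in [l..r] with 2^i < z <= 2^{i+1}, clamped to r."""
    if z <= (1 << l):
        raise ValueError(f"z={z} is not heavy for l={l}")
    i = (z - 1).bit_length() - 1
    return min(i, r)


@dataclass
class TagArray:
    """M tag words of ``width`` bits each (position width + 1, or wider)."""

    width: int
    pos_bits: int
    l: int
    tags: np.ndarray  # uint64[M]

    @classmethod
    def empty(cls, M: int, pos_bits: int, l: int, width: int) -> "TagArray":
        return cls(width, pos_bits, l, np.zeros(M, dtype=np.uint64))

    # field geometry -----------------------------------------------------
    @property
    def group_bits(self) -> int:
        return self.width - self.l - 2

    @property
    def offset_bits(self) -> int:
        return self.width - 5

    def encode_singleton(self, t: int, j: int) -> None:
        self.tags[t - 1] = np.uint64(j << 1)

    def encode_light(self, t: int, z: int, gi: int) -> None:
        if gi >= (1 << self.group_bits):
            raise OverflowError("group index field too narrow")
        word = 0b01 | ((z - 2) << 2) | (gi << (2 + self.l))
        self.tags[t - 1] = np.uint64(word)

    def encode_heavy(self, t: int, part: int, o: int) -> None:
        if o >= (1 << self.offset_bits):
            raise OverflowError("heavy offset field too narrow")
        word = 0b11 | (part << 2) | (o << 5)
        self.tags[t - 1] = np.uint64(word)

    def decode(self, t: int) -> tuple:
        """('singleton', j) | ('light', z, gi) | ('heavy', part, o)."""
        word = int(self.tags[t - 1])
        if word & 1 == 0:
            return ("singleton", word >> 1)
        if word & 2 == 0:
            z = ((word >> 2) & ((1 << self.l) - 1)) + 2
            return ("light", z, word >> (2 + self.l))
        return ("heavy", (word >> 2) & 0b111, word >> 5)

    @property
    def M(self) -> int:
        return len(self.tags)

    def size_bits(self) -> int:
        return self.M * self.width


@dataclass
class LightStore:
    """Locate sets of size 2..2^l, concatenated in L grouped by size."""

    l: int
    L: np.ndarray  # int64 positions
    G: np.ndarray  # int64[2^l + 1]; G[z] = start of the size-z group in L
    reads: int = 0  # instrumentation: entries of L read

    def get(self, z: int, gi: int) -> list[int]:
        start = int(self.G[z]) + gi * z
        self.reads += z
        return [int(v) for v in self.L[start : start + z]]


@dataclass
class SkewPartition:
    i: int
    f: Mphf
    V: np.ndarray  # int64, 0-based indices into the owning locate set
    width_bits: int


@dataclass
class HeavyStore:
    """Concatenated heavy locate sets plus the skew index partitions."""

    H: np.ndarray  # int64 positions
    partitions: dict[int, SkewPartition] = field(default_factory=dict)
    h_reads: int = 0
    v_reads: int = 0

    def locate_one(self, part_id: int, o: int, kmer_code: int) -> int | None:
        """j = H[o + V_i[f_i(x)]]; None if the slot falls outside H (only
        possible for foreign k-mers)."""
        part = self.partitions.get(part_id)
        if part is None:
            return None
        v = int(part.V[part.f.eval(kmer_code) - 1])
        self.v_reads += 1
        idx = o + v
        if idx >= len(self.H):
            return None
        self.h_reads += 1
        return int(self.H[idx])

    def first_position(self, o: int) -> int | None:
        """H[o]: the first element of the set at offset o (used only on the
        negative path to decide whether the minimizer exists in S at all)."""
        if o >= len(self.H):
            return None
        return int(self.H[o])


def plan_tag_width(N: int, M: int, n_light: int, len_H: int, l: int) -> tuple[int, int, bool]:
    """(pos_bits, width, widened): the tag word is position width + 1 bits,
    widened minimally when the light group index or heavy offset would not
    fit (a tiny-N corner case)."""
    pos_bits = max(1, N.bit_length())
    width = pos_bits + 1
    need_group = max(1, n_light.bit_length()) if n_light else 1
    need_off = max(1, len_H.bit_length()) if len_H else 1
    extra = max(0, need_group - (width - l - 2), need_off - (width - 5))
    return pos_bits, width + extra, extra > 0


def build_layout(
    occ: dict[int, list[int]],
    heavy_kmers: dict[int, list[tuple[int, int]]],
    f: Mphf,
    l: int,
    N: int,
    r: int | None = None,
    mphf_seed: int = 0,
) -> tuple[TagArray, LightStore, HeavyStore]:
    """Assemble tags and the three stores from the per-minimizer occurrence
    map.

    ``occ`` maps minimizer code -> sorted distinct absolute positions in S;
    ``heavy_kmers`` maps each heavy minimizer code -> [(k-mer key, index of
    its occurrence within the locate set)], used to build the skew index.
    """
    if r is None:
        r = l + MAX_PARTITIONS - 1
    if r - l + 1 > MAX_PARTITIONS:
        raise ValueError("r - l + 1 must be <= 8")
    M = len(occ)
    light_cap = 1 << l

    light_by_z: dict[int, list[tuple[int, list[int]]]] = {}
    heavy_list: list[tuple[int, list[int]]] = []
    n_light_sets = 0
    len_H = 0
    for code, positions in occ.items():
        z = len(positions)
        if z == 1:
            continue
        if z <= light_cap:
            light_by_z.setdefault(z, []).append((code, positions))
            n_light_sets += 1
        else:
            heavy_list.append((code, positions))
            len_H += z

    pos_bits, width, _widened = plan_tag_width(N, M, n_light_sets, len_H, l)
    tags = TagArray.empty(M, pos_bits, l, width)

    # light store: groups by ascending size
    L_parts: list[int] = []
    G = np.zeros(light_cap + 1, dtype=np.int64)
    light_slot: dict[int, tuple[int, int]] = {}
    for z in sorted(light_by_z):
        G[z] = len(L_parts)
        for gi, (code, positions) in enumerate(light_by_z[z]):
            light_slot[code] = (z, gi)
            L_parts.extend(positions)
    light = LightStore(l, np.asarray(L_parts, dtype=np.int64), G)

    # heavy store
    H_parts: list[int] = []
    heavy_slot: dict[int, tuple[int, int]] = {}
    for code, positions in heavy_list:
        part = skew_partition_of(len(positions), l, r)
        heavy_slot[code] = (part, len(H_parts))
        H_parts.extend(positions)
    heavy = HeavyStore(np.asarray(H_parts, dtype=np.int64))

    # skew index partitions
    by_part: dict[int, list[tuple[int, int]]] = {}
    for code, kmers in heavy_kmers.items():
        part = skew_partition_of(len(occ[code]), l, r)
        by_part.setdefault(part, []).extend(kmers)
    max_z = max((len(p) for _, p in heavy_list), default=0)
    for part, pairs in sorted(by_part.items()):
        keys = [key for key, _ in pairs]
        fi = Mphf.build(keys, seed=mphf_seed + part + 1)
        V = np.zeros(len(keys), dtype=np.int64)
        for key, loc_idx in pairs:
            V[fi.eval(key) - 1] = loc_idx
        wbits = (part + 1) if part < r else max(1, (max(1, max_z - 1)).bit_length())
        heavy.partitions[part] = SkewPartition(part, fi, V, wbits)

    # tags
    for code, positions in occ.items():
        t = f.eval(code)
        z = len(positions)
        if z == 1:
            tags.encode_singleton(t, positions[0])
        elif z <= light_cap:
            zz, gi = light_slot[code]
            tags.encode_light(t, zz, gi)
        else:
            part, o = heavy_slot[code]
            tags.encode_heavy(t, part - l, o)
    return tags, light, heavy


def locate(
    entry: tuple,
    kmer_code: int,
    light: LightStore,
    heavy: HeavyStore,
    l: int,
) -> list[int]:
    """Candidate occurrence positions j for a decoded tag entry."""
    kind = entry[0]
    if kind == "singleton":
        return [entry[1]]
    if kind == "light":
        _, z, gi = entry
        return light.get(z, gi)
    _, part, o = entry
    j = heavy.locate_one(part + l, o, kmer_code)
    return [] if j is None else [j]
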