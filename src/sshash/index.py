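"""The assembled order-preserving k-mer dictionary.

The index stores the SPSS concatenation S (2 bits/base), the string start
offsets P as an Elias-Fano sequence, an MPHF over the minimizer set, and the
typed locate layout.  A k-mer's locate set holds the absolute positions of
its minimizer occurrences, so LOOKUP turns a stored occurrence j directly
into candidate k-mer start positions:

* regular mode (one strand): q = j - pos(MINI(x), x) + 1, and if the forward
  query fails the whole pipeline is retried with rc(x);
* canonical mode (both strands share one entry): two candidates when
  MINI(x) != MINI(rc(x)) and four when they coincide, with reverse-strand
  positions mirrored via pos(rc(phi), rc(x)) = k - m - pos(phi, x) + 2.

A positive answer carries the handle h = q - (i-1)(k-1), where i is the id
of the comprising string — this maps the n indexed k-mers onto [1..n] and
gives consecutive k-mers of a string consecutive handles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ef import EliasFanoArray
from .kmer import (
    EncodedKmer,
    Spss,
    canonical_code,
    encode_kmer,
    pack_spss,
    rc_code,
)
from .layout import (
    HeavyStore,
    LightStore,
    TagArray,
    build_layout,
    locate,
)
from .minimizer import (
    MinimizerHit,
    MinimizerScheme,
    Mode,
    mini,
    rc_position,
    window_occurrences,
)
from .mphf import Mphf

DEFAULT_L = 6


@dataclass(frozen=True)
class LookupResult:
    """Answer to LOOKUP: handle (None encodes a negative answer), string id,
    orientation (+1 forward / -1 reverse), absolute position q in S, and
    whether the query's minimizer was found in S at all."""

    handle: int | None
    string_id: int = 0
    orientation: int = 0
    position: int = 0
    found: bool = False

    @property
    def is_hit(self) -> bool:
        return self.handle is not None


_MISS = LookupResult(None)


def displace_regular(j: int, hit: MinimizerHit) -> int:
    """Putative k-mer start: q = j - pos + 1 (caller bounds-checks)."""
    return j - hit.pos + 1


def displace_canonical(
    x: EncodedKmer, j: int, scheme: MinimizerScheme
) -> list[tuple[int, int]]:
    """Candidate (start position, orientation) pairs for a stored occurrence
    j of the canonical minimizer of x.  Candidates with q < 1 are dropped."""
    k, m = scheme.k, scheme.m
    f = mini(x, scheme)
    r = mini(EncodedKmer(k, rc_code(x.code, k)), scheme)
    pf_pair = scheme.order_pair(f.mmer.code)
    pr_pair = scheme.order_pair(r.mmer.code)
    pf, pr = f.pos, r.pos
    cands: list[tuple[int, int]] = []
    if pf_pair < pr_pair:
        cands.append((j - pf + 1, +1))
        cands.append((j - rc_position(k, m, pf) + 1, -1))
    elif pf_pair > pr_pair:
        cands.append((j - pr + 1, -1))
        cands.append((j - rc_position(k, m, pr) + 1, +1))
    else:
        cands.append((j - pf + 1, +1))
        cands.append((j - rc_position(k, m, pf) + 1, -1))
        cands.append((j - pr + 1, -1))
        cands.append((j - rc_position(k, m, pr) + 1, +1))
    out = []
    seen = set()
    for q, o in cands:
        if q >= 1 and (q, o) not in seen:
            seen.add((q, o))
            out.append((q, o))
    return out


class SsHashIndex:
    """Sparse-and-skew-hashing dictionary over the k-mers of an SPSS."""

    def __init__(
        self,
        spss: Spss,
        scheme: MinimizerScheme,
        mode: Mode,
        P: EliasFanoArray,
        f: Mphf,
        tags: TagArray,
        light: LightStore,
        heavy: HeavyStore,
        l: int,
        r: int,
        Z: int,
        n_singleton: int,
        seed: int,
        max_loc: int = 1,
    ):
        self.spss = spss
        self.scheme = scheme
        self.mode = mode
        self.P = P
        self.f = f
        self.tags = tags
        self.light = light
        self.heavy = heavy
        self.l = l
        self.r = r
        self.Z = Z
        self.n_singleton = n_singleton
        self.seed = seed
        self.max_loc = max_loc

    # convenience aliases -------------------------------------------------
    @property
    def k(self) -> int:
        return self.scheme.k

    @property
    def m(self) -> int:
        return self.scheme.m

    @property
    def n(self) -> int:
        return self.spss.n_kmers

    @property
    def N(self) -> int:
        return self.spss.N

    @property
    def M(self) -> int:
        return self.tags.M

    # -- construction -----------------------------------------------------
    @classmethod
    def build(
        cls,
        strings: list[str],
        k: int,
        m: int,
        mode: Mode = "regular",
        l: int = DEFAULT_L,
        order: str = "random",
        seed: int = 0,
    ) -> "SsHashIndex":
        if m >= k:
            raise ValueError(f"need m < k, got m={m}, k={k}")
        scheme = MinimizerScheme(k, m, order, seed)
        spss = pack_spss(strings, k, canonical=(mode == "canonical"))
        r = l + 7

        # one pass over all windows: occurrence map + per-window records
        occ: dict[int, list[int]] = {}
        win_codes: list[int] = []  # minimizer code per window
        win_occs: list[int] = []  # occurrence position per window
        for i in range(1, spss.num_strings + 1):
            p_i, p_next = spss.string_bounds(i)
            codes = spss.packed.codes[p_i - 1 : p_next - 1]
            for code, j in window_occurrences(codes, scheme, mode, offset=p_i - 1):
                lst = occ.get(code)
                if lst is None:
                    occ[code] = [j]
                elif lst[-1] != j:
                    lst.append(j)
                win_codes.append(code)
                win_occs.append(j)
        for lst in occ.values():
            lst.sort()

        light_cap = 1 << l
        heavy_codes = {c for c, p in occ.items() if len(p) > light_cap}
        heavy_kmers: dict[int, list[tuple[int, int]]] = {c: [] for c in heavy_codes}
        if heavy_codes:
            rank = {
                c: {j: idx for idx, j in enumerate(occ[c])} for c in heavy_codes
            }
            w = 0
            for i in range(1, spss.num_strings + 1):
                p_i, p_next = spss.string_bounds(i)
                for q in range(p_i, p_next - k + 1):
                    code = win_codes[w]
                    if code in heavy_codes:
                        kc = spss.packed.window_int(q, k)
                        if mode == "canonical":
                            kc = canonical_code(kc, k)
                        heavy_kmers[code].append((kc, rank[code][win_occs[w]]))
                    w += 1

        f = Mphf.build(sorted(occ.keys()), seed=seed)
        tags, light, heavy = build_layout(
            occ, heavy_kmers, f, l, spss.N, r=r, mphf_seed=seed
        )
        P = EliasFanoArray.from_sorted(spss.starts, U=spss.N + 1)
        Z = sum(len(p) for p in occ.values())
        n_singleton = sum(1 for p in occ.values() if len(p) == 1)
        max_loc = max(len(p) for p in occ.values())
        return cls(
            spss, scheme, mode, P, f, tags, light, heavy, l, r, Z,
            n_singleton, seed, max_loc,
        )

    # -- internal helpers --------------------------------------------------
    def _string_of(self, q: int) -> tuple[int, int, int] | None:
        """(string id i, p_i, p_{i+1}) if the window [q..q+k) lies within one
        string, else None."""
        k = self.k
        if q < 1 or q + k - 1 > self.N:
            return None
        idx, y = self.P.successor(q)
        i = idx if y == q else idx - 1
        if i < 1:
            return None
        p_i = q if y == q else self.P.access(i)
        p_next = self.P.access(i + 1)
        if q > p_next - k:
            return None
        return i, p_i, p_next

    def _handle(self, q: int, i: int) -> int:
        return q - (i - 1) * (self.k - 1)

    def _mmer_at(self, j: int) -> int | None:
        m = self.m
        if j < 1 or j + m - 1 > self.N:
            return None
        return self.spss.packed.window_int(j, m)

    def _minimizer_present(self, phi: int, candidates: list[int], entry) -> bool:
        """Does phi occur in S where the layout says it should?  For the
        heavy type the probed candidate may be wrong for foreign k-mers, so
        fall back to the first element of the stored set."""
        def matches(j: int | None) -> bool:
            got = self._mmer_at(j) if j is not None else None
            if got is None:
                return False
            if self.mode == "regular":
                return got == phi
            return got == phi or got == rc_code(phi, self.m)

        probe = candidates[0] if candidates else None
        if matches(probe):
            return True
        if entry[0] == "heavy":
            # the probed element is k-mer-specific and may be wrong for a
            # foreign k-mer even when phi is present: consult the set head
            return matches(self.heavy.first_position(entry[2]))
        return False

    def _try_candidate(self, q: int, code: int, orientation: int) -> LookupResult | None:
        loc = self._string_of(q)
        if loc is None:
            return None
        i, _, _ = loc
        if self.spss.packed.window_int(q, self.k) == code:
            return LookupResult(self._handle(q, i), i, orientation, q, True)
        return None

    def _lookup_regular_pass(self, code: int, orientation: int) -> LookupResult:
        hit = mini(EncodedKmer(self.k, code), self.scheme)
        phi = hit.mmer.code
        t = self.f.eval(phi)
        entry = self.tags.decode(t)
        cands = locate(entry, code, self.light, self.heavy, self.l)
        if not self._minimizer_present(phi, cands, entry):
            # the tag belongs to another minimizer: phi is foreign
            return _MISS
        for j in cands:
            if self._mmer_at(j) != phi:
                # a k-mer-specific heavy probe gone astray (foreign k-mer)
                continue
            q = displace_regular(j, hit)
            res = self._try_candidate(q, code, orientation)
            if res is not None:
                return res
        return LookupResult(None, found=True)

    def _lookup_canonical(self, code: int) -> LookupResult:
        k, m = self.k, self.m
        x = EncodedKmer(k, code)
        rcc = rc_code(code, k)
        fh = mini(x, self.scheme)
        rh = mini(EncodedKmer(k, rcc), self.scheme)
        fp_pair = self.scheme.order_pair(fh.mmer.code)
        rp_pair = self.scheme.order_pair(rh.mmer.code)
        phi = fh.mmer.code if fp_pair <= rp_pair else rh.mmer.code
        t = self.f.eval(phi)
        entry = self.tags.decode(t)
        skew_key = canonical_code(code, k)
        cands = locate(entry, skew_key, self.light, self.heavy, self.l)
        if not self._minimizer_present(phi, cands, entry):
            return _MISS
        rcphi = rc_code(phi, m)
        pf, pr = fh.pos, rh.pos
        for j in cands:
            got = self._mmer_at(j)
            if got != phi and got != rcphi:
                continue  # stray heavy probe of a foreign k-mer
            if fp_pair < rp_pair:
                pairs = ((j - pf + 1, +1), (j - rc_position(k, m, pf) + 1, -1))
            elif fp_pair > rp_pair:
                pairs = ((j - pr + 1, -1), (j - rc_position(k, m, pr) + 1, +1))
            else:
                pairs = (
                    (j - pf + 1, +1),
                    (j - rc_position(k, m, pf) + 1, -1),
                    (j - pr + 1, -1),
                    (j - rc_position(k, m, pr) + 1, +1),
                )
            tried = set()
            for q, o in pairs:
                if q < 1 or (q, o) in tried:
                    continue
                tried.add((q, o))
                res = self._try_candidate(q, code if o > 0 else rcc, o)
                if res is not None:
                    return LookupResult(res.handle, res.string_id, o, res.position, True)
        return LookupResult(None, found=True)

    # -- public queries ----------------------------------------------------
    def lookup(self, x: str | EncodedKmer) -> LookupResult:
        """LOOKUP(x): a handle in [1..n] with location info, or a miss."""
        if isinstance(x, str):
            x = encode_kmer(x)
        if x.k != self.k:
            raise ValueError(f"query length {x.k} != index k {self.k}")
        return self.lookup_code(x.code)

    def lookup_code(self, code: int) -> LookupResult:
        if self.mode == "canonical":
            return self._lookup_canonical(code)
        res = self._lookup_regular_pass(code, +1)
        if res.is_hit:
            return res
        res2 = self._lookup_regular_pass(rc_code(code, self.k), -1)
        if res2.is_hit:
            return LookupResult(
                res2.handle, res2.string_id, res2.orientation,
                res2.position, res.found or res2.found,
            )
        return LookupResult(None, found=res.found or res2.found)

    def access(self, h: int) -> str:
        """ACCESS(h): the k-mer with handle h, or the empty string."""
        if not 1 <= h <= self.n:
            return ""
        k = self.k
        lo, hi = 1, self.spss.num_strings
        # largest i with first_handle(i) <= h, where
        # first_handle(i) = p_i - (i-1)(k-1)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.P.access(mid) - (mid - 1) * (k - 1) <= h:
                lo = mid
            else:
                hi = mid - 1
        i = lo
        q = h + (i - 1) * (k - 1)
        return self.spss.packed.decode(q, k)

    # -- accounting --------------------------------------------------------
    def space_report(self) -> dict:
        """Component-wise logical bit counts and bits per k-mer."""
        pos_bits = self.tags.pos_bits
        skew_f = sum(p.f.size_bits() for p in self.heavy.partitions.values())
        skew_V = sum(
            len(p.V) * p.width_bits for p in self.heavy.partitions.values()
        )
        comps = {
            "S": 2 * self.N,
            "P": self.P.size_bits(),
            "P_select_overhead": self.P.select_overhead_bits(),
            "f": self.f.size_bits(),
            "T": self.tags.size_bits(),
            "L": len(self.light.L) * pos_bits,
            "G": len(self.light.G) * pos_bits,
            "H": len(self.heavy.H) * pos_bits,
            "skew_f": skew_f,
            "skew_V": skew_V,
        }
        total = sum(v for k_, v in comps.items() if k_ != "P_select_overhead")
        comps["total"] = total
        comps["bits_per_kmer"] = total / self.n
        comps["M"] = self.M
        comps["Z"] = self.Z
        comps["n"] = self.n
        comps["N"] = self.N
        comps["beta"] = 1 - self.n_singleton / self.M if self.M else 0.0
        comps["alpha"] = sum(len(p.V) for p in self.heavy.partitions.values())
        comps["max_loc"] = self.max_loc
        return comps

    # -- serialization (delegates) ------------------------------------------
    def save(self, path) -> None:
        from .io import save_index

        save_index(self, path)

    @classmethod
    def load(cls, path) -> "SsHashIndex":
        from .io import load_index

        return load_index(path)
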