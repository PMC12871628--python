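"""Minimal perfect hashing over integer key sets, by bucket placement.

Keys are hashed into buckets (about 3 keys per bucket on average); buckets
are processed from largest to smallest and each searches for a *pilot*
value under which all its keys land on distinct, still-free slots of the
global table of size M.  Size-1 buckets skip the search and are assigned
the remaining free slots directly (the pilot then encodes the slot).

Evaluation on a build key returns its unique slot in [1..M]; evaluation on
a foreign key is legal and returns an arbitrary in-range value — exactly
the contract a k-mer dictionary needs, since membership is verified
downstream against the text anyway.
"""

from __future__ import annotations

import numpy as np

from ._hash import MASK64, fold64, splitmix64, splitmix64_vec

_LAMBDA = 3.0  # average bucket size
_PILOT_LIMIT = 1 << 18
_BATCH = 64
_DIRECT = 1 << 48  # pilots >= this encode a direct slot assignment
_MAX_ATTEMPTS = 16


class MphfBuildError(RuntimeError):
    pass


class Mphf:
    def __init__(self, M: int, seed: int, salt: int, nbuckets: int, pilots: np.ndarray):
        self.M = M
        self.seed = seed
        self.salt = salt
        self.nbuckets = nbuckets
        self.pilots = pilots  # uint64[nbuckets]

    # -- hashing helpers -------------------------------------------------
    @staticmethod
    def _key_hash(key: int, salt: int) -> int:
        return splitmix64(fold64(key) ^ salt)

    @staticmethod
    def _pilot_const(salt: int, p: int) -> int:
        return splitmix64((salt + 1 + p) & MASK64)

    # -- construction ----------------------------------------------------
    @classmethod
    def build(cls, keys, seed: int = 0) -> "Mphf":
        keys = list(keys)
        M = len(keys)
        if M < 1:
            raise ValueError("need at least one key")
        if len(set(keys)) != M:
            raise ValueError("duplicate keys in MPHF build set")
        folded = np.fromiter((fold64(k) for k in keys), dtype=np.uint64, count=M)
        base = fold64(seed)
        for attempt in range(_MAX_ATTEMPTS):
            salt = splitmix64((base + attempt) & MASK64)
            result = cls._try_build(folded, M, salt)
            if result is not None:
                return cls(M, seed, salt, *result)
        raise MphfBuildError(
            f"MPHF construction failed after {_MAX_ATTEMPTS} attempts "
            f"for {M} keys; try a different seed"
        )

    @staticmethod
    def _try_build(folded: np.ndarray, M: int, salt: int):
        kh = splitmix64_vec(folded ^ np.uint64(salt))
        if len(np.unique(kh)) != M:
            return None  # 64-bit key-hash collision; re-salt
        nb = max(1, int(np.ceil(M / _LAMBDA)))
        bucket = (kh % np.uint64(nb)).astype(np.int64)
        order = np.argsort(bucket, kind="stable")
        bsorted = bucket[order]
        starts = np.searchsorted(bsorted, np.arange(nb))
        ends = np.searchsorted(bsorted, np.arange(nb), side="right")
        sizes = ends - starts
        # process larger buckets first; ties by bucket id for determinism
        proc = np.lexsort((np.arange(nb), -sizes))
        occupied = np.zeros(M, dtype=bool)
        pilots = np.zeros(nb, dtype=np.uint64)
        singles: list[int] = []
        uM = np.uint64(M)
        for b in proc:
            z = sizes[b]
            if z == 0:
                continue
            if z == 1:
                singles.append(b)
                continue
            bkh = kh[order[starts[b] : ends[b]]]
            placed = False
            for p0 in range(0, _PILOT_LIMIT, _BATCH):
                pcs = splitmix64_vec(
                    (np.uint64(salt) + np.uint64(1) + np.arange(p0, p0 + _BATCH, dtype=np.uint64))
                )
                posm = (splitmix64_vec(bkh[None, :] ^ pcs[:, None]) % uM).astype(np.int64)
                srt = np.sort(posm, axis=1)
                ok = np.all(np.diff(srt, axis=1) != 0, axis=1)
                ok &= ~np.any(occupied[posm], axis=1)
                hits = np.flatnonzero(ok)
                if len(hits):
                    row = int(hits[0])
                    occupied[posm[row]] = True
                    pilots[b] = p0 + row
                    placed = True
                    break
            if not placed:
                return None
        free = np.flatnonzero(~occupied)
        assert len(free) == len(singles)
        for slot, b in zip(free, singles):
            bkey = kh[order[starts[b]]]
            pilots[b] = np.uint64(_DIRECT + int(slot))
            _ = bkey  # slot assignment is positional; key plays no role
        return nb, pilots

    # -- evaluation ------------------------------------------------------
    def eval(self, key: int) -> int:
        """Map a key to [1..M]; bijective on the build set."""
        kh = self._key_hash(key, self.salt)
        b = kh % self.nbuckets
        p = int(self.pilots[b])
        if p >= _DIRECT:
            return (p - _DIRECT) + 1
        return splitmix64(kh ^ self._pilot_const(self.salt, p)) % self.M + 1

    __call__ = eval

    # -- accounting ------------------------------------------------------
    def bits_per_key(self) -> float:
        """Logical pilot storage per key (multi-bucket pilots at the width
        of the largest pilot; direct slots at ceil(log2 M) bits)."""
        pil = self.pilots
        direct = pil >= np.uint64(_DIRECT)
        n_direct = int(direct.sum())
        n_multi = len(pil) - n_direct
        max_pilot = int(pil[~direct].max()) if n_multi else 0
        w_multi = max(1, max_pilot.bit_length())
        w_direct = max(1, (self.M - 1).bit_length())
        return (n_multi * w_multi + n_direct * w_direct) / self.M

    def size_bits(self) -> int:
        return int(round(self.bits_per_key() * self.M))

    # -- serialization ---------------------------------------------------
    def state(self) -> dict:
        return {
            "M": self.M,
            "seed": self.seed,
            "salt": self.salt,
            "nbuckets": self.nbuckets,
            "pilots": self.pilots,
        }

    @classmethod
    def from_state(cls, st: dict) -> "Mphf":
        return cls(int(st["M"]), int(st["seed"]), int(st["salt"]),
                   int(st["nbuckets"]), np.asarray(st["pilots"], dtype=np.uint64))


def mphf_build(keys, seed: int = 0) -> Mphf:
    return Mphf.build(keys, seed)


def mphf_eval(f: Mphf, key: int) -> int:
    return f.eval(key)
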