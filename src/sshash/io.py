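"""File I/O: FASTA/FASTQ readers and writers, truth tables, and the
versioned binary index format.

FASTA parsing goes through Bio.SeqIO (multi-line records are fine; headers
are kept only for diagnostics).  FASTQ input may be gzip-compressed and is
decompressed incrementally — the reader is a generator and never
materializes the whole file.

Index format (little-endian): magic, version, a fixed header (k, m, mode,
order, l, r, seed, N, n, M, Z, tag width, ...), then the payload sections
(2-bit packed S, P, minimizer MPHF, tags, L, G, H, skew partitions), each a
length-prefixed byte block.  A CRC32 of the payload guards the load path.
"""

from __future__ import annotations

import gzip
import struct
import zlib
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

from .ef import EliasFanoArray
from .kmer import PackedSequence, Spss, pack_2bit, unpack_2bit
from .layout import HeavyStore, LightStore, SkewPartition, TagArray
from .minimizer import MinimizerScheme
from .mphf import Mphf

MAGIC = b"SSHIDX\x00\x01"
_MODES = ["regular", "canonical"]
_ORDERS = ["random", "lexicographic"]


# ---------------------------------------------------------------------------
# sequence files
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[str]:
    """All sequences of a (possibly gzipped) FASTA file, uppercased."""
    with _open_maybe_gzip(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, strings: list[str], prefix: str = "s") -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for i, s in enumerate(strings, start=1):
            fh.write(f">{prefix}{i}\n")
            for off in range(0, len(s), 80):
                fh.write(s[off : off + 80] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs, streaming; .gz handled on the fly."""
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


def write_fastq(path, reads, quality_char: str = "I") -> None:
    """``reads`` yields (name, seq); writes plain or gzipped by suffix."""
    with _open_maybe_gzip(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth_table(path, truth: dict[int, tuple[int, int]], k: int) -> None:
    """k-mer -> (string id, position) as TSV, language-agnostic."""
    from .kmer import decode_code

    with open(path, "w") as fh:
        fh.write("kmer\tstring_id\tposition\n")
        for code in sorted(truth):
            sid, pos = truth[code]
            fh.write(f"{decode_code(code, k)}\t{sid}\t{pos}\n")


def read_truth_table(path, k: int) -> dict[int, tuple[int, int]]:
    from .kmer import encode_kmer

    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            kmer, sid, pos = line.rstrip("\n").split("\t")
            out[encode_kmer(kmer, k).code] = (int(sid), int(pos))
    return out


# ---------------------------------------------------------------------------
# index serialization
# ---------------------------------------------------------------------------

def _block(data: bytes) -> bytes:
    return struct.pack("<Q", len(data)) + data


def _arr_block(a: np.ndarray, dtype) -> bytes:
    return _block(np.ascontiguousarray(a, dtype=dtype).tobytes())


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.off = 0

    def block(self) -> bytes:
        (n,) = struct.unpack_from("<Q", self.data, self.off)
        self.off += 8
        out = self.data[self.off : self.off + n]
        self.off += n
        return out

    def arr(self, dtype) -> np.ndarray:
        return np.frombuffer(self.block(), dtype=dtype).copy()


def _mphf_bytes(f: Mphf) -> bytes:
    head = struct.pack("<QqQQ", f.M, f.seed, f.salt, f.nbuckets)
    return _block(head + _arr_block(f.pilots, np.uint64))


def _mphf_from(reader: _Reader) -> Mphf:
    blk = _Reader(reader.block())
    M, seed, salt, nb = struct.unpack_from("<QqQQ", blk.data, 0)
    blk.off = 32
    pilots = blk.arr(np.uint64)
    return Mphf(M, seed, salt, nb, pilots)


def save_index(index, path) -> None:
    from .index import SsHashIndex  # noqa: F401  (type reference)

    sections = []
    sections.append(_block(pack_2bit(index.spss.packed.codes)))
    sections.append(_arr_block(index.spss.starts, np.int64))
    sections.append(_mphf_bytes(index.f))
    sections.append(_arr_block(index.tags.tags, np.uint64))
    sections.append(_arr_block(index.light.L, np.int64))
    sections.append(_arr_block(index.light.G, np.int64))
    sections.append(_arr_block(index.heavy.H, np.int64))
    parts = sorted(index.heavy.partitions)
    sections.append(struct.pack("<Q", len(parts)))
    for i in parts:
        p = index.heavy.partitions[i]
        sections.append(struct.pack("<QQ", i, p.width_bits))
        sections.append(_mphf_bytes(p.f))
        sections.append(_arr_block(p.V, np.int64))
    payload = b"".join(sections)

    header = struct.pack(
        "<8sHHBBHHqQQQQQQQ",
        MAGIC,
        index.k,
        index.m,
        _MODES.index(index.mode),
        _ORDERS.index(index.scheme.order),
        index.l,
        index.r,
        index.seed,
        index.N,
        index.n,
        index.M,
        index.Z,
        index.tags.width,
        index.max_loc,
        zlib.crc32(payload),
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)


def load_index(path):
    from .index import SsHashIndex

    raw = Path(path).read_bytes()
    hsize = struct.calcsize("<8sHHBBHHqQQQQQQQ")
    (magic, k, m, mode_i, order_i, l, r, seed, N, n, M, Z, tag_width,
     max_loc, crc) = struct.unpack_from("<8sHHBBHHqQQQQQQQ", raw, 0)
    if magic != MAGIC:
        raise ValueError(f"{path}: not an index file (bad magic)")
    payload = raw[hsize:]
    if zlib.crc32(payload) != crc:
        raise ValueError(f"{path}: payload checksum mismatch")
    rd = _Reader(payload)

    codes = unpack_2bit(rd.block(), N)
    starts = rd.arr(np.int64)
    f = _mphf_from(rd)
    tags_arr = rd.arr(np.uint64)
    L = rd.arr(np.int64)
    G = rd.arr(np.int64)
    H = rd.arr(np.int64)
    (nparts,) = struct.unpack_from("<Q", rd.data, rd.off)
    rd.off += 8
    partitions = {}
    for _ in range(nparts):
        i, width_bits = struct.unpack_from("<QQ", rd.data, rd.off)
        rd.off += 16
        fi = _mphf_from(rd)
        V = rd.arr(np.int64)
        partitions[int(i)] = SkewPartition(int(i), fi, V, int(width_bits))

    mode = _MODES[mode_i]
    scheme = MinimizerScheme(k, m, _ORDERS[order_i], seed)
    spss = Spss(PackedSequence(codes), starts, k)
    pos_bits = max(1, N.bit_length())
    tags = TagArray(int(tag_width), pos_bits, l, tags_arr)
    light = LightStore(l, L, G)
    heavy = HeavyStore(H, partitions)
    P = EliasFanoArray.from_sorted(starts, U=N + 1)
    n_singleton = int(np.sum((tags_arr & np.uint64(1)) == 0))
    return SsHashIndex(
        spss, scheme, mode, P, f, tags, light, heavy, l, r, int(Z),
        n_singleton, seed, int(max_loc),
    )
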