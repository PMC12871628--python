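import numpy as np
import pytest

from sshash import (
    MinimizerScheme,
    cmini,
    encode_kmer,
    mini,
    parse_super_kmers,
    rc_position,
    reverse_complement,
    streaming_minimizers,
)
from sshash.kmer import encode_to_codes
from sshash.minimizer import streaming_minimizer_pairs


def mini_oracle(s: str, m: int, scheme: MinimizerScheme):
    """Full scan: order-minimal m-mer, leftmost occurrence on ties."""
    best = None
    best_pos = None
    for p in range(len(s) - m + 1):
        pair = scheme.order_pair(encode_kmer(s[p : p + m]).code)
        if best is None or pair < best:
            best, best_pos = pair, p + 1
    return best[1], best_pos


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMini:
    @pytest.mark.parametrize(
        "kmer,expected_mmer,expected_pos",
        [
            ("TCAAGTT", "AAG", 3),
            ("AACTTGA", "AAC", 1),
            ("TTGGCCT", "CCT", 5),
        ],
    )
    def test_lexicographic_worked_examples(self, lex7, kmer, expected_mmer, expected_pos):
        h = mini(encode_kmer(kmer), lex7)
        assert str(h.mmer) == expected_mmer
        assert h.pos == expected_pos

    @pytest.mark.parametrize("order", ["lexicographic", "random"])
    def test_agrees_with_full_scan_oracle(self, order):
        rng = np.random.default_rng(0)
        scheme = MinimizerScheme(21, 8, order, seed=4)
        for _ in range(300):
            s = random_dna(rng, 21)
            h = mini(encode_kmer(s), scheme)
            mmer, pos = mini_oracle(s, 8, scheme)
            assert (h.mmer.code, h.pos) == (mmer, pos)

    def test_leftmost_tie_breaking(self):
        scheme = MinimizerScheme(7, 3, "lexicographic")
        h = mini(encode_kmer("AACAACG"), scheme)  # AAC occurs at 1 and 4
        assert (str(h.mmer), h.pos) == ("AAC", 1)


class TestCmini:
    def test_canonical_position_worked_example(self, lex7):
        h = cmini(encode_kmer("TCAAGTT"), lex7)
        assert (str(h.mmer), h.pos) == ("AAC", 5)

    def test_reverse_strand_minimizer_worked_example(self, lex7):
        h = cmini(encode_kmer("TTGGCCT"), lex7)
        assert str(h.mmer) == "AGG"

    @pytest.mark.parametrize("order", ["lexicographic", "random"])
    def test_value_is_strand_symmetric(self, order):
        rng = np.random.default_rng(1)
        scheme = MinimizerScheme(15, 5, order, seed=9)
        for _ in range(200):
            x = encode_kmer(random_dna(rng, 15))
            a = cmini(x, scheme)
            b = cmini(reverse_complement(x), scheme)
            assert a.mmer == b.mmer


class TestRcPosition:
    def test_worked_example(self):
        assert rc_position(7, 3, 1) == 5

    def test_end_to_end_flip(self):
        for k, m in ((7, 3), (31, 13), (15, 14)):
            assert rc_position(k, m, 1) == k - m + 1

    def test_involution(self):
        for pos in range(1, 7 - 3 + 2):
            assert rc_position(7, 3, rc_position(7, 3, pos)) == pos

    def test_string_search_oracle(self):
        # where a k-mer's m-mer has a unique occurrence, the position of its
        # rc in the rc k-mer is found by plain string search
        rng = np.random.default_rng(2)
        scheme = MinimizerScheme(21, 7, "random", seed=1)
        checked = 0
        while checked < 100:
            s = random_dna(rng, 21)
            h = mini(encode_kmer(s), scheme)
            mm = str(h.mmer)
            if s.count(mm) != 1:
                continue
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            rc_s = "".join(comp[c] for c in reversed(s))
            rc_mm = "".join(comp[c] for c in reversed(mm))
            assert rc_s.index(rc_mm) + 1 == rc_position(21, 7, h.pos)
            checked += 1


class TestSuperKmers:
    def test_single_super_kmer_when_occurrence_is_shared(self):
        scheme = MinimizerScheme(7, 3, "lexicographic")
        # AAA at position 3 is minimal for and shared by every window
        sks = parse_super_kmers("GTAAACGTC", scheme)
        assert len(sks) == 1
        assert sks[0].n_kmers == 3

    @pytest.mark.parametrize("mode", ["regular", "canonical"])
    def test_exact_tiling_and_span_bound(self, mode):
        rng = np.random.default_rng(3)
        scheme = MinimizerScheme(31, 13, "random", seed=7)
        for _ in range(5):
            s = random_dna(rng, 500)
            sks = parse_super_kmers(s, scheme, mode)
            assert sum(sk.n_kmers for sk in sks) == len(s) - 31 + 1
            assert all(sk.n_kmers <= 31 - 13 + 1 for sk in sks)
            # windows tile contiguously
            assert sks[0].win_start == 1
            for a, b in zip(sks, sks[1:]):
                assert b.win_start == a.win_end + 1

    def test_density_matches_random_minimizer_expectation(self):
        # distinct sampled positions ~ 2/(k-m+2) * (N-m+1), within 10%
        k, m, N = 31, 13, 100_000
        expectation = 2 / (k - m + 2) * (N - m + 1)
        rng = np.random.default_rng(4)
        for seed in (1, 2, 3):
            scheme = MinimizerScheme(k, m, "random", seed=seed)
            s = random_dna(rng, N)
            sks = parse_super_kmers(s, scheme)
            distinct = len({sk.occ for sk in sks})
            assert abs(distinct - expectation) / expectation < 0.10


class TestStreaming:
    @pytest.mark.parametrize("mode", ["regular", "canonical"])
    @pytest.mark.parametrize("order", ["lexicographic", "random"])
    def test_equals_from_scratch_per_window(self, mode, order):
        rng = np.random.default_rng(5)
        scheme = MinimizerScheme(15, 4, order, seed=2)
        for _ in range(30):
            s = random_dna(rng, 80)
            hits = list(streaming_minimizers(s, scheme, mode))
            for w, h in enumerate(hits):
                x = encode_kmer(s[w : w + 15])
                ref = mini(x, scheme) if mode == "regular" else cmini(x, scheme)
                assert (h.mmer, h.pos) == (ref.mmer, ref.pos), (s, w)

    def test_constant_sequence(self):
        scheme = MinimizerScheme(7, 3, "lexicographic")
        for h in streaming_minimizers("A" * 20, scheme):
            assert (str(h.mmer), h.pos) == ("AAA", 1)

    def test_reverse_strand_minimizer_maintained(self):
        # the per-window pair must report mini(rc(window)) exactly
        rng = np.random.default_rng(6)
        scheme = MinimizerScheme(15, 4, "random", seed=8)
        s = random_dna(rng, 120)
        codes = encode_to_codes(s)
        for w, (fc, fp, rc, rp) in enumerate(streaming_minimizer_pairs(codes, scheme)):
            x = encode_kmer(s[w : w + 15])
            fref = mini(x, scheme)
            rref = mini(reverse_complement(x), scheme)
            assert (fc, fp) == (fref.mmer.code, fref.pos)
            assert (rc, rp) == (rref.mmer.code, rref.pos)
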