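import random

import pytest

from sshash import (
    MinimizerScheme,
    SsHashIndex,
    SyntheticSpssSpec,
    displace_canonical,
    displace_regular,
    encode_kmer,
    gen_spss,
    mini,
    parse_super_kmers,
)
from sshash.kmer import canonical_code, decode_code, rc_code


class TestDisplacements:
    def test_regular_foreign_minimizer_candidate(self, lex7):
        # query AACTTGA, stored occurrence j=27: q = 27 - 1 + 1 = 27
        hit = mini(encode_kmer("AACTTGA"), lex7)
        assert displace_regular(27, hit) == 27

    def test_regular_reverse_pass_candidate(self, lex7):
        # query TCAAGTT, occurrence j=3: q = 3 - 3 + 1 = 1
        hit = mini(encode_kmer("TCAAGTT"), lex7)
        assert displace_regular(3, hit) == 1

    def test_identity_when_minimizer_leads(self, lex7):
        hit = mini(encode_kmer("AACTTGA"), lex7)
        for j in (1, 5, 100):
            assert displace_regular(j, hit) == j

    def test_canonical_two_candidates_worked_example(self, lex7):
        # TTGGCCT falls in the MINI(x) > MINI(rc(x)) case: positions {10, 6}
        cands = displace_canonical(encode_kmer("TTGGCCT"), 10, lex7)
        assert {q for q, _ in cands} == {10, 6}

    def test_palindromic_minimizer_emits_four(self, lex7):
        # MINI(AAACTTT) = MINI(rc(AAACTTT)) = AAA: the equal-minimizer case
        # checks all four displacements (here all distinct)
        from sshash import reverse_complement

        x = encode_kmer("AAACTTT")
        f = mini(x, lex7)
        r = mini(reverse_complement(x), lex7)
        assert f.mmer == r.mmer
        cands = displace_canonical(x, 50, lex7)
        assert len(cands) == 4
        assert {q for q, _ in cands} == {50, 46}
        assert {o for _, o in cands} == {+1, -1}

    def test_out_of_bounds_candidates_dropped(self, lex7):
        cands = displace_canonical(encode_kmer("TTGGCCT"), 2, lex7)
        assert all(q >= 1 for q, _ in cands)

    @pytest.mark.parametrize("mode", ["regular", "canonical"])
    def test_true_position_always_among_candidates(self, mode, small_spss):
        # for every indexed k-mer, the displacement of its stored occurrence
        # must contain the true start position
        idx = SsHashIndex.build(small_spss.strings, k=15, m=7, mode=mode, seed=3)
        spss = idx.spss
        for code, (sid, pos) in list(small_spss.truth.items())[:800]:
            p_i, _ = spss.string_bounds(sid)
            q_true = p_i + pos - 1
            res = idx.lookup_code(code)
            assert res.position == q_true


class TestBuild:
    def test_single_occurrence_string(self):
        # all k-mers share one minimizer occurrence -> M=1 singleton
        idx = SsHashIndex.build(["GTAAACGTC"], k=7, m=3, order="lexicographic")
        assert idx.M == 1
        assert idx.Z == 1
        assert idx.n_singleton == 1

    def test_fig_scale_spss_has_21_kmers(self):
        data = gen_spss(SyntheticSpssSpec(33, 2, 7, seed=2, lengths=(21, 12)))
        idx = SsHashIndex.build(data.strings, k=7, m=3, order="lexicographic")
        assert idx.n == 21
        handles = sorted(idx.lookup_code(c).handle for c in data.truth)
        assert handles == list(range(1, 22))

    def test_loc_sizes_sum_to_super_kmer_count(self, small_spss):
        idx = SsHashIndex.build(small_spss.strings, k=15, m=7, seed=3)
        total_sks = sum(
            len(parse_super_kmers(s, idx.scheme, "regular"))
            for s in small_spss.strings
        )
        assert idx.Z == total_sks

    def test_m_ge_k_rejected(self):
        with pytest.raises(ValueError, match="m < k"):
            SsHashIndex.build(["ACGTACG"], k=7, m=7)


class TestLookup:
    def test_wrong_length_is_an_error_not_a_miss(self, small_index):
        with pytest.raises(ValueError):
            small_index.lookup("ACGT")

    def test_worked_example_rc_query(self, worked_example_strings):
        idx = SsHashIndex.build(
            worked_example_strings, k=7, m=3, order="lexicographic"
        )
        res = idx.lookup("AACTTGA")  # rc of the first indexed k-mer
        assert res.is_hit
        assert (res.position, res.orientation, res.handle) == (1, -1, 1)
        fwd = idx.lookup("TCAAGTT")
        assert (fwd.position, fwd.orientation, fwd.handle) == (1, +1, 1)

    def test_bijection_and_order_preservation(self, small_index, small_spss):
        handles = {}
        for code in small_spss.truth:
            handles[code] = small_index.lookup_code(code).handle
        assert sorted(handles.values()) == list(range(1, small_index.n + 1))
        # consecutive k-mers of a string get consecutive handles
        k = small_index.k
        for s in small_spss.strings[:2]:
            prev = None
            for pos in range(len(s) - k + 1):
                h = handles[encode_kmer(s[pos : pos + k]).code]
                if prev is not None:
                    assert h == prev + 1
                prev = h

    def test_strand_coherence(self, small_index, small_spss):
        for code in list(small_spss.truth)[:500]:
            a = small_index.lookup_code(code)
            b = small_index.lookup_code(rc_code(code, 15))
            assert a.handle == b.handle
            assert a.orientation == -b.orientation

    def test_negative_soundness(self, small_index, small_spss):
        rng = random.Random(11)
        canon = small_spss.canonical_set()
        tried = 0
        while tried < 5000:
            c = rng.randrange(4**15)
            if canonical_code(c, 15) in canon:
                continue
            res = small_index.lookup_code(c)
            assert not res.is_hit
            tried += 1

    def test_boundary_windows_never_cross_strings(self):
        # adversarial: string 2 starts with the suffix of string 1, so a
        # boundary-crossing window would spell an indexed-looking k-mer
        s1 = "ACGGTCACCTA"
        s2 = "CCTAGGATTAC"
        idx = SsHashIndex.build([s1, s2], k=7, m=3, order="lexicographic")
        concat = s1 + s2
        k = 7
        indexed = {s1[i : i + k] for i in range(len(s1) - k + 1)}
        indexed |= {s2[i : i + k] for i in range(len(s2) - k + 1)}
        for i in range(len(concat) - k + 1):
            w = concat[i : i + k]
            res = idx.lookup(w)
            if res.is_hit:
                # the returned window must lie inside one string
                p2 = len(s1) + 1
                assert res.position + k - 1 < p2 or res.position >= p2

    def test_heavy_path_lookup(self, repetitive_index, repetitive_spss):
        assert repetitive_index.heavy.partitions  # skew index is in use
        handles = set()
        for code in repetitive_spss.truth:
            res = repetitive_index.lookup_code(code)
            assert res.is_hit
            handles.add(res.handle)
        assert handles == set(range(1, repetitive_index.n + 1))


class TestAccess:
    def test_round_trip_up_to_rc(self, small_index, small_spss):
        for code in list(small_spss.truth)[:500]:
            res = small_index.lookup_code(code)
            got = small_index.access(res.handle)
            assert got in (decode_code(code, 15), decode_code(rc_code(code, 15), 15))

    def test_first_handle_is_first_kmer(self, small_index, small_spss):
        assert small_index.access(1) == small_spss.strings[0][:15]

    def test_out_of_range_returns_empty(self, small_index):
        assert small_index.access(0) == ""
        assert small_index.access(small_index.n + 1) == ""


class TestSpaceReport:
    def test_exactly_determined_terms(self, small_index):
        rep = small_index.space_report()
        assert rep["S"] == 2 * small_index.N
        assert rep["T"] == small_index.M * small_index.tags.width
        pos_bits = small_index.tags.pos_bits
        stored = (rep["L"] + rep["H"]) // pos_bits
        assert stored == small_index.Z - small_index.n_singleton

    def test_no_heavy_means_no_skew_bits(self, small_index):
        rep = small_index.space_report()
        if not small_index.heavy.partitions:
            assert rep["skew_f"] == 0 and rep["skew_V"] == 0

    @staticmethod
    def _check_closed_form_bound(idx):
        # the structure-level bound 2N + (Z+alpha)w + M(1+beta*w) + (MPHF
        # bits) + EF(P) + G, with the implementation's measured MPHF costs
        # substituted for the asymptotic terms, must dominate the total
        rep = idx.space_report()
        w = idx.tags.pos_bits
        bound = (
            2 * idx.N
            + (idx.Z + rep["alpha"]) * w
            + idx.M * (1 + rep["beta"] * w)
            + rep["skew_f"]
            + rep["f"]
            + idx.P.size_bits()
            + rep["G"]
            # tag words widen beyond pos_bits+1 only in the tiny-N corner;
            # account for the excess explicitly
            + idx.M * (idx.tags.width - (w + 1))
        )
        assert rep["total"] <= bound

    def test_total_within_closed_form_bound_sparse(self, small_index):
        self._check_closed_form_bound(small_index)

    def test_total_within_closed_form_bound_skewed(self, repetitive_index):
        self._check_closed_form_bound(repetitive_index)
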