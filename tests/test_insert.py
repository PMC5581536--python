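"""Insert-match trimming: overlap detection, confirmation, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from pairtrim.insertmatch import (
    CorrectionPolicy,
    InsertMatchParams,
    TieMode,
    confirm_adapters,
    error_correct,
    find_insert_candidates,
    insert_trim_pair,
    merge_pair,
    overwrite_poor_read,
    random_match_prob,
    reverse_complement,
    reverse_complement_record,
    _min_matches_table,
)
from pairtrim.records import ReadRecord

from _oracles import oracle_insert_shift_scan
from conftest import make_read, random_seq

RL = 125


def simulate_clean_pair(rng, insert_len, params, read_len=RL, name="p"):
    """Error-free pair following the library geometry."""
    insert = random_seq(rng, insert_len)
    t1 = insert + params.adapter1.sequence + random_seq(rng, read_len)
    t2 = (reverse_complement(insert) + params.adapter2.sequence
          + random_seq(rng, read_len))
    return (make_read(t1[:read_len], name, mate=1),
            make_read(t2[:read_len], name, mate=2))


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [
        ("ACGT", "ACGT"), ("AAYC", "GRTT"), ("", ""),
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGTUNRYSWKMBDHVacgtn", max_size=60))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_involution(self, s):
        if "U" in s.upper():  # U complements to A, which returns as T
            s = s.replace("U", "T").replace("u", "t")
        assert reverse_complement(reverse_complement(s)) == s

    def test_record_reverses_qualities(self):
        r = ReadRecord("x", "ACGG", np.array([10, 20, 30, 40]))
        rc = reverse_complement_record(r)
        assert rc.bases == "CCGT"
        assert list(rc.qualities) == [40, 30, 20, 10]

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            reverse_complement("AC!T")


class TestRandomMatchProb:
    def test_zero_matches_is_certain(self):
        assert random_match_prob(0, 17) == 1.0

    def test_all_match_single_term(self):
        assert random_match_prob(4, 4) == pytest.approx(0.25 ** 4)

    def test_against_direct_summation(self):
        # k=8, n=10: direct binomial sum of the three upper terms
        expect = sum(comb(10, i, exact=True) * 0.25 ** i * 0.75 ** (10 - i)
                     for i in range(8, 11))
        assert expect == pytest.approx(4.158e-4, rel=1e-3)
        assert random_match_prob(8, 10) == pytest.approx(expect, rel=1e-12)

    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError):
            random_match_prob(5, 4)

    def test_min_matches_table_matches_definition(self):
        table = _min_matches_table(40, 0.25, 1e-6)
        for n in range(1, 41):
            passing = [k for k in range(n + 1)
                       if random_match_prob(k, n) <= 1e-6]
            expect = passing[0] if passing else n + 1
            assert table[n] == expect, n


class TestFindCandidates:
    def test_clean_pair_top_candidate_is_truth(self, rng):
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 100, params)
        top = find_insert_candidates(r1, r2, params)[0]
        assert (top.insert_length, top.overlap_len, top.mismatches) \
            == (100, 100, 0)

    def test_unrelated_reads_yield_nothing(self, rng):
        params = InsertMatchParams()
        for _ in range(100):
            r1 = make_read(random_seq(rng, RL))
            r2 = make_read(random_seq(rng, RL))
            assert find_insert_candidates(r1, r2, params) == []

    def test_long_insert_partial_overlap_geometry(self, rng):
        params = InsertMatchParams()
        insert = random_seq(rng, 150)
        r1 = make_read(insert[:RL])
        r2 = make_read(reverse_complement(insert)[:RL])
        top = find_insert_candidates(r1, r2, params)[0]
        assert (top.insert_length, top.overlap_len) == (150, 100)
        # trim points beyond the read ends: nothing would be trimmed
        assert top.insert_length >= RL

    def test_agrees_with_naive_shift_scan(self, rng):
        """Correlation-based scan equals a per-shift counting oracle."""
        params = InsertMatchParams(min_insert_overlap=1,
                                   max_mismatch_frac=1.0,
                                   max_random_match_prob=1.0)
        for _ in range(25):
            n1 = int(rng.integers(5, 30))
            n2 = int(rng.integers(5, 30))
            r1 = make_read(random_seq(rng, n1, "ACGTN"))
            r2 = make_read(random_seq(rng, n2, "ACGTN"))
            expected = oracle_insert_shift_scan(
                r1.bases, reverse_complement(r2.bases))
            got = {c.insert_length: (c.overlap_len, c.matches, c.mismatches)
                   for c in find_insert_candidates(r1, r2, params)}
            assert got == expected

    def test_sorted_by_decreasing_overlap(self, rng):
        params = InsertMatchParams(min_insert_overlap=1,
                                   max_mismatch_frac=1.0,
                                   max_random_match_prob=1.0)
        r1 = make_read(random_seq(rng, 30))
        r2 = make_read(random_seq(rng, 30))
        cands = find_insert_candidates(r1, r2, params)
        overlaps = [c.overlap_len for c in cands]
        assert overlaps == sorted(overlaps, reverse=True)


class TestConfirmAdapters:
    def test_exact_overhangs_confirm_both(self, rng):
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 100, params)
        cand = find_insert_candidates(r1, r2, params)[0]
        res = confirm_adapters(cand, r1, r2, params)
        assert res.adapter1_confirmed and res.adapter2_confirmed
        assert res.insert_length == 100

    def test_single_confirmation_trims_both(self, rng):
        """Corrupting the read-2 overhang still fixes the symmetric trim
        point through the read-1 adapter."""
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 100, params)
        garbled = r2.bases[:100] + "T" * 25
        r2 = make_read(garbled, r2.name, mate=2)
        cand = find_insert_candidates(r1, r2, params)[0]
        res = confirm_adapters(cand, r1, r2, params)
        assert res is not None
        assert res.adapter1_confirmed and not res.adapter2_confirmed

    def test_random_overhangs_reject(self, rng):
        params = InsertMatchParams()
        insert = random_seq(rng, 100)
        r1 = make_read((insert + random_seq(rng, 25)))
        r2 = make_read((reverse_complement(insert) + random_seq(rng, 25)))
        cand = find_insert_candidates(r1, r2, params)[0]
        assert confirm_adapters(cand, r1, r2, params) is None


class TestErrorCorrect:
    def _pair_with_mismatch(self, q1=30, q2=10):
        # insert of length 4; read1 carries A at insert position 1 while
        # read2's complement carries G there (read-2 index 2 = L-1-i)
        r1 = ReadRecord("p", "CAGT", np.array([30, q1, 30, 30]), 1)
        r2 = ReadRecord("p", reverse_complement("CGGT"),
                        np.array([30, 30, q2, 30]), 2)
        return r1, r2

    def test_higher_quality_base_wins(self):
        from pairtrim.insertmatch import InsertMatchResult
        r1, r2 = self._pair_with_mismatch(q1=30, q2=10)
        res = InsertMatchResult(4, 4, 3, 1, 1e-7)
        c1, c2, n = error_correct(r1, r2, res,
                                  CorrectionPolicy(mode=TieMode.BEST_READ))
        assert n == 1
        assert c1.bases == "CAGT"                       # read1 untouched
        assert reverse_complement(c2.bases) == "CAGT"   # read2 corrected
        # consensus quality is the max of the two
        assert c2.qualities[::-1][1] == 30

    def test_tie_to_n(self):
        from pairtrim.insertmatch import InsertMatchResult
        r1, r2 = self._pair_with_mismatch(q1=20, q2=20)
        res = InsertMatchResult(4, 4, 3, 1, 1e-7)
        c1, c2, n = error_correct(r1, r2, res,
                                  CorrectionPolicy(mode=TieMode.TO_N))
        assert n == 2
        assert c1.bases[1] == "N" and c2.bases[::-1][1] == "N"

    def test_identical_overlap_is_identity(self, rng):
        from pairtrim.insertmatch import InsertMatchResult
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 60, params)
        res = InsertMatchResult(60, 60, 60, 0, 0.0)
        c1, c2, n = error_correct(r1, r2, res,
                                  CorrectionPolicy(mode=TieMode.BEST_READ))
        assert n == 0 and c1.bases == r1.bases and c2.bases == r2.bases

    def test_none_mode_untouched(self):
        from pairtrim.insertmatch import InsertMatchResult
        r1, r2 = self._pair_with_mismatch()
        res = InsertMatchResult(4, 4, 3, 1, 1e-7)
        c1, c2, n = error_correct(r1, r2, res, CorrectionPolicy())
        assert n == 0 and c1 is r1 and c2 is r2

    def test_correction_never_decreases_quality(self, rng):
        from pairtrim.insertmatch import InsertMatchResult
        for _ in range(20):
            L = 30
            insert = random_seq(rng, L)
            q1 = rng.integers(2, 41, L).astype(np.uint8)
            q2 = rng.integers(2, 41, L).astype(np.uint8)
            # sprinkle disagreements
            b1 = list(insert)
            for pos in rng.integers(0, L, 5):
                b1[pos] = "ACGT"[(("ACGT".index(b1[pos])) + 1) % 4]
            r1 = ReadRecord("p", "".join(b1), q1, 1)
            r2 = ReadRecord("p", reverse_complement(insert),
                            q2[::-1].copy(), 2)
            res = InsertMatchResult(L, L, L - 5, 5, 0.0)
            c1, c2, _ = error_correct(
                r1, r2, res, CorrectionPolicy(mode=TieMode.BEST_READ))
            assert np.all(c1.qualities >= r1.qualities)
            assert np.all(c2.qualities >= r2.qualities)


class TestOverwrite:
    def test_poor_mate_is_replaced_over_overlap(self, rng):
        from pairtrim.insertmatch import InsertMatchResult
        insert = random_seq(rng, 50)
        r1 = make_read(insert, quality=35, mate=1)
        r2 = ReadRecord("p", reverse_complement(random_seq(rng, 50)),
                        np.full(50, 8, dtype=np.uint8), 2)
        res = InsertMatchResult(50, 50, 40, 10, 1e-8)
        c1, c2, fired = overwrite_poor_read(r1, r2, res, 3.0)
        assert fired
        assert reverse_complement(c2.bases) == insert
        assert c1.bases == insert

    def test_similar_qualities_do_not_fire(self, rng):
        from pairtrim.insertmatch import InsertMatchResult
        r1 = make_read(random_seq(rng, 50), quality=30)
        r2 = make_read(random_seq(rng, 50), quality=28)
        res = InsertMatchResult(50, 50, 50, 0, 0.0)
        _, _, fired = overwrite_poor_read(r1, r2, res, 3.0)
        assert not fired


class TestMerge:
    def test_short_insert_merges_to_insert_length(self, rng):
        params = InsertMatchParams()
        insert = random_seq(rng, 100)
        r1 = make_read((insert + params.adapter1.sequence)[:RL])
        r2 = make_read((reverse_complement(insert)
                        + params.adapter2.sequence)[:RL])
        out = insert_trim_pair(r1, r2, params,
                               CorrectionPolicy(mode=TieMode.BEST_READ,
                                                merge_pairs=True))
        assert out.merged is not None
        assert len(out.merged) == 100
        assert out.merged.bases == insert

    def test_long_insert_merges_to_full_length(self, rng):
        from pairtrim.insertmatch import InsertMatchResult
        insert = random_seq(rng, 150)
        r1 = make_read(insert[:RL])
        r2 = make_read(reverse_complement(insert)[:RL])
        res = InsertMatchResult(150, 100, 100, 0, 0.0)
        merged = merge_pair(r1, r2, res)
        assert len(merged) == 150
        assert merged.bases == insert

    def test_disagreement_resolved_like_error_correct(self):
        from pairtrim.insertmatch import InsertMatchResult
        r1 = ReadRecord("p", "CAGT", np.array([30, 35, 30, 30]), 1)
        r2 = ReadRecord("p", reverse_complement("CGGT"),
                        np.array([30, 30, 10, 30])[::-1].copy(), 2)
        res = InsertMatchResult(4, 4, 3, 1, 1e-7)
        merged = merge_pair(r1, r2, res)
        assert merged.bases == "CAGT"  # q35 beats q10


class TestInsertTrimPair:
    def test_clean_pair_trims_symmetrically(self, rng):
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 100, params)
        out = insert_trim_pair(r1, r2, params)
        assert out.tag == "insert"
        assert len(out.read1) == len(out.read2) == 100

    def test_adapter_dimer_falls_back_and_trims_to_zero(self, rng):
        params = InsertMatchParams()
        r1 = make_read((params.adapter1.sequence + random_seq(rng, RL))[:RL])
        r2 = make_read((params.adapter2.sequence + random_seq(rng, RL))[:RL])
        out = insert_trim_pair(r1, r2, params)
        assert out.tag == "fallback"
        assert len(out.read1) == 0 and len(out.read2) == 0

    def test_adapter_free_long_insert_unchanged(self, rng):
        params = InsertMatchParams()
        insert = random_seq(rng, 300)
        r1 = make_read(insert[:RL])
        r2 = make_read(reverse_complement(insert)[:RL])
        out = insert_trim_pair(r1, r2, params)
        assert len(out.read1) == RL and len(out.read2) == RL

    def test_exact_recovery_over_insert_lengths(self, rng):
        """Error-free pairs: the detected insert length equals the truth
        for every insert length from the overlap minimum to read length-1
        (spot-checked here; exhaustively in the acceptance suite)."""
        params = InsertMatchParams()
        for L in list(range(10, 125, 7)) + [10, 124]:
            r1, r2 = simulate_clean_pair(rng, L, params)
            out = insert_trim_pair(r1, r2, params)
            assert out.tag == "insert" and out.result.insert_length == L
            assert len(out.read1) == len(out.read2) == L

    def test_symmetry_invariant(self, rng):
        """Whenever the insert path fires, both mates end up the same
        length (the insert length, capped at the read length)."""
        params = InsertMatchParams()
        for _ in range(50):
            L = int(rng.integers(10, 240))
            if L < RL:
                r1, r2 = simulate_clean_pair(rng, L, params)
            else:
                insert = random_seq(rng, L)
                r1 = make_read(insert[:RL])
                r2 = make_read(reverse_complement(insert)[:RL])
            out = insert_trim_pair(r1, r2, params)
            if out.tag == "insert":
                assert len(out.read1) == len(out.read2) \
                    == min(RL, out.result.insert_length)

    def test_names_preserved_through_paths(self, rng):
        params = InsertMatchParams()
        r1, r2 = simulate_clean_pair(rng, 80, params, name="pair1")
        out = insert_trim_pair(r1, r2, params)
        assert out.read1.name == out.read2.name == "pair1"
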