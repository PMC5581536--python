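"""Semi-global alignment: IUPAC handling, acceptance rule, oracle checks."""

import numpy as np
import pytest

from pairtrim.align import (
    AdapterEnd,
    AdapterSpec,
    compatible,
    encode_iupac,
    hamming_align,
    semiglobal_align,
    trim_by_location,
)

from _oracles import oracle_edit_distances_back, oracle_semiglobal
from conftest import make_read, random_seq


class TestIupac:
    @pytest.mark.parametrize("symbol, bits", [
        ("A", {"A"}), ("N", {"A", "C", "G", "T"}),
        ("H", {"A", "C", "T"}), ("Y", {"C", "T"}),
    ])
    def test_masks(self, symbol, bits):
        mask = encode_iupac(symbol)
        decoded = {b for b, bit in zip("ACGT", (1, 2, 4, 8)) if mask & bit}
        assert decoded == bits

    def test_compatibility_is_set_intersection(self):
        assert compatible("Y", "H")        # share C, T
        assert not compatible("A", "Y")
        assert compatible("n", "a")        # case-insensitive

    def test_unknown_character_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            encode_iupac("X")
        with pytest.raises(ValueError, match="position 2"):
            AdapterSpec("AGXT")


class TestSemiglobalExamples:
    def test_exact_suffix_occurrence(self):
        loc = semiglobal_align(AdapterSpec("AGATCGGAA"),
                               make_read("CCCCCAGATCGGAA"))
        assert (loc.read_start, loc.read_stop) == (5, 14)
        assert loc.matches == 9 and loc.errors == 0

    def test_no_occurrence_returns_none(self):
        assert semiglobal_align(AdapterSpec("AGATCGGAA"),
                                make_read("CCCCCCCCCC")) is None

    def test_partial_adapter_at_read_end(self):
        # only the first 5 adapter bases fit before the 3' read end
        loc = semiglobal_align(AdapterSpec("AGATCGGAA"),
                               make_read("TTTTTTTTTTAGATC"))
        assert (loc.read_start, loc.read_stop) == (10, 15)
        assert loc.adapter_stop == 5 and loc.errors == 0

    def test_front_adapter(self):
        loc = semiglobal_align(
            AdapterSpec("AGATT", where=AdapterEnd.FRONT),
            make_read("CCAGATTGGG"))
        assert (loc.read_start, loc.read_stop) == (2, 7)

    def test_acceptance_rule_is_per_aligned_adapter_length(self):
        # 1 error over 5 aligned characters: allowed at 0.2, not at 0.1
        read = make_read("CCCCCCCCCCAGTTT")
        hit = semiglobal_align(
            AdapterSpec("AGATT", max_error_rate=0.2, min_overlap=5), read)
        assert hit is not None and hit.errors == 1
        assert semiglobal_align(
            AdapterSpec("AGATT", max_error_rate=0.1, min_overlap=5),
            read) is None

    def test_read_n_matches_only_adapter_n(self):
        read = make_read("CCCCCNNNNNNNNN")
        assert semiglobal_align(AdapterSpec("AGATCGGAA"), read) is None
        loc = semiglobal_align(AdapterSpec("NNNNNNNNN"), read)
        assert loc.matches == 9


def _random_instance(rng, iupac_adapter):
    m = int(rng.integers(1, 13))
    n = int(rng.integers(1, 21))
    adapter = random_seq(rng, m, "ACGTN" if iupac_adapter else "ACGT")
    read = random_seq(rng, n, "ACGTACGTACGTN")  # occasional N
    rate = float(rng.choice([0.0, 0.1, 0.2, 0.3]))
    min_overlap = int(rng.choice([1, 3]))
    where = "back" if rng.random() < 0.5 else "front"
    return adapter, read, where, rate, min_overlap


class TestOracleEquivalence:
    def test_matches_bruteforce_on_random_instances(self, rng):
        """The single-column cutoff DP equals a full-matrix enumeration of
        every shift on 500 random instances, with and without cutoff."""
        for trial in range(500):
            adapter, read, where, rate, mo = _random_instance(
                rng, iupac_adapter=trial % 3 == 0)
            spec = AdapterSpec(adapter, AdapterEnd(where),
                               max_error_rate=rate, min_overlap=mo)
            expected = oracle_semiglobal(adapter, read, where, rate, mo)
            for cutoff in (True, False):
                got = semiglobal_align(spec, make_read(read),
                                       use_cutoff=cutoff)
                if expected is None:
                    assert got is None, (adapter, read, where, rate, mo)
                else:
                    assert got is not None, (adapter, read, where, rate, mo)
                    for key, val in expected.items():
                        assert getattr(got, key) == val, (
                            key, adapter, read, where, rate, mo, got)

    def test_bottom_row_equals_all_shifts_edit_distance(self, rng):
        """Independent cross-check: the DP's full-adapter candidates carry
        the minimum over all start shifts of the plain edit distance
        (computed by edlib) for each end position."""
        from _oracles import IUPAC, oracle_semiglobal_back

        for _ in range(40):
            adapter = random_seq(rng, int(rng.integers(2, 10)))
            read = random_seq(rng, int(rng.integers(2, 18)))
            dists = oracle_edit_distances_back(adapter, read)
            # recompute the oracle's bottom row directly
            m, n = len(adapter), len(read)
            res = oracle_semiglobal_back(adapter, read, 1.0, 1)
            # rate 1.0 accepts everything; the winner's error count must
            # agree with the independent edit-distance minimum at its end
            assert res is not None
            rstart, rstop, astop, mat, errs = res
            if astop == m:
                assert errs == dists[rstop]

    def test_accepted_locations_satisfy_contract(self, rng):
        for _ in range(200):
            adapter, read, where, rate, mo = _random_instance(rng, False)
            spec = AdapterSpec(adapter, AdapterEnd(where),
                               max_error_rate=rate, min_overlap=mo)
            loc = semiglobal_align(spec, make_read(read))
            if loc is None:
                continue
            alen = loc.aligned_adapter_length
            assert alen >= mo
            assert loc.errors <= rate * alen + 1e-9
            assert 0 <= loc.read_start <= loc.read_stop <= len(read)

    def test_iupac_containment_never_reduces_matches(self, rng):
        """Replacing an adapter character by a superset code (e.g. A -> N)
        never decreases the best match count."""
        superset = {"A": "R", "C": "Y", "G": "N", "T": "W"}
        for _ in range(100):
            adapter = random_seq(rng, int(rng.integers(3, 10)))
            read = random_seq(rng, int(rng.integers(5, 20)))
            pos = int(rng.integers(0, len(adapter)))
            widened = (adapter[:pos] + superset[adapter[pos]]
                       + adapter[pos + 1:])
            base = semiglobal_align(AdapterSpec(adapter, max_error_rate=0.3,
                                                min_overlap=1),
                                    make_read(read))
            wide = semiglobal_align(AdapterSpec(widened, max_error_rate=0.3,
                                                min_overlap=1),
                                    make_read(read))
            if base is not None:
                assert wide is not None
                assert wide.matches >= base.matches


class TestHamming:
    def test_prefix_examples(self):
        spec = AdapterSpec("AGATT", AdapterEnd.FRONT, anchored=True,
                           allow_indels=False)
        loc = hamming_align(spec, make_read("AGATTCCC"))
        assert (loc.read_start, loc.read_stop, loc.errors) == (0, 5, 0)
        spec2 = AdapterSpec("AGATT", AdapterEnd.FRONT, anchored=True,
                            allow_indels=False, max_error_rate=0.2)
        loc2 = hamming_align(spec2, make_read("AGCTTCCC"))
        assert (loc2.errors, loc2.matches) == (1, 4)

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            hamming_align(AdapterSpec("ACGT"), make_read("ACGT"))

    def test_agrees_with_semiglobal_on_random_anchored_cases(self, rng):
        for _ in range(500):
            m = int(rng.integers(1, 10))
            n = int(rng.integers(m, 20))
            adapter = random_seq(rng, m)
            read = random_seq(rng, n)
            where = AdapterEnd.BACK if rng.random() < 0.5 else AdapterEnd.FRONT
            rate = float(rng.choice([0.0, 0.2, 0.5]))
            spec = AdapterSpec(adapter, where, anchored=True,
                               allow_indels=False, max_error_rate=rate,
                               min_overlap=1)
            fast = hamming_align(spec, make_read(read))
            slow = semiglobal_align(spec, make_read(read))
            if fast is None:
                assert slow is None
            else:
                assert slow is not None
                assert (fast.read_start, fast.read_stop, fast.errors,
                        fast.matches) == (slow.read_start, slow.read_stop,
                                          slow.errors, slow.matches)


class TestTrim:
    def test_back_trim_keeps_prefix(self):
        read = make_read("CCCCCAGATCGGAA")
        loc = semiglobal_align(AdapterSpec("AGATCGGAA"), read)
        assert trim_by_location(read, AdapterEnd.BACK, loc).bases == "CCCCC"

    def test_front_trim_keeps_suffix(self):
        read = make_read("AGATTCCC")
        spec = AdapterSpec("AGATT", AdapterEnd.FRONT, anchored=True,
                           allow_indels=False)
        loc = hamming_align(spec, read)
        assert trim_by_location(read, AdapterEnd.FRONT, loc).bases == "CCC"

    def test_no_location_is_identity(self):
        read = make_read("ACGTACGT")
        assert trim_by_location(read, AdapterEnd.BACK, None) is read

    def test_qualities_trimmed_in_lockstep(self):
        read = make_read("CCCCCAGATCGGAA", quality=37)
        loc = semiglobal_align(AdapterSpec("AGATCGGAA"), read)
        out = trim_by_location(read, AdapterEnd.BACK, loc)
        assert len(out.qualities) == len(out.bases) == 5
        assert np.all(out.qualities == 37)
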