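"""Insert-match trimming for read pairs.

For a paired-end read pair, the adapter position can be inferred without
knowing the adapter sequence precisely: if the insert (the fragment
between the adapters) is shorter than the read length, read 1 and the
reverse complement of read 2 overlap over the full insert, and everything
past the overlap is adapter.  The algorithm:

1. finds all relative shifts at which the two reads' 3' ends overlap,
   scoring each by match count, mismatch fraction, and the binomial
   probability that the agreement arose by chance;
2. tests candidates in order of decreasing overlap length, confirming
   each by comparing the user-supplied adapters against the overhangs;
   confirmation in either mate suffices, and the trim point is applied
   symmetrically to both reads;
3. optionally uses the duplicated insert coverage for mutual error
   correction, low-quality-mate overwriting, and pair merging;
4. falls back to independent semi-global adapter matching in each read
   when no overlap candidate is confirmed.

The shift scan is an indel-free special case of the semi-global aligner,
evaluated for all shifts at once by cross-correlating 4-bit one-hot
encodings of the two sequences.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import binom

from .align import AdapterEnd, AdapterSpec, encode_adapter, encode_read, semiglobal_align
from .records import ReadRecord

_EPS = 1e-9

#: Canonical TruSeq 3' adapter stems (read 1 / read 2).
TRUSEQ_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
TRUSEQ_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide/IUPAC string."""
    for ch in seq:
        if ch.upper() not in _COMPLEMENT:
            raise ValueError(f"cannot complement unknown character {ch!r}")
    return seq.translate(_COMP_TABLE)[::-1]


def reverse_complement_record(read: ReadRecord) -> ReadRecord:
    """Reverse-complement a read; qualities are reversed in lockstep."""
    return ReadRecord(read.name, reverse_complement(read.bases),
                      read.qualities[::-1].copy(), read.mate)


def random_match_prob(k: int, n: int, p: float = 0.25) -> float:
    """Probability of >= k matches among n compared bases by chance.

    Binomial tail P = sum_{i=k}^{n} C(n, i) p^i (1-p)^(n-i), evaluated
    through the survival function for numerical stability.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


@functools.lru_cache(maxsize=16)
def _min_matches_table(n_max: int, p: float, threshold: float) -> np.ndarray:
    """For each overlap length n, the smallest match count k whose random
    match probability is <= threshold (n+1 if unattainable)."""
    ns = np.arange(1, n_max + 1)
    # binom.isf(q, n, p) is the smallest k with P(X > k) <= q,
    # so P(X >= k+1) <= q and k+1 is the minimal passing match count.
    kmin = binom.isf(threshold, ns, p) + 1
    kmin = np.minimum(kmin, ns + 1).astype(np.int64)
    return np.concatenate([[1], kmin])  # index by n directly


def _default_adapter1() -> AdapterSpec:
    return AdapterSpec(TRUSEQ_ADAPTER_R1, AdapterEnd.BACK)


def _default_adapter2() -> AdapterSpec:
    return AdapterSpec(TRUSEQ_ADAPTER_R2, AdapterEnd.BACK)


@dataclass(frozen=True)
class InsertMatchParams:
    """Specificity thresholds and adapters for insert matching.

    The three user-configurable thresholds: minimum overlap length,
    maximum mismatch fraction of the overlap, and maximum random-match
    probability under a binomial null with per-base match probability
    ``base_match_prob``.
    """

    min_insert_overlap: int = 10
    max_mismatch_frac: float = 0.2
    max_random_match_prob: float = 1e-6
    adapter1: AdapterSpec = field(default_factory=_default_adapter1)
    adapter2: AdapterSpec = field(default_factory=_default_adapter2)
    base_match_prob: float = 0.25
    #: Overhang adapter confirmation is "constrained": the offset is fixed
    #: by the insert candidate, overhangs are short and 3'-biased in error,
    #: so only a relaxed mismatch-fraction test applies there.
    overhang_max_error_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.min_insert_overlap < 1:
            raise ValueError("min_insert_overlap must be >= 1")
        for name in ("max_mismatch_frac", "max_random_match_prob",
                     "base_match_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


class TieMode(enum.Enum):
    """What to do with an overlap mismatch whose two bases tie on quality."""
    NONE = "none"        # no correction at all
    KEEP = "keep"        # leave both bases unchanged
    TO_N = "N"           # mask both to N
    BEST_READ = "best"   # take the base from the read with higher mean quality


@dataclass(frozen=True)
class CorrectionPolicy:
    mode: TieMode = TieMode.NONE
    overwrite_poor_read: bool = False
    #: Overwrite fires when one mate's mean error probability exceeds this
    #: multiple of the other's.
    overwrite_quality_gap: float = 3.0
    merge_pairs: bool = False


class InsertCandidate(NamedTuple):
    insert_length: int
    overlap_len: int
    matches: int
    mismatches: int


@dataclass
class InsertMatchResult:
    insert_length: int
    overlap_len: int
    matches: int
    mismatches: int
    prob: float
    adapter1_confirmed: bool = False
    adapter2_confirmed: bool = False
    corrected_positions: int = 0


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _onehot(bases: str) -> np.ndarray:
    codes = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return (codes[None, :] == _ACGT[:, None]).astype(np.float64)


def find_insert_candidates(read1: ReadRecord, read2: ReadRecord,
                           params: InsertMatchParams
                           ) -> list[InsertCandidate]:
    """All insert-length candidates passing the three thresholds, sorted
    by decreasing overlap length (ties: more matches, shorter insert).

    Two geometric regimes appear: insert <= read length (full-insert
    overlap, adapter overhangs on both 3' ends) and insert > read length
    (partial 3' overlap, no overhangs).
    """
    if len(read1) == 0 or len(read2) == 0:
        return []
    n1, n2 = len(read1), len(read2)
    oh1 = _onehot(read1.bases)
    oh2 = _onehot(read2.bases)
    # one-hot of revcomp(read2): complement = swap A<->T, C<->G channels;
    # reverse positions.
    rc2 = oh2[[3, 2, 1, 0]][:, ::-1]
    corr = np.zeros(n1 + n2 - 1)
    for c in range(4):
        corr += np.correlate(oh1[c], rc2[c], mode="full")
    matches = np.rint(corr).astype(np.int64)

    lengths = np.arange(1, n1 + n2)  # candidate insert lengths
    overlap = np.minimum(n1, lengths) - np.maximum(0, lengths - n2)
    mism = overlap - matches

    kmin = _min_matches_table(max(n1, n2), params.base_match_prob,
                              params.max_random_match_prob)
    ok = (
        (overlap >= params.min_insert_overlap)
        & (mism <= params.max_mismatch_frac * overlap + _EPS)
        & (matches >= kmin[overlap])
    )
    idx = np.nonzero(ok)[0]
    cands = [
        InsertCandidate(int(lengths[i]), int(overlap[i]),
                        int(matches[i]), int(mism[i]))
        for i in idx
    ]
    cands.sort(key=lambda c: (-c.overlap_len, -c.matches, c.insert_length))
    return cands


def _overhang_match(adapter: AdapterSpec, bases: str, start: int,
                    max_error_rate: float) -> bool:
    """Constrained adapter comparison at a fixed offset: the adapter is
    laid position-wise against ``bases[start:]``."""
    alen = min(len(adapter.sequence), len(bases) - start)
    if alen < 1:
        return False
    amask = encode_adapter(adapter.sequence[:alen])
    rmask = encode_read(bases[start:start + alen])
    wild = amask == 15
    m = int(np.count_nonzero(((amask & rmask) != 0) | wild))
    return (alen - m) <= max_error_rate * alen + _EPS


def confirm_adapters(candidate: InsertCandidate, read1: ReadRecord,
                     read2: ReadRecord, params: InsertMatchParams
                     ) -> InsertMatchResult | None:
    """Confirm an overhang-bearing candidate by matching each adapter
    against its read's overhang at the offset the candidate implies.

    Adapter location must be symmetric across the pair, so confirmation in
    either mate fixes the trim point for both; with neither confirmed the
    candidate is rejected and the next one is tried.
    """
    L = candidate.insert_length
    if L >= len(read1) and L >= len(read2):
        raise ValueError("candidate implies no overhangs; nothing to confirm")
    c1 = L < len(read1) and _overhang_match(
        params.adapter1, read1.bases, L, params.overhang_max_error_rate)
    c2 = L < len(read2) and _overhang_match(
        params.adapter2, read2.bases, L, params.overhang_max_error_rate)
    if not (c1 or c2):
        return None
    return InsertMatchResult(
        insert_length=L, overlap_len=candidate.overlap_len,
        matches=candidate.matches, mismatches=candidate.mismatches,
        prob=random_match_prob(candidate.matches, candidate.overlap_len,
                               params.base_match_prob),
        adapter1_confirmed=c1, adapter2_confirmed=c2)


def _overlap_columns(L: int, n1: int, n2: int) -> tuple[int, int]:
    """Read-1 coordinate span [lo, hi) of the insert overlap for insert
    length L; the matching read-2 index for read-1 position i is L-1-i."""
    return max(0, L - n2), min(n1, L)


def error_correct(read1: ReadRecord, read2: ReadRecord,
                  result: InsertMatchResult, policy: CorrectionPolicy
                  ) -> tuple[ReadRecord, ReadRecord, int]:
    """Mutual error correction over the insert overlap.

    At each disagreeing column the base with the higher Phred quality is
    written into both reads (complemented in read 2, which stores the
    opposite strand) and the column's quality becomes the maximum of the
    two.  Quality ties follow the policy mode.  Returns the corrected
    reads and the number of base assignments that changed a read.
    """
    if policy.mode is TieMode.NONE:
        return read1, read2, 0
    L, n1, n2 = result.insert_length, len(read1), len(read2)
    lo, hi = _overlap_columns(L, n1, n2)
    if hi <= lo:
        return read1, read2, 0
    b1 = bytearray(read1.bases, "ascii")
    b2 = bytearray(read2.bases, "ascii")
    q1 = read1.qualities.copy()
    q2 = read2.qualities.copy()
    mean1 = read1.mean_error_prob()
    mean2 = read2.mean_error_prob()
    ncorr = 0
    for i in range(lo, hi):
        j = L - 1 - i
        base1 = chr(b1[i])
        base2c = _COMPLEMENT.get(chr(b2[j]), "N")
        if base1 == base2c:
            continue
        qa, qb = int(q1[i]), int(q2[j])
        if qa > qb:
            cons = base1
        elif qb > qa:
            cons = base2c
        elif policy.mode is TieMode.KEEP:
            continue
        elif policy.mode is TieMode.TO_N:
            cons = "N"
        else:  # BEST_READ: lower mean error prob = higher mean quality
            cons = base1 if mean1 <= mean2 else base2c
        qmax = max(qa, qb)
        if base1 != cons:
            b1[i] = ord(cons)
            ncorr += 1
        if base2c != cons:
            b2[j] = ord(_COMPLEMENT[cons])
            ncorr += 1
        q1[i] = qmax
        q2[j] = qmax
    r1 = ReadRecord(read1.name, b1.decode("ascii"), q1, read1.mate)
    r2 = ReadRecord(read2.name, b2.decode("ascii"), q2, read2.mate)
    return r1, r2, ncorr


def overwrite_poor_read(read1: ReadRecord, read2: ReadRecord,
                        result: InsertMatchResult, quality_gap: float
                        ) -> tuple[ReadRecord, ReadRecord, bool]:
    """If one mate's mean error probability exceeds ``quality_gap`` times
    the other's, replace its overlap span with the reverse complement of
    the better mate's (bases and qualities)."""
    e1, e2 = read1.mean_error_prob(), read2.mean_error_prob()
    if e1 <= quality_gap * e2 and e2 <= quality_gap * e1:
        return read1, read2, False
    L, n1, n2 = result.insert_length, len(read1), len(read2)
    lo, hi = _overlap_columns(L, n1, n2)
    if hi <= lo:
        return read1, read2, False
    if e1 > quality_gap * e2:  # read1 is poor: copy from read2
        b1 = bytearray(read1.bases, "ascii")
        q1 = read1.qualities.copy()
        for i in range(lo, hi):
            j = L - 1 - i
            b1[i] = ord(_COMPLEMENT.get(read2.bases[j], "N"))
            q1[i] = read2.qualities[j]
        read1 = ReadRecord(read1.name, b1.decode("ascii"), q1, read1.mate)
    else:
        b2 = bytearray(read2.bases, "ascii")
        q2 = read2.qualities.copy()
        for j in range(max(0, L - n1), min(n2, L)):
            i = L - 1 - j
            b2[j] = ord(_COMPLEMENT.get(read1.bases[i], "N"))
            q2[j] = read1.qualities[i]
        read2 = ReadRecord(read2.name, b2.decode("ascii"), q2, read2.mate)
    return read1, read2, True


def merge_pair(read1: ReadRecord, read2: ReadRecord,
               result: InsertMatchResult,
               policy: CorrectionPolicy | None = None) -> ReadRecord:
    """Merge an insert-matched pair into one read covering the full insert.

    Layout: read-1-only prefix + consensus overlap + (when the insert is
    longer than the reads) reverse-complemented read-2 suffix.  Overlap
    disagreements are resolved exactly as in :func:`error_correct`.
    """
    policy = policy or CorrectionPolicy(mode=TieMode.BEST_READ)
    eff = policy if policy.mode is not TieMode.NONE else replace(
        policy, mode=TieMode.BEST_READ)
    r1, r2, _ = error_correct(read1, read2, result, eff)
    L, n1, n2 = result.insert_length, len(r1), len(r2)
    lo, hi = _overlap_columns(L, n1, n2)
    rc2 = reverse_complement_record(r2)
    # rc2 covers insert positions [L - n2, L); its local index for insert
    # position t is t - (L - n2).
    bases = r1.bases[:hi]
    quals = [r1.qualities[:hi]]
    if L > hi:
        off = L - n2
        bases += rc2.bases[hi - off:]
        quals.append(rc2.qualities[hi - off:])
    return ReadRecord(r1.name, bases, np.concatenate(quals), None)


@dataclass
class InsertTrimOutcome:
    read1: ReadRecord
    read2: ReadRecord | None         # None when merged
    merged: ReadRecord | None
    tag: str                         # 'insert' | 'fallback'
    result: InsertMatchResult | None
    trimmed1: int = 0                # bases removed from each mate
    trimmed2: int = 0


def _fallback_adapter_trim(read: ReadRecord, adapter: AdapterSpec,
                           params: InsertMatchParams
                           ) -> tuple[ReadRecord, int]:
    """Unconstrained semi-global adapter match in one read, additionally
    gated by the random-match probability threshold so that short chance
    matches at 3' ends do not trigger spurious trimming."""
    loc = semiglobal_align(adapter, read)
    if loc is None:
        return read, 0
    alen = loc.aligned_adapter_length
    if random_match_prob(loc.matches, alen, params.base_match_prob) \
            > params.max_random_match_prob:
        return read, 0
    trimmed = read.slice(0, loc.read_start)
    return trimmed, len(read) - len(trimmed)


def insert_trim_pair(read1: ReadRecord, read2: ReadRecord,
                     params: InsertMatchParams | None = None,
                     policy: CorrectionPolicy | None = None
                     ) -> InsertTrimOutcome:
    """Trim one read pair: insert-match first, adapter-match fallback.

    Candidates are tried in decreasing overlap order.  A candidate without
    overhangs (insert at least as long as the reads) is accepted directly
    since there is nothing to trim or confirm; otherwise adapter
    confirmation is required.  When no candidate is confirmed, each
    adapter is matched independently in its own read.
    """
    params = params or InsertMatchParams()
    policy = policy or CorrectionPolicy()
    n1, n2 = len(read1), len(read2)

    accepted: InsertMatchResult | None = None
    for cand in find_insert_candidates(read1, read2, params):
        if cand.insert_length >= n1 and cand.insert_length >= n2:
            accepted = InsertMatchResult(
                insert_length=cand.insert_length,
                overlap_len=cand.overlap_len, matches=cand.matches,
                mismatches=cand.mismatches,
                prob=random_match_prob(cand.matches, cand.overlap_len,
                                       params.base_match_prob))
            break
        accepted = confirm_adapters(cand, read1, read2, params)
        if accepted is not None:
            break

    if accepted is not None:
        r1, r2 = read1, read2
        if policy.overwrite_poor_read:
            r1, r2, _ = overwrite_poor_read(
                r1, r2, accepted, policy.overwrite_quality_gap)
        if policy.mode is not TieMode.NONE:
            r1, r2, ncorr = error_correct(r1, r2, accepted, policy)
            accepted.corrected_positions = ncorr
        L = accepted.insert_length
        t1 = max(0, n1 - L)
        t2 = max(0, n2 - L)
        if t1:
            r1 = r1.slice(0, L)
        if t2:
            r2 = r2.slice(0, L)
        if policy.merge_pairs:
            merged = merge_pair(read1, read2, accepted, policy)
            return InsertTrimOutcome(r1, None, merged, "insert", accepted,
                                     t1, t2)
        return InsertTrimOutcome(r1, r2, None, "insert", accepted, t1, t2)

    r1, t1 = _fallback_adapter_trim(read1, params.adapter1, params)
    r2, t2 = _fallback_adapter_trim(read2, params.adapter2, params)
    return InsertTrimOutcome(r1, r2, None, "fallback", None, t1, t2)
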