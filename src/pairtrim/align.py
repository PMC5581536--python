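"""IUPAC-aware semi-global alignment of adapter patterns against reads.

The aligner follows the edit-operation formulation used by modern adapter
trimmers: instead of maximizing an alignment score, it computes edit
distances for all allowed shifts of the adapter relative to the read and,
among the shifts whose *error rate* (edits divided by the number of aligned
adapter characters) does not exceed a user threshold, returns the one with
the highest number of matching columns.

The dynamic program fills three matrices column by column:

* ``D(i, j)`` - edit distance between the i-prefix of the adapter and the
  j-prefix of the read, with base cases chosen by adapter end so that a
  read prefix (3' adapters) or suffix (5' adapters) can be skipped free;
* ``M(i, j)`` - number of matching columns on the tracked optimal path;
* ``O(i, j)`` - the *origin*, i.e. how many read characters were skipped
  at the start of the alignment.

Only a single column of each matrix is kept in memory.  A Ukkonen-style
cutoff abandons the lower part of a column as soon as its cost exceeds the
maximum number of edits any acceptable candidate could have; enabling the
cutoff never changes the result.  Nucleotides and IUPAC ambiguity codes are
represented as 4-bit patterns so that character compatibility is a single
binary AND.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numba import njit

#: 4-bit nucleotide masks: one bit per nucleotide A/C/G/T.
_A, _C, _G, _T = 1, 2, 4, 8

IUPAC_MASKS: dict[str, int] = {
    "A": _A, "C": _C, "G": _G, "T": _T, "U": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T,
    "V": _A | _C | _G, "N": _A | _C | _G | _T,
}

_WILDCARD = _A | _C | _G | _T  # the N pattern


class AdapterEnd(enum.Enum):
    """Which read end an adapter is expected at."""
    FRONT = "front"   # 5' adapter
    BACK = "back"     # 3' adapter


def encode_iupac(symbol: str) -> int:
    """Return the 4-bit nucleotide mask for a single IUPAC code.

    Two symbols are compatible iff their masks share a set bit.
    """
    try:
        return IUPAC_MASKS[symbol.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC character {symbol!r}") from None


def compatible(a: str, b: str) -> bool:
    """True iff the two IUPAC symbols can denote a common nucleotide."""
    return bool(encode_iupac(a) & encode_iupac(b))


def encode_adapter(sequence: str) -> np.ndarray:
    """Encode an IUPAC adapter sequence as a uint8 mask array."""
    masks = np.empty(len(sequence), dtype=np.uint8)
    for pos, ch in enumerate(sequence):
        try:
            masks[pos] = IUPAC_MASKS[ch.upper()]
        except KeyError:
            raise ValueError(
                f"unknown IUPAC character {ch!r} at position {pos}"
            ) from None
    return masks


def encode_read(bases: str) -> np.ndarray:
    """Encode read bases as uint8 masks.

    ``N`` in a read encodes as 0 (matches nothing): a run of Ns must not
    fake an adapter hit.  Only an adapter-side ``N`` wildcard matches it.
    """
    masks = np.empty(len(bases), dtype=np.uint8)
    for pos, ch in enumerate(bases):
        if ch in ("N", "n"):
            masks[pos] = 0
            continue
        try:
            masks[pos] = IUPAC_MASKS[ch.upper()]
        except KeyError:
            raise ValueError(
                f"unknown nucleotide {ch!r} at position {pos}"
            ) from None
    return masks


@dataclass(frozen=True)
class AdapterSpec:
    """An adapter pattern plus its matching policy.

    Parameters
    ----------
    sequence:
        IUPAC adapter string (non-empty).
    where:
        :class:`AdapterEnd` - ``BACK`` (3') or ``FRONT`` (5').
    anchored:
        If true, the adapter must align flush with the read end
        (a prefix for FRONT, a suffix for BACK).
    max_error_rate:
        Maximum edits divided by aligned adapter length, in [0, 1].
    min_overlap:
        Minimum number of aligned adapter characters.
    allow_indels:
        Whether insertions/deletions are allowed in the alignment.
    """

    sequence: str
    where: AdapterEnd = AdapterEnd.BACK
    anchored: bool = False
    max_error_rate: float = 0.1
    min_overlap: int = 3
    allow_indels: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("adapter sequence must be non-empty")
        encode_adapter(self.sequence)  # validates characters
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class AlignmentLocation:
    """Result of a semi-global adapter alignment.

    Spans are 0-based half-open; ``origin`` is the signed number of read
    characters skipped before the alignment begins (negative when adapter
    characters were skipped instead, which happens for 5' adapters).
    """

    read_start: int
    read_stop: int
    adapter_start: int
    adapter_stop: int
    matches: int
    errors: int
    origin: int

    @property
    def aligned_adapter_length(self) -> int:
        return self.adapter_stop - self.adapter_start


_EPS = 1e-9
_INF = 1 << 30


@njit(cache=False)
def _semiglobal_back_kernel(amask, wild, rmask, max_error_rate, min_overlap,
                            anchored, use_cutoff):
    """Single-column DP over the adapter (rows) x read (columns) grid with
    3'-adapter base cases (free read-prefix skip; candidates on the bottom
    row and in the final column).

    Returns (found, read_start, read_stop, adapter_stop, matches, errors).
    """
    m = amask.shape[0]
    n = rmask.shape[0]
    k_max = int(max_error_rate * m + _EPS)

    D = np.empty(m + 1, dtype=np.int64)
    M = np.zeros(m + 1, dtype=np.int64)
    O = np.zeros(m + 1, dtype=np.int64)
    for i in range(m + 1):
        D[i] = i
    prevD = np.empty(m + 1, dtype=np.int64)
    prevM = np.empty(m + 1, dtype=np.int64)
    prevO = np.empty(m + 1, dtype=np.int64)

    last = m
    if use_cutoff and k_max < m:
        last = k_max

    # Best candidate so far: maximize matches, then minimize errors, then
    # maximize aligned adapter length, then minimize read_start, then the
    # earliest end position (candidates are visited in end order, so a
    # full tie keeps the incumbent).  For FRONT adapters these rules apply
    # in the mirrored scan orientation.
    best_found = False
    b_matches = -1
    b_errors = 0
    b_alen = 0
    b_rstart = 0
    b_rstop = 0
    b_astop = 0

    # column j = 0 bottom-row candidate (empty read span) is only sensible
    # at error rate 1.0; handled for completeness.
    if last == m and not anchored:
        errs = D[m]
        if m >= min_overlap and errs <= max_error_rate * m + _EPS:
            best_found = True
            b_matches = 0
            b_errors = errs
            b_alen = m
            b_rstart = 0
            b_rstop = 0
            b_astop = m

    for j in range(1, n + 1):
        for i in range(last + 1):
            prevD[i] = D[i]
            prevM[i] = M[i]
            prevO[i] = O[i]
        prev_last = last
        D[0] = 0
        M[0] = 0
        O[0] = j
        upper = m
        if use_cutoff:
            upper = prev_last + 1
            if upper > m:
                upper = m
        rj = rmask[j - 1]
        for i in range(1, upper + 1):
            ai = amask[i - 1]
            is_match = (ai & rj) != 0 or wild[i - 1]
            # diagonal: consume one adapter and one read character
            if i - 1 <= prev_last:
                cost = prevD[i - 1] + (0 if is_match else 1)
                mat = prevM[i - 1] + (1 if is_match else 0)
                org = prevO[i - 1]
            else:
                cost = _INF
                mat = 0
                org = 0
            # up: consume an adapter character (gap in read)
            c_up = D[i - 1] + 1
            if c_up < cost or (c_up == cost and M[i - 1] > mat):
                cost = c_up
                mat = M[i - 1]
                org = O[i - 1]
            # left: consume a read character (gap in adapter)
            if i <= prev_last:
                c_left = prevD[i] + 1
                if c_left < cost or (c_left == cost and prevM[i] > mat):
                    cost = c_left
                    mat = prevM[i]
                    org = prevO[i]
            D[i] = cost
            M[i] = mat
            O[i] = org
        if use_cutoff:
            last = upper
            while D[last] > k_max:
                last -= 1
                if last < 0:
                    last = 0
                    break
        # bottom-row candidate: full adapter aligned, ending at read pos j
        if last == m and (not anchored or j == n):
            errs = D[m]
            if m >= min_overlap and errs <= max_error_rate * m + _EPS:
                mat = M[m]
                rstart = O[m]
                better = False
                if not best_found:
                    better = True
                elif mat > b_matches:
                    better = True
                elif mat == b_matches:
                    if errs < b_errors:
                        better = True
                    elif errs == b_errors:
                        if m > b_alen:
                            better = True
                        elif m == b_alen and rstart < b_rstart:
                            better = True
                if better:
                    best_found = True
                    b_matches = mat
                    b_errors = errs
                    b_alen = m
                    b_rstart = rstart
                    b_rstop = j
                    b_astop = m
    # final-column candidates: adapter prefix aligned, running off the
    # 3' read end (not available for anchored adapters, which require the
    # full adapter).
    if not anchored:
        for i in range(min_overlap, m):
            if use_cutoff and i > last:
                break
            errs = D[i]
            if errs <= max_error_rate * i + _EPS:
                mat = M[i]
                rstart = O[i]
                better = False
                if not best_found:
                    better = True
                elif mat > b_matches:
                    better = True
                elif mat == b_matches:
                    if errs < b_errors:
                        better = True
                    elif errs == b_errors:
                        if i > b_alen:
                            better = True
                        elif i == b_alen and rstart < b_rstart:
                            better = True
                if better:
                    best_found = True
                    b_matches = mat
                    b_errors = errs
                    b_alen = i
                    b_rstart = rstart
                    b_rstop = n
                    b_astop = i
    return best_found, b_rstart, b_rstop, b_astop, b_matches, b_errors


def _noindel_back(amask, wild, rmask, max_error_rate, min_overlap, anchored):
    """Indel-free variant: position-wise comparison at every shift of the
    adapter along the read (3'-adapter orientation)."""
    m, n = amask.shape[0], rmask.shape[0]
    match_ok = (amask[None, :] & rmask[:, None]).astype(bool) | wild[None, :]
    best = None
    shifts = [n - m] if (anchored and n >= m) else range(n + 1)
    for s in shifts:
        alen = min(m, n - s)
        if alen < min_overlap:
            continue
        matches = int(np.count_nonzero(np.diagonal(match_ok[s:s + alen, :alen])))
        errors = alen - matches
        if errors > max_error_rate * alen + _EPS:
            continue
        cand = (matches, -errors, alen, -s)
        if best is None or cand > best[0]:
            best = (cand, s, s + alen, alen, matches, errors)
    if best is None:
        return False, 0, 0, 0, 0, 0
    _, s, stop, alen, matches, errors = best
    return True, s, stop, alen, matches, errors


def _align_back_oriented(amask, wild, rmask, spec: AdapterSpec,
                         use_cutoff: bool):
    if spec.allow_indels:
        return _semiglobal_back_kernel(
            amask, wild, rmask, spec.max_error_rate, spec.min_overlap,
            spec.anchored, use_cutoff)
    return _noindel_back(amask, wild, rmask, spec.max_error_rate,
                         spec.min_overlap, spec.anchored)


def semiglobal_align(adapter: AdapterSpec, read, *,
                     use_cutoff: bool = True) -> AlignmentLocation | None:
    """Best acceptable alignment of ``adapter`` against ``read``, or None.

    ``read`` may be a :class:`~pairtrim.records.ReadRecord` or a plain
    string.  Qualities play no role in alignment.
    """
    bases = read if isinstance(read, str) else read.bases
    if not bases:
        return None
    amask = encode_adapter(adapter.sequence)
    wild = amask == _WILDCARD
    rmask = encode_read(bases)
    m, n = amask.shape[0], rmask.shape[0]

    if adapter.where is AdapterEnd.BACK:
        found, rstart, rstop, astop, matches, errors = _align_back_oriented(
            amask, wild, rmask, adapter, use_cutoff)
        if not found:
            return None
        return AlignmentLocation(
            read_start=rstart, read_stop=rstop,
            adapter_start=0, adapter_stop=astop,
            matches=matches, errors=errors, origin=rstart)
    # FRONT: mirror image - reverse both sequences and run the BACK logic,
    # then map coordinates back.
    found, rstart, rstop, astop, matches, errors = _align_back_oriented(
        amask[::-1].copy(), wild[::-1].copy(), rmask[::-1].copy(),
        adapter, use_cutoff)
    if not found:
        return None
    return AlignmentLocation(
        read_start=n - rstop, read_stop=n - rstart,
        adapter_start=m - astop, adapter_stop=m,
        matches=matches, errors=errors,
        origin=-(m - astop) if astop < m else n - rstop)


def hamming_align(adapter: AdapterSpec, read) -> AlignmentLocation | None:
    """Fast path for anchored, indel-free adapters: position-wise
    comparison of the adapter with the read prefix (FRONT) or suffix
    (BACK), under the same acceptance rule as :func:`semiglobal_align`.
    """
    if not adapter.anchored or adapter.allow_indels:
        raise ValueError(
            "hamming_align requires an anchored adapter with indels disabled")
    bases = read if isinstance(read, str) else read.bases
    amask = encode_adapter(adapter.sequence)
    wild = amask == _WILDCARD
    rmask = encode_read(bases)
    m, n = amask.shape[0], rmask.shape[0]
    if m > n:
        return None
    if adapter.where is AdapterEnd.BACK:
        seg = rmask[n - m:]
        rstart = n - m
    else:
        seg = rmask[:m]
        rstart = 0
    matches = int(np.count_nonzero(((amask & seg) != 0) | wild))
    errors = m - matches
    if m < adapter.min_overlap or errors > adapter.max_error_rate * m + _EPS:
        return None
    return AlignmentLocation(
        read_start=rstart, read_stop=rstart + m,
        adapter_start=0, adapter_stop=m,
        matches=matches, errors=errors, origin=rstart)


def trim_by_location(read, where: AdapterEnd,
                     loc: AlignmentLocation | None):
    """Remove the adapter occurrence from the read.

    BACK keeps ``[0, read_start)``; FRONT keeps ``[read_stop, n)``.
    With no location the read is returned unchanged.
    """
    if loc is None:
        return read
    n = len(read)
    if not (0 <= loc.read_start <= loc.read_stop <= n):
        raise ValueError(
            f"alignment span [{loc.read_start}, {loc.read_stop}) outside "
            f"read of length {n}")
    if where is AdapterEnd.BACK:
        return read.slice(0, loc.read_start)
    return read.slice(loc.read_stop, n)
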