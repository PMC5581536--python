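"""Independent brute-force reference implementations used only by tests.

These deliberately favour clarity over speed: full DP matrices, explicit
enumeration of every shift and cut point.  They share no code with the
package's optimized single-column / vectorized implementations.
"""

from __future__ import annotations

IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

EPS = 1e-9


def _masks(adapter: str, read: str):
    am = [IUPAC[c] for c in adapter.upper()]
    wild = [c.upper() == "N" for c in adapter]
    rm = [0 if c.upper() == "N" else IUPAC[c.upper()] for c in read]
    return am, wild, rm


def oracle_semiglobal_back(adapter: str, read: str, max_error_rate: float,
                           min_overlap: int, anchored: bool = False):
    """Full-matrix DP over all shifts with 3'-adapter base cases.

    Returns (read_start, read_stop, adapter_stop, matches, errors) or None.
    Tie rule inside a cell: diagonal, then up (gap in read), then left
    (gap in adapter); an equal-cost alternative wins only with a strictly
    higher match count.  Candidate selection: max matches, then min
    errors, then longest aligned adapter, then leftmost start.
    """
    am, wild, rm = _masks(adapter, read)
    m, n = len(am), len(rm)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    M = [[0] * (n + 1) for _ in range(m + 1)]
    O = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = 0
        O[0][j] = j
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            hit = bool(am[i - 1] & rm[j - 1]) or wild[i - 1]
            cost = D[i - 1][j - 1] + (0 if hit else 1)
            mat = M[i - 1][j - 1] + (1 if hit else 0)
            org = O[i - 1][j - 1]
            if D[i - 1][j] + 1 < cost or (
                    D[i - 1][j] + 1 == cost and M[i - 1][j] > mat):
                cost, mat, org = D[i - 1][j] + 1, M[i - 1][j], O[i - 1][j]
            if D[i][j - 1] + 1 < cost or (
                    D[i][j - 1] + 1 == cost and M[i][j - 1] > mat):
                cost, mat, org = D[i][j - 1] + 1, M[i][j - 1], O[i][j - 1]
            D[i][j], M[i][j], O[i][j] = cost, mat, org

    # selection: max matches, min errors, longest aligned adapter,
    # leftmost read start, earliest end position
    candidates = []
    js = range(n + 1) if not anchored else [n]
    for j in js:  # bottom row: full adapter
        errs = D[m][j]
        if m >= min_overlap and errs <= max_error_rate * m + EPS:
            candidates.append((M[m][j], -errs, m, -O[m][j], -j, m))
    if not anchored:
        for i in range(min_overlap, m):  # final column: partial adapter
            errs = D[i][n]
            if errs <= max_error_rate * i + EPS:
                candidates.append((M[i][n], -errs, i, -O[i][n], -n, i))
    if not candidates:
        return None
    mat, neg_err, alen, neg_start, neg_j, astop = max(candidates)
    return (-neg_start, -neg_j, astop, mat, -neg_err)


def oracle_semiglobal(adapter: str, read: str, where: str,
                      max_error_rate: float, min_overlap: int,
                      anchored: bool = False):
    """Front adapters are the mirror image of back adapters."""
    if where == "back":
        res = oracle_semiglobal_back(adapter, read, max_error_rate,
                                     min_overlap, anchored)
        if res is None:
            return None
        rstart, rstop, astop, mat, errs = res
        return dict(read_start=rstart, read_stop=rstop, adapter_start=0,
                    adapter_stop=astop, matches=mat, errors=errs)
    res = oracle_semiglobal_back(adapter[::-1], read[::-1], max_error_rate,
                                 min_overlap, anchored)
    if res is None:
        return None
    rstart, rstop, astop, mat, errs = res
    m, n = len(adapter), len(read)
    return dict(read_start=n - rstop, read_stop=n - rstart,
                adapter_start=m - astop, adapter_stop=m,
                matches=mat, errors=errs)


def oracle_edit_distances_back(adapter: str, read: str) -> list[int]:
    """For each end position j, the minimum over all start shifts s of the
    plain global edit distance between the adapter and read[s:j].  Used to
    cross-check the DP's bottom row independently."""
    import edlib

    out = []
    for j in range(len(read) + 1):
        best = min(
            edlib.align(adapter, read[s:j], mode="NW", task="distance")
            ["editDistance"]
            for s in range(j + 1)
        )
        out.append(best)
    return out


def oracle_quality_cut(qualities, cutoff: int) -> int:
    """Brute-force optimal 3' cut point: the index c maximizing
    sum(cutoff - q[i] for i >= c), ties resolved toward trimming less;
    no trimming unless the maximum is positive."""
    n = len(qualities)
    best_c, best_sum = None, None
    for c in range(n + 1):
        s = sum(cutoff - q for q in qualities[c:])
        if best_sum is None or s >= best_sum:  # ties: trim less
            best_c, best_sum = c, s
    return best_c if best_sum > 0 else n


def oracle_insert_shift_scan(read1: str, read2rc: str):
    """Naive per-shift overlap scan: for every candidate insert length,
    count matches/mismatches between read 1 and rc(read 2) over the
    overlap (N never matches)."""
    n1, n2 = len(read1), len(read2rc)
    out = {}
    for L in range(1, n1 + n2):
        lo, hi = max(0, L - n2), min(n1, L)
        if hi <= lo:
            continue
        matches = 0
        for i in range(lo, hi):
            a, b = read1[i], read2rc[i - (L - n2)]
            if a == b and a in "ACGT":
                matches += 1
        out[L] = (hi - lo, matches, hi - lo - matches)
    return out
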