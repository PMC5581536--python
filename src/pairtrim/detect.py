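"""De novo adapter/contaminant detection by iterative k-mer profiling.

Library construction details are often lost by the time data reaches an
analyst; this module recovers likely adapter sequences from the reads
alone.  From a sample of reads (poly-A tails pre-trimmed, low-complexity
reads excluded) a k-mer profile is built and k-mers whose counts exceed
an over-representation threshold are kept.  The profile is rebuilt with
doubled k using only the reads linked to surviving k-mers, until no
k-mer qualifies.  Qualifying k-mers from all rounds are merged - exact
suffix/prefix overlaps are unioned and sequences contained in longer
ones dropped - and the survivors are ranked, optionally labelled against
a list of known contaminants, and reported (at most 20).

A k-mer K of length k is over-represented in N reads of length l when

    count(K) > N * (l - k + 1) * O / 4^k

with O = 100 by default: its count exceeds O times the expectation for a
uniform-random k-mer.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .records import ReadRecord

_LOW_COMPLEXITY_BITS = 1.0


@dataclass(frozen=True)
class DetectParams:
    k0: int = 12                      # initial k-mer length
    sample_size: int = 10_000         # reads profiled (N)
    overrepresentation: float = 100.0  # factor O over random expectation
    polyA_min_run: int = 8
    complexity_threshold: float = _LOW_COMPLEXITY_BITS
    max_report: int = 20
    #: A singleton k-mer is never evidence of contamination, whatever the
    #: analytic threshold says (for large k it drops below one count).
    min_count: int = 2
    known_contaminants: dict[str, str] | None = None
    #: identity to a known contaminant required for labelling
    known_identity: float = 0.9

    def __post_init__(self) -> None:
        if self.k0 < 1 or self.sample_size < 1:
            raise ValueError("k0 and sample_size must be >= 1")
        if self.overrepresentation <= 0 or self.complexity_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ContaminantHit:
    sequence: str
    count: int                     # supporting reads
    abundance_ratio: float         # count over the random expectation
    known_match: tuple[str, float] | None = None
    rank: int = 0


def polyA_pretrim(read: ReadRecord, min_run: int = 8) -> ReadRecord:
    """Remove a run of >= ``min_run`` consecutive A bases and everything
    3' of it: the sequencer scanned past the end of the template."""
    idx = read.bases.find("A" * min_run)
    if idx < 0:
        return read
    return read.slice(0, idx)


def complexity(seq: str) -> float:
    """Shannon entropy of the nucleotide composition, in bits [0, 2].

    Sequences below 1.0 bit are treated as low-complexity.
    """
    if not seq:
        raise ValueError("complexity of an empty sequence is undefined")
    total = len(seq)
    x = 0.0
    for base in "ACGT":
        f = seq.count(base) / total
        if f > 0:
            x -= f * math.log2(f)
    return x


def abundance_threshold(params: DetectParams, read_length: int,
                        k: int) -> float:
    """Minimum count (exclusive) for a k-mer to be over-represented."""
    if k > read_length:
        raise ValueError(f"k={k} exceeds the read length {read_length}")
    return params.sample_size * (read_length - k + 1) \
        * params.overrepresentation / 4.0 ** k


def _count_kmers(seqs: list[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        seen = {s[i:i + k] for i in range(len(s) - k + 1)}
        counts.update(seen)  # one count per supporting read
    return counts


def _link_reads(seqs: list[str], indices: list[int], k: int,
                wanted: set[str]) -> dict[str, set[int]]:
    links: dict[str, set[int]] = {w: set() for w in wanted}
    for ridx, s in zip(indices, seqs):
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if km in links:
                links[km].add(ridx)
    return links


def _chain_same_length(items: dict[str, set[int]]) -> dict[str, set[int]]:
    """Unitig-style chaining within each length class: two sequences of
    length k are joined when they overlap by exactly k-1 characters and
    the junction is unambiguous (unique successor and predecessor)."""
    by_len: dict[int, list[str]] = {}
    for s in items:
        by_len.setdefault(len(s), []).append(s)
    out: dict[str, set[int]] = {}
    for length in sorted(by_len):
        seqs = sorted(by_len[length])
        pref: dict[str, list[str]] = {}
        for s in seqs:
            pref.setdefault(s[:-1], []).append(s)
        succ = {s: pref.get(s[1:], []) for s in seqs}
        n_preds: Counter = Counter()
        for s in seqs:
            for t in succ[s]:
                n_preds[t] += 1
        usable_next = {s: succ[s][0] for s in seqs
                       if len(succ[s]) == 1 and n_preds[succ[s][0]] == 1
                       and succ[s][0] != s}
        has_usable_pred = set(usable_next.values())
        visited: set[str] = set()
        for start in seqs:
            if start in visited or start in has_usable_pred:
                continue
            chain = [start]
            visited.add(start)
            cur = start
            while cur in usable_next and usable_next[cur] not in visited:
                cur = usable_next[cur]
                chain.append(cur)
                visited.add(cur)
            merged = chain[0] + "".join(s[-1] for s in chain[1:])
            reads: set[int] = set()
            for s in chain:
                reads |= items[s]
            out[merged] = out.get(merged, set()) | reads
        for s in seqs:  # safety: cyclic leftovers pass through unchanged
            if s not in visited:
                out[s] = out.get(s, set()) | items[s]
    return out


def _merge_overlapping(seqs_with_reads: dict[str, set[int]]
                       ) -> dict[str, set[int]]:
    """Union sequences joined by exact suffix/prefix overlaps of at least
    min(len)-1 characters, then drop sequences contained in longer ones."""
    items = _chain_same_length(seqs_with_reads)
    # bounded cross-length pairwise union (the chained set is small)
    if len(items) <= 200:
        changed = True
        while changed:
            changed = False
            seqs = sorted(items, key=lambda s: (-len(s), s))
            for a in seqs:
                if changed:
                    break
                for b in seqs:
                    if a == b:
                        continue
                    merged = _overlap_union(a, b)
                    if merged is not None and merged not in (a, b):
                        reads = items.pop(a) | items.pop(b)
                        items[merged] = items.get(merged, set()) | reads
                        changed = True
                        break
    # containment removal
    out: dict[str, set[int]] = {}
    for s in sorted(items, key=lambda s: (-len(s), s)):
        container = next((t for t in out if s in t), None)
        if container is None:
            out[s] = items[s]
        else:
            out[container] |= items[s]
    return out


def _overlap_union(a: str, b: str) -> str | None:
    """a followed by b with maximal exact suffix/prefix overlap, if that
    overlap is at least min(len)-1; containment returns the container."""
    if b in a:
        return a
    if a in b:
        return b
    need = min(len(a), len(b)) - 1
    top = min(len(a), len(b))
    for olap in range(top, need - 1, -1):
        if olap > 0 and a[-olap:] == b[:olap]:
            return a + b[olap:]
    return None


def _identity_to_known(candidate: str, known: str) -> float:
    """Best identity of the candidate against a known sequence over all
    ungapped offsets: matches / candidate length."""
    best = 0
    for off in range(-len(candidate) + 1, len(known)):
        m = sum(1 for i, ch in enumerate(candidate)
                if 0 <= off + i < len(known) and known[off + i] == ch)
        best = max(best, m)
    return best / len(candidate)


def load_known_contaminants(path: str | Path | None = None
                            ) -> dict[str, str]:
    """Name -> sequence table from a FASTA file; without a path, the
    bundled list of common adapters is used."""
    from Bio import SeqIO

    if path is None:
        ref = resources.files("pairtrim.data") / "contaminants.fasta"
        with resources.as_file(ref) as p:
            return {rec.description: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(p), "fasta")}
    return {rec.description: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def detect(reads: list[ReadRecord] | list[str],
           params: DetectParams | None = None) -> list[ContaminantHit]:
    """Rank likely adapter/contaminant sequences in a read sample."""
    params = params or DetectParams()
    seqs_all = [r if isinstance(r, str) else r.bases for r in reads]
    seqs_all = seqs_all[:params.sample_size]
    if not seqs_all:
        import logging
        logging.getLogger(__name__).warning(
            "adapter detection got an empty read sample")
        return []
    read_length = max(len(s) for s in seqs_all)

    # poly-A pre-trim + low-complexity read filter
    kept: list[str] = []
    indices: list[int] = []
    for i, s in enumerate(seqs_all):
        idx = s.find("A" * params.polyA_min_run)
        if idx >= 0:
            s = s[:idx]
        if len(s) < params.k0:
            continue
        if complexity(s) < params.complexity_threshold:
            continue
        kept.append(s)
        indices.append(i)
    if not kept:
        return []

    qualifying: dict[str, set[int]] = {}
    k = params.k0
    cur_seqs, cur_idx = kept, indices
    k_cap = max(params.k0, read_length // 2)
    while k <= k_cap and cur_seqs:
        thr = abundance_threshold(params, read_length, k)
        counts = _count_kmers(cur_seqs, k)
        good = {km for km, c in counts.items()
                if c > thr and c >= params.min_count
                and complexity(km) >= params.complexity_threshold}
        if not good:
            break
        links = _link_reads(cur_seqs, cur_idx, k, good)
        qualifying.update(links)
        linked = set().union(*links.values())
        nxt = [(s, i) for s, i in zip(cur_seqs, cur_idx) if i in linked]
        cur_seqs = [s for s, _ in nxt]
        cur_idx = [i for _, i in nxt]
        k *= 2

    if not qualifying:
        return []
    merged = _merge_overlapping(qualifying)

    hits = []
    for seq, readset in merged.items():
        keff = min(len(seq), read_length)
        expect = params.sample_size * (read_length - keff + 1) / 4.0 ** keff
        hits.append(ContaminantHit(
            sequence=seq, count=len(readset),
            abundance_ratio=len(readset) / expect if expect > 0
            else float("inf")))

    if params.known_contaminants:
        for h in hits:
            best = None
            for name, kseq in params.known_contaminants.items():
                ident = _identity_to_known(h.sequence, kseq)
                if ident >= params.known_identity and (
                        best is None or ident > best[1]):
                    best = (name, ident)
            h.known_match = best

    hits.sort(key=lambda h: (h.known_match is None,
                             -h.count * len(h.sequence), h.sequence))
    hits = hits[:params.max_report]
    for rank, h in enumerate(hits, 1):
        h.rank = rank
    return hits


def report_json(hits: list[ContaminantHit], path: str | Path) -> None:
    payload = {
        "schema": "pairtrim/detect/1",
        "hits": [
            {
                "rank": h.rank,
                "sequence": h.sequence,
                "count": h.count,
                "abundance_ratio": h.abundance_ratio,
                "known_match": None if h.known_match is None else
                {"name": h.known_match[0], "identity": h.known_match[1]},
            }
            for h in hits
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def format_report(hits: list[ContaminantHit]) -> str:
    if not hits:
        return "No over-represented sequences detected.\n"
    lines = [f"{'rank':>4}  {'count':>7}  {'ratio':>10}  sequence"]
    for h in hits:
        label = f"  [{h.known_match[0]} {h.known_match[1]:.0%}]" \
            if h.known_match else ""
        lines.append(f"{h.rank:>4}  {h.count:>7}  {h.abundance_ratio:>10.3g}"
                     f"  {h.sequence}{label}")
    return "\n".join(lines) + "\n"
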