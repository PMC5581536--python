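"""Score trimmed output against simulator ground truth.

Each trimmed mate is compared with the known adapter start position and
assigned at most one category:

* *wrongly trimmed* - the fragment contains no adapter but bases were
  removed anyway;
* *over-trimmed*    - the fragment contains an adapter and too many bases
  were removed;
* *under-trimmed*   - the fragment contains an adapter and too few bases
  were removed (correctness requires the exact trim point).

Pairs discarded by the length filter are counted separately, not as
trimming errors.  Base-level error is the number of over- plus
under-trimmed bases over all original bases.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import fastq
from .records import pair_name
from .sim import TruthRecord


class TrimCategory(enum.Enum):
    CORRECT = "correct"
    WRONGLY = "wrongly"
    OVER = "over"
    UNDER = "under"


def classify_read(trimmed_length: int, adapter_start: int | None,
                  original_length: int
                  ) -> tuple[TrimCategory, int, int]:
    """Classify one mate; returns (category, over_bases, under_bases)."""
    if trimmed_length > original_length:
        raise ValueError("trimmed read longer than the original")
    if adapter_start is None:
        if trimmed_length < original_length:
            return TrimCategory.WRONGLY, original_length - trimmed_length, 0
        return TrimCategory.CORRECT, 0, 0
    if trimmed_length > adapter_start:
        return TrimCategory.UNDER, 0, trimmed_length - adapter_start
    if trimmed_length < adapter_start:
        return TrimCategory.OVER, adapter_start - trimmed_length, 0
    return TrimCategory.CORRECT, 0, 0


@dataclass
class AccuracyReport:
    total_pairs: int
    total_reads: int
    total_bases: int
    correct_reads: int
    wrongly_reads: int
    over_reads: int
    under_reads: int
    discarded_pairs: int
    discarded_reads: int
    over_bases: int
    under_bases: int

    @property
    def read_error_pct(self) -> float:
        """(wrongly + over + under) reads as % of all reads."""
        errs = self.wrongly_reads + self.over_reads + self.under_reads
        return 100.0 * errs / self.total_reads if self.total_reads else 0.0

    @property
    def read_error_pct_pairs(self) -> float:
        errs = self.wrongly_reads + self.over_reads + self.under_reads
        return 100.0 * errs / self.total_pairs if self.total_pairs else 0.0

    @property
    def base_error_pct(self) -> float:
        bases = self.over_bases + self.under_bases
        return 100.0 * bases / self.total_bases if self.total_bases else 0.0

    @property
    def discarded_fraction(self) -> float:
        return self.discarded_pairs / self.total_pairs if self.total_pairs \
            else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            read_error_pct=self.read_error_pct,
            read_error_pct_pairs=self.read_error_pct_pairs,
            base_error_pct=self.base_error_pct,
            discarded_fraction=self.discarded_fraction,
        )
        return d

    def write_json(self, path: str | Path) -> None:
        payload = {"schema": "pairtrim/accuracy/1", **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def format_table(self) -> str:
        rows = [
            ("Total pairs", self.total_pairs),
            ("Total reads", self.total_reads),
            ("Wrongly trimmed reads", self.wrongly_reads),
            ("Over-trimmed reads", self.over_reads),
            ("Under-trimmed reads", self.under_reads),
            ("Read-level total error (%)", f"{self.read_error_pct:.4f}"),
            ("Over-trimmed bases", self.over_bases),
            ("Under-trimmed bases", self.under_bases),
            ("Base-level total error (%)", f"{self.base_error_pct:.6f}"),
            ("Discarded pairs", self.discarded_pairs),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def read_truth_table(path: str | Path
                     ) -> tuple[list[TruthRecord], int | None]:
    """Load a truth table; returns the records and the read length parsed
    from the header comment (None when absent)."""
    read_length = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = re.search(r"read_length=(\d+)", first)
        if m:
            read_length = int(m.group(1))
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"name": str, "insert_seq": str},
                     keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        a1 = None if row.adapter_start1 == "" else int(row.adapter_start1)
        a2 = None if row.adapter_start2 == "" else int(row.adapter_start2)
        records.append(TruthRecord(str(row.name), int(row.insert_length),
                                   a1, a2, str(row.insert_seq)))
    return records, read_length


def _lengths_from_fastq(path: str | Path) -> dict[str, int]:
    return {pair_name(r.name): len(r) for r in fastq.read_fastq(path)}


def evaluate(truths: list[TruthRecord], read_length: int,
             lengths1: dict[str, int], lengths2: dict[str, int] | None = None,
             merged: bool = False) -> AccuracyReport:
    """Aggregate per-mate classifications into an accuracy report.

    ``lengths1``/``lengths2`` map pair names to trimmed lengths; a pair
    absent from the output counts as discarded.  With ``merged`` a single
    length map describes merged reads covering the full insert, implying
    the symmetric per-mate trim point.
    """
    counts = {c: 0 for c in TrimCategory}
    over_b = under_b = 0
    discarded_pairs = 0
    seen = set()
    for t in truths:
        if merged:
            if t.name in lengths1:
                seen.add(t.name)
                trim = min(read_length, lengths1[t.name])
                mate_lengths = (trim, trim)
            else:
                mate_lengths = None
        else:
            l1 = lengths1.get(t.name)
            l2 = None if lengths2 is None else lengths2.get(t.name)
            if l1 is None or (lengths2 is not None and l2 is None):
                mate_lengths = None
            else:
                seen.add(t.name)
                mate_lengths = (l1, l2) if l2 is not None else (l1,)
        if mate_lengths is None:
            discarded_pairs += 1
            continue
        starts = (t.adapter_start1, t.adapter_start2)
        for mate_len, astart in zip(mate_lengths, starts):
            cat, ob, ub = classify_read(mate_len, astart, read_length)
            counts[cat] += 1
            over_b += ob
            under_b += ub
    extra = (set(lengths1) | set(lengths2 or {})) - {t.name for t in truths}
    if extra:
        raise ValueError(
            f"trimmed records not present in the truth table: "
            f"{sorted(extra)[:5]}")
    mates_per_pair = 1 if (lengths2 is None and not merged) else 2
    total_pairs = len(truths)
    total_reads = mates_per_pair * total_pairs
    return AccuracyReport(
        total_pairs=total_pairs,
        total_reads=total_reads,
        total_bases=total_reads * read_length,
        correct_reads=counts[TrimCategory.CORRECT],
        wrongly_reads=counts[TrimCategory.WRONGLY],
        over_reads=counts[TrimCategory.OVER],
        under_reads=counts[TrimCategory.UNDER],
        discarded_pairs=discarded_pairs,
        discarded_reads=mates_per_pair * discarded_pairs,
        over_bases=over_b,
        under_bases=under_b,
    )


def evaluate_files(truth_path: str | Path, trimmed1: str | Path,
                   trimmed2: str | Path | None = None,
                   merged: bool = False,
                   read_length: int | None = None) -> AccuracyReport:
    """Evaluate trimmed FASTQ files against a truth table."""
    truths, rl = read_truth_table(truth_path)
    rl = read_length or rl
    if rl is None:
        raise ValueError("read length not recorded in truth table; "
                         "pass read_length explicitly")
    lengths1 = _lengths_from_fastq(trimmed1)
    lengths2 = _lengths_from_fastq(trimmed2) if trimmed2 else None
    return evaluate(truths, rl, lengths1, lengths2, merged=merged)
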