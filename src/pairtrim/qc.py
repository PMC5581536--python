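"""FastQC-style quality-control metrics.

Metrics are accumulated in a single pass and can be collected before
(PRE) and/or after (POST) trimming in the same run.  Collection is a
pure observer - it never alters the records - and two summaries merge
associatively, so per-worker accumulation equals a single pass over the
concatenated input.

Collected per summary: a position x Phred count matrix, a per-read
mean-quality histogram, per-position base composition (A/C/G/T/N),
a GC-content histogram (integer percent), the read-length distribution,
and total read/base counts.  Quality binning is exact: one bin per
Phred value.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .records import MAX_PHRED, ReadRecord

_BASE_ORDER = "ACGTN"
_BASE_INDEX = np.full(256, 4, dtype=np.int64)  # anything odd counts as N
for _i, _b in enumerate(_BASE_ORDER.encode("ascii")):
    _BASE_INDEX[_b] = _i


class Stage(enum.Enum):
    PRE = "pre"
    POST = "post"


@dataclass
class QCSummary:
    stage: Stage = Stage.PRE
    total_reads: int = 0
    total_bases: int = 0
    #: shape (max_len, MAX_PHRED+1): count of reads with quality q at pos
    quality_by_position: np.ndarray = field(
        default_factory=lambda: np.zeros((0, MAX_PHRED + 1), dtype=np.int64))
    #: shape (max_len, 5): base composition per position (A,C,G,T,N)
    base_by_position: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 5), dtype=np.int64))
    #: histogram over rounded per-read mean quality (0..MAX_PHRED)
    mean_quality_hist: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_PHRED + 1, dtype=np.int64))
    #: histogram over integer GC percent (0..100)
    gc_hist: np.ndarray = field(
        default_factory=lambda: np.zeros(101, dtype=np.int64))
    #: read-length distribution {length: count}
    length_hist: dict[int, int] = field(default_factory=dict)

    def _grow(self, n: int) -> None:
        if n <= self.quality_by_position.shape[0]:
            return
        q = np.zeros((n, MAX_PHRED + 1), dtype=np.int64)
        b = np.zeros((n, 5), dtype=np.int64)
        q[:self.quality_by_position.shape[0]] = self.quality_by_position
        b[:self.base_by_position.shape[0]] = self.base_by_position
        self.quality_by_position = q
        self.base_by_position = b

    def add(self, read: ReadRecord) -> None:
        n = len(read)
        self.total_reads += 1
        self.total_bases += n
        self.length_hist[n] = self.length_hist.get(n, 0) + 1
        if n == 0:
            return
        self._grow(n)
        pos = np.arange(n)
        self.quality_by_position[pos, read.qualities] += 1
        codes = _BASE_INDEX[np.frombuffer(read.bases.encode("ascii"),
                                          dtype=np.uint8)]
        self.base_by_position[pos, codes] += 1
        mean_q = int(round(float(read.qualities.mean())))
        self.mean_quality_hist[mean_q] += 1
        gc = int(round(100.0 * np.count_nonzero((codes == 1) | (codes == 2))
                       / n))
        self.gc_hist[gc] += 1

    def merge(self, other: "QCSummary") -> "QCSummary":
        self._grow(other.quality_by_position.shape[0])
        q, b = other.quality_by_position, other.base_by_position
        self.quality_by_position[:q.shape[0]] += q
        self.base_by_position[:b.shape[0]] += b
        self.mean_quality_hist += other.mean_quality_hist
        self.gc_hist += other.gc_hist
        self.total_reads += other.total_reads
        self.total_bases += other.total_bases
        for k, v in other.length_hist.items():
            self.length_hist[k] = self.length_hist.get(k, 0) + v
        return self

    def to_dict(self) -> dict:
        return {
            "stage": self.stage.value,
            "total_reads": self.total_reads,
            "total_bases": self.total_bases,
            "quality_by_position": self.quality_by_position.tolist(),
            "base_by_position": self.base_by_position.tolist(),
            "base_order": _BASE_ORDER,
            "mean_quality_hist": self.mean_quality_hist.tolist(),
            "gc_hist": self.gc_hist.tolist(),
            "length_hist": {str(k): v
                            for k, v in sorted(self.length_hist.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCSummary":
        s = cls(stage=Stage(d["stage"]))
        s.total_reads = d["total_reads"]
        s.total_bases = d["total_bases"]
        s.quality_by_position = np.array(d["quality_by_position"],
                                         dtype=np.int64).reshape(
            -1, MAX_PHRED + 1)
        s.base_by_position = np.array(d["base_by_position"],
                                      dtype=np.int64).reshape(-1, 5)
        s.mean_quality_hist = np.array(d["mean_quality_hist"],
                                       dtype=np.int64)
        s.gc_hist = np.array(d["gc_hist"], dtype=np.int64)
        s.length_hist = {int(k): v for k, v in d["length_hist"].items()}
        return s


def collect(reads: Iterable[ReadRecord], stage: Stage = Stage.PRE
            ) -> QCSummary:
    """Accumulate a QC summary over reads in one pass."""
    summary = QCSummary(stage=stage)
    for read in reads:
        summary.add(read)
    return summary


def write_summary(summaries: Iterable[QCSummary], path: str | Path) -> None:
    """One JSON document per sample, containing every collected stage;
    serialization is byte-stable (sorted keys) and round-trips."""
    payload = {
        "schema": "pairtrim/qc/1",
        "stages": {s.stage.value: s.to_dict() for s in summaries},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_summary(path: str | Path) -> dict[str, QCSummary]:
    payload = json.loads(Path(path).read_text())
    return {k: QCSummary.from_dict(v)
            for k, v in payload["stages"].items()}
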