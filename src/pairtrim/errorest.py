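"""Per-file sequencing error-rate estimation from base qualities.

Each Phred score q encodes a base-call error probability 10^(-q/10); the
estimate is the mean of those probabilities over all bases in a sample
of reads.  It is fast but tends to overestimate the true error rate,
since base callers are conservative at read ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .records import ReadRecord


@dataclass
class ErrorEstimate:
    per_file_error: float
    sample_size: int                  # reads actually used
    total_bases: int
    per_position_error: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "schema": "pairtrim/error-estimate/1",
            "per_file_error": self.per_file_error,
            "sample_size": self.sample_size,
            "total_bases": self.total_bases,
        }
        if self.per_position_error is not None:
            d["per_position_error"] = [float(x)
                                       for x in self.per_position_error]
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))


def estimate_error(reads: Iterable[ReadRecord],
                   sample_size: int = 10_000,
                   per_position: bool = False) -> ErrorEstimate:
    """Mean base-call error probability over the first ``sample_size``
    reads; order-invariant in the estimate and monotone decreasing in
    any quality increase."""
    total = 0.0
    n_bases = 0
    n_reads = 0
    pos_sum: np.ndarray | None = None
    pos_n: np.ndarray | None = None
    for read in reads:
        if n_reads >= sample_size:
            break
        n_reads += 1
        e = 10.0 ** (-read.qualities.astype(float) / 10.0)
        total += float(e.sum())
        n_bases += e.size
        if per_position:
            if pos_sum is None or e.size > pos_sum.size:
                grow = e.size
                new_sum = np.zeros(grow)
                new_n = np.zeros(grow, dtype=np.int64)
                if pos_sum is not None:
                    new_sum[:pos_sum.size] = pos_sum
                    new_n[:pos_n.size] = pos_n
                pos_sum, pos_n = new_sum, new_n
            pos_sum[:e.size] += e
            pos_n[:e.size] += 1
    if n_reads == 0:
        raise ValueError("cannot estimate an error rate from zero reads")
    per_pos = None
    if per_position and pos_sum is not None:
        per_pos = pos_sum / np.maximum(pos_n, 1)
    return ErrorEstimate(total / n_bases, n_reads, n_bases, per_pos)


def estimate_error_shadow(reads, sample_size: int = 10_000):
    """Shadow-regression error estimation (named but not implemented).

    The method regresses counts of near-duplicate 'shadow' reads on read
    abundance (Wang et al.); it is defined outside this package's scope.
    """
    raise NotImplementedError(
        "shadow-regression error estimation is not implemented; "
        "use the quality-averaging estimator (estimate_error)")
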