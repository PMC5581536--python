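"""Sequencing-read records.

A :class:`ReadRecord` is the unit that flows through every stage of the
toolkit: a named nucleotide sequence with per-base Phred quality scores.
Qualities are stored as integer Phred values (0-93); on disk they are
Phred+33 ASCII, one FASTQ record per four lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHRED_OFFSET = 33
MAX_PHRED = 93


@dataclass
class ReadRecord:
    """A named read with per-base Phred qualities.

    Parameters
    ----------
    name:
        Read identifier (FASTQ header without the leading ``@``).
    bases:
        Nucleotide string over ``{A, C, G, T, N}`` (upper case).
    qualities:
        Integer Phred scores, same length as ``bases``.
    mate:
        Optional mate number (1 or 2) for paired-end data.
    """

    name: str
    bases: str
    qualities: np.ndarray
    mate: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.bases) != q.shape[0]:
            raise ValueError(
                f"read {self.name!r}: {len(self.bases)} bases but "
                f"{q.shape[0]} quality values"
            )
        if q.size and q.max() > MAX_PHRED:
            raise ValueError(f"read {self.name!r}: Phred score > {MAX_PHRED}")
        self.qualities = q

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def quality_string(self) -> str:
        return (self.qualities + PHRED_OFFSET).tobytes().decode("ascii")

    @classmethod
    def from_strings(cls, name: str, bases: str, quality_string: str,
                     mate: int | None = None) -> "ReadRecord":
        q = np.frombuffer(quality_string.encode("ascii"), dtype=np.uint8)
        if q.size and (q.min() < PHRED_OFFSET):
            raise ValueError(f"read {name!r}: quality character below '!'")
        return cls(name, bases.upper(), q - PHRED_OFFSET, mate)

    def slice(self, start: int, stop: int) -> "ReadRecord":
        """Return the sub-read covering ``[start, stop)`` (bases and
        qualities trimmed in lockstep)."""
        return ReadRecord(self.name, self.bases[start:stop],
                          self.qualities[start:stop], self.mate)

    def mean_error_prob(self) -> float:
        """Mean base-call error probability implied by the qualities."""
        if len(self) == 0:
            return 0.0
        return float(np.mean(10.0 ** (-self.qualities.astype(float) / 10.0)))

    def to_fastq(self) -> str:
        return f"@{self.name}\n{self.bases}\n+\n{self.quality_string}\n"


def pair_name(name: str) -> str:
    """Canonical pair identifier: first whitespace token, without a
    trailing ``/1`` or ``/2``."""
    token = name.split(None, 1)[0]
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token
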