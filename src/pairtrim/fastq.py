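"""FASTQ reading and writing, plain or gzip-compressed.

Supports single files, two-file paired input and interleaved paired input.
Parsing is delegated to Biopython's FastqGeneralIterator; writing emits
standard 4-line records with Phred+33 qualities.  Gzip output files written
in separate members are safe to concatenate.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import ReadRecord, pair_name


class FastqError(Exception):
    """Malformed or inconsistent FASTQ input."""


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path, mate: int | None = None) -> Iterator[ReadRecord]:
    """Iterate over the records of a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for name, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord.from_strings(name, seq, qual, mate)


def read_paired(path1: str | Path, path2: str | Path
                ) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Iterate over synchronized read pairs from two FASTQ files.

    Raises :class:`FastqError` naming the offending record if one file
    runs out before the other or if names fall out of sync.
    """
    it1 = read_fastq(path1, mate=1)
    it2 = read_fastq(path2, mate=2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            orphan = r2 if r1 is sentinel else r1
            raise FastqError(
                f"unpaired record {orphan.name!r}: input files have "
                "different numbers of reads"
            )
        if pair_name(r1.name) != pair_name(r2.name):
            raise FastqError(
                f"read pair out of sync: {r1.name!r} vs {r2.name!r}"
            )
        yield r1, r2


def read_interleaved(path: str | Path
                     ) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Iterate over read pairs from an interleaved FASTQ file."""
    it = read_fastq(path)
    for r1 in it:
        r2 = next(it, None)
        if r2 is None:
            raise FastqError(
                f"interleaved input ends with unpaired record {r1.name!r}"
            )
        if pair_name(r1.name) != pair_name(r2.name):
            raise FastqError(
                f"interleaved records out of sync: {r1.name!r} vs {r2.name!r}"
            )
        r1.mate, r2.mate = 1, 2
        yield r1, r2


class FastqWriter:
    """Write ReadRecords to a FASTQ file, gzipping if the path ends in .gz."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._handle = _open_text(self.path, "wt")

    def write(self, read: ReadRecord) -> None:
        self._handle.write(read.to_fastq())

    def write_text(self, text: str) -> None:
        self._handle.write(text)

    def close(self) -> None:
        self._handle.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def records_to_text(reads: Iterable[ReadRecord]) -> str:
    return "".join(r.to_fastq() for r in reads)


def parse_fastq_text(text: str, mate: int | None = None) -> list[ReadRecord]:
    """Parse 4-line FASTQ records from an in-memory string."""
    lines = text.splitlines()
    if len(lines) % 4:
        raise FastqError("FASTQ text length is not a multiple of 4 lines")
    out = []
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i:i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FastqError(f"malformed FASTQ record at line {i + 1}")
        out.append(ReadRecord.from_strings(header[1:], seq, qual, mate))
    return out
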