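"""End-to-end FASTQ trimming pipeline.

Per-read modifiers (fixed-base cutting, adapter/insert trimming, quality
trimming with an optional NextSeq poly-G mode, linked adapters) and the
minimum-length filter are orchestrated over single-end or paired-end
input, serially or with a parallel reader/worker/writer architecture.

Modifier order is fixed: fixed-base cuts first (technical bases should
not take part in alignment), then adapter or insert trimming, then
quality trimming (after adapter removal so that overhang evidence is not
destroyed), then the length filter; both mates always receive the same
stack.

Parallel execution contract: a reader thread cuts the input into
fixed-size batches that preserve file order and feeds a bounded queue;
independent worker processes apply the whole modifier/filter stack to
entire batches; output is produced in one of three modes

* ``WORKER_COMPRESS`` - workers gzip-compress their results, a single
  serializer writes one ordered stream (gzip members concatenate);
* ``WRITER_COMPRESS`` - workers return text, the serializer compresses;
* ``PARALLEL_WRITE``  - every worker writes its own output file pair; the
  serializer is replaced by an extra worker, and one more worker starts
  as soon as the reader finishes.

All modes produce the same multiset of output records, and read pairs
remain in sync within any single output stream.
"""

from __future__ import annotations

import dataclasses
import enum
import gzip
import json
import multiprocessing as mp
import queue
import threading
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from . import fastq
from .align import AdapterEnd, AdapterSpec, semiglobal_align, trim_by_location
from .insertmatch import (
    CorrectionPolicy,
    InsertMatchParams,
    insert_trim_pair,
)
from .records import ReadRecord


class PipelineError(Exception):
    pass


# ---------------------------------------------------------------------------
# Per-read modifiers and filters


def quality_trim(read: ReadRecord, cutoff: int) -> ReadRecord:
    """Trim the 3' end by the partial-sum method.

    The cut point maximizes the running sum of ``cutoff - q`` accumulated
    from the 3' end; the suffix is removed only when that maximum is
    positive, so a cutoff of 0 is the identity.  Equivalent to a brute
    force over all cut points.
    """
    if cutoff <= 0 or len(read) == 0:
        return read
    return _partial_sum_trim(read, cutoff - read.qualities.astype(np.int64))


def nextseq_trim(read: ReadRecord, cutoff: int) -> ReadRecord:
    """Quality trimming for two-channel (NextSeq) chemistry.

    G is encoded as a dark cycle, so trailing G runs carry untrustworthy
    high qualities; G bases are scanned as quality 0.
    """
    if cutoff < 1 or len(read) == 0:
        return read
    q = read.qualities.astype(np.int64).copy()
    codes = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8)
    q[codes == ord("G")] = 0
    return _partial_sum_trim(read, cutoff - q)


def _partial_sum_trim(read: ReadRecord, deficit: np.ndarray) -> ReadRecord:
    s = np.cumsum(deficit[::-1])
    t = int(np.argmax(s))  # first maximum from the 3' end = shortest trim
    if s[t] <= 0:
        return read
    return read.slice(0, len(read) - (t + 1))


def fixed_trim(read: ReadRecord, front_n: int, back_n: int) -> ReadRecord:
    """Unconditionally remove ``front_n`` leading and ``back_n`` trailing
    bases, clamped at the read length."""
    if front_n < 0 or back_n < 0:
        raise ValueError("cut lengths must be non-negative")
    n = len(read)
    start = min(front_n, n)
    stop = max(start, n - back_n)
    return read.slice(start, stop)


@dataclass
class LinkedTrimInfo:
    found5: bool = False
    found3: bool = False


def linked_adapter_trim(read: ReadRecord, five_prime: AdapterSpec,
                        three_prime: AdapterSpec
                        ) -> tuple[ReadRecord, LinkedTrimInfo]:
    """Linked 5'+3' adapter: locate the 5' adapter first (anchored by
    default), then search the 3' adapter only downstream of it; the span
    between them is retained."""
    info = LinkedTrimInfo()
    loc5 = semiglobal_align(five_prime, read)
    if loc5 is not None:
        info.found5 = True
        read = trim_by_location(read, AdapterEnd.FRONT, loc5)
    loc3 = semiglobal_align(three_prime, read)
    if loc3 is not None:
        info.found3 = True
        read = trim_by_location(read, AdapterEnd.BACK, loc3)
    return read, info


def length_filter(pair: tuple[ReadRecord, ReadRecord | None],
                  min_length: int) -> bool:
    """True (keep) unless either mate is shorter than ``min_length``."""
    r1, r2 = pair
    if len(r1) < min_length:
        return False
    return not (r2 is not None and len(r2) < min_length)


# ---------------------------------------------------------------------------
# Configuration and statistics


class Aligner(enum.Enum):
    ADAPTER = "adapter"
    INSERT = "insert"


class OutputMode(enum.Enum):
    WORKER_COMPRESS = "worker"
    WRITER_COMPRESS = "writer"
    PARALLEL_WRITE = "parallel"


@dataclass
class TrimConfig:
    aligner: Aligner = Aligner.INSERT
    adapter1: AdapterSpec | None = None
    adapter2: AdapterSpec | None = None
    insert_params: InsertMatchParams = field(default_factory=InsertMatchParams)
    correction: CorrectionPolicy = field(default_factory=CorrectionPolicy)
    quality_cutoff: int = 0          # 0 = off
    nextseq_mode: bool = False
    cut_front: int = 0
    cut_back: int = 0
    min_length: int = 25
    threads: int = 1
    #: None selects automatically: writer compression below 8 threads,
    #: worker compression at 8 or more.
    output_mode: OutputMode | None = None
    batch_size: int = 5000

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.aligner is Aligner.ADAPTER and self.adapter1 is None \
                and self.adapter2 is None:
            # adapter-match with no adapters degenerates to quality-only
            # trimming; that is allowed.
            pass

    def resolved_output_mode(self) -> OutputMode:
        if self.output_mode is not None:
            return self.output_mode
        return (OutputMode.WORKER_COMPRESS if self.threads >= 8
                else OutputMode.WRITER_COMPRESS)


@dataclass
class TrimStats:
    pairs_read: int = 0
    pairs_written: int = 0
    pairs_discarded: int = 0
    reads_adapter_trimmed1: int = 0
    reads_adapter_trimmed2: int = 0
    bases_removed_adapter: int = 0
    bases_removed_quality: int = 0
    bases_removed_fixed: int = 0
    pairs_merged: int = 0
    outcome_tags: Counter = field(default_factory=Counter)

    def merge(self, other: "TrimStats") -> "TrimStats":
        for f in dataclasses.fields(self):
            if f.name == "outcome_tags":
                self.outcome_tags.update(other.outcome_tags)
            else:
                setattr(self, f.name,
                        getattr(self, f.name) + getattr(other, f.name))
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_tags"] = dict(self.outcome_tags)
        return d

    def write_json(self, path: str | Path) -> None:
        payload = {"schema": "pairtrim/trim-stats/1", **self.to_dict()}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Record processing


def _adapter_match_read(read: ReadRecord, spec: AdapterSpec | None
                        ) -> tuple[ReadRecord, int]:
    if spec is None:
        return read, 0
    loc = semiglobal_align(spec, read)
    if loc is None:
        return read, 0
    trimmed = trim_by_location(read, spec.where, loc)
    return trimmed, len(read) - len(trimmed)


def process_pair(r1: ReadRecord, r2: ReadRecord | None, config: TrimConfig,
                 stats: TrimStats) -> tuple[ReadRecord, ...] | None:
    """Apply the full modifier/filter stack to one pair (or single read).

    Returns the records to write, or None when the pair is discarded.
    """
    stats.pairs_read += 1
    if config.cut_front or config.cut_back:
        for r in (r1, r2):
            if r is not None:
                stats.bases_removed_fixed += min(
                    len(r), config.cut_front + config.cut_back)
        r1 = fixed_trim(r1, config.cut_front, config.cut_back)
        if r2 is not None:
            r2 = fixed_trim(r2, config.cut_front, config.cut_back)

    merged = None
    if config.aligner is Aligner.INSERT and r2 is not None:
        out = insert_trim_pair(r1, r2, config.insert_params,
                               config.correction)
        stats.outcome_tags[out.tag] += 1
        stats.bases_removed_adapter += out.trimmed1 + out.trimmed2
        if out.trimmed1:
            stats.reads_adapter_trimmed1 += 1
        if out.trimmed2:
            stats.reads_adapter_trimmed2 += 1
        if out.merged is not None:
            merged = out.merged
            stats.pairs_merged += 1
        else:
            r1, r2 = out.read1, out.read2
    else:
        spec1, spec2 = config.adapter1, config.adapter2
        if config.aligner is Aligner.INSERT:
            # single-end data under the insert aligner: fall back to the
            # configured insert adapters for plain adapter matching
            spec1 = spec1 or config.insert_params.adapter1
            spec2 = spec2 or config.insert_params.adapter2
        r1, t1 = _adapter_match_read(r1, spec1)
        stats.bases_removed_adapter += t1
        if t1:
            stats.reads_adapter_trimmed1 += 1
        if r2 is not None:
            r2, t2 = _adapter_match_read(r2, spec2)
            stats.bases_removed_adapter += t2
            if t2:
                stats.reads_adapter_trimmed2 += 1
        stats.outcome_tags["adapter"] += 1

    if config.quality_cutoff > 0:
        trim = nextseq_trim if config.nextseq_mode else quality_trim
        if merged is not None:
            before = len(merged)
            merged = trim(merged, config.quality_cutoff)
            stats.bases_removed_quality += before - len(merged)
        else:
            before = len(r1) + (len(r2) if r2 is not None else 0)
            r1 = trim(r1, config.quality_cutoff)
            if r2 is not None:
                r2 = trim(r2, config.quality_cutoff)
            after = len(r1) + (len(r2) if r2 is not None else 0)
            stats.bases_removed_quality += before - after

    if merged is not None:
        keep = len(merged) >= config.min_length
        records = (merged,)
    else:
        keep = length_filter((r1, r2), config.min_length)
        records = (r1,) if r2 is None else (r1, r2)
    if not keep:
        stats.pairs_discarded += 1
        return None
    stats.pairs_written += 1
    return records


def _process_batch(pairs: Iterable[tuple[ReadRecord, ReadRecord | None]],
                   config: TrimConfig) -> tuple[str, str, TrimStats]:
    """Process a batch; returns FASTQ text for each output stream."""
    stats = TrimStats()
    out1: list[str] = []
    out2: list[str] = []
    for r1, r2 in pairs:
        records = process_pair(r1, r2, config, stats)
        if records is None:
            continue
        out1.append(records[0].to_fastq())
        if len(records) > 1:
            out2.append(records[1].to_fastq())
    return "".join(out1), "".join(out2), stats


# ---------------------------------------------------------------------------
# I/O plumbing


@dataclass
class PairedEndFiles:
    """Input or output locations: two files, one interleaved file, or a
    single file for single-end data."""
    path1: str | Path
    path2: str | Path | None = None
    interleaved: bool = False

    @property
    def paired(self) -> bool:
        return self.path2 is not None or self.interleaved


def _iter_input(files: PairedEndFiles
                ) -> Iterator[tuple[ReadRecord, ReadRecord | None]]:
    if files.interleaved:
        yield from fastq.read_interleaved(files.path1)
    elif files.path2 is not None:
        yield from fastq.read_paired(files.path1, files.path2)
    else:
        for r in fastq.read_fastq(files.path1):
            yield r, None


def _iter_batches(files: PairedEndFiles, batch_size: int
                  ) -> Iterator[list[tuple[ReadRecord, ReadRecord | None]]]:
    batch: list = []
    for pair in _iter_input(files):
        batch.append(pair)
        if len(batch) >= batch_size:
            yield batch
            batch = []
    if batch:
        yield batch


def worker_output_paths(out: PairedEndFiles, worker: int) -> PairedEndFiles:
    """Per-worker output paths for PARALLEL_WRITE: ``x.fq.gz`` becomes
    ``x.w3.fq.gz`` for worker 3."""
    def tag(p):
        p = Path(p)
        suffix = "".join(p.suffixes[-2:] if p.suffixes[-1:] == [".gz"]
                         else p.suffixes[-1:])
        stem = p.name[:len(p.name) - len(suffix)]
        return p.with_name(f"{stem}.w{worker}{suffix}")
    return PairedEndFiles(
        tag(out.path1),
        tag(out.path2) if out.path2 is not None else None,
        out.interleaved)


def _encode_chunk(text: str, path: str | Path, compress: bool) -> bytes:
    data = text.encode("ascii")
    if compress and str(path).endswith(".gz"):
        return gzip.compress(data)
    return data


def _open_sink(path: str | Path, pre_compressed: bool):
    """Binary sink; transparent gzip unless the payload is already
    compressed (worker-compression mode)."""
    if str(path).endswith(".gz") and not pre_compressed:
        return gzip.open(path, "wb")
    return open(path, "wb")


# ---------------------------------------------------------------------------
# Engines


def _run_serial(config: TrimConfig, inputs: PairedEndFiles,
                outputs: PairedEndFiles) -> TrimStats:
    stats = TrimStats()
    two_streams = outputs.path2 is not None
    with fastq.FastqWriter(outputs.path1) as w1:
        w2 = fastq.FastqWriter(outputs.path2) if two_streams else None
        try:
            for r1, r2 in _iter_input(inputs):
                records = process_pair(r1, r2, config, stats)
                if records is None:
                    continue
                if w2 is not None and len(records) > 1:
                    w1.write(records[0])
                    w2.write(records[1])
                else:
                    for rec in records:
                        w1.write(rec)
        finally:
            if w2 is not None:
                w2.close()
    return stats


def _worker_loop(in_q, out_q, config: TrimConfig, mode: OutputMode,
                 outputs: PairedEndFiles, worker_id: int) -> None:
    try:
        writer1 = writer2 = None
        if mode is OutputMode.PARALLEL_WRITE:
            wpaths = worker_output_paths(outputs, worker_id)
            writer1 = fastq.FastqWriter(wpaths.path1)
            if wpaths.path2 is not None:
                writer2 = fastq.FastqWriter(wpaths.path2)
        while True:
            item = in_q.get()
            if item is None:
                break
            idx, text1, text2, paired = item
            pairs = _decode_batch(text1, text2, paired)
            t1, t2, stats = _process_batch(pairs, config)
            if mode is OutputMode.PARALLEL_WRITE:
                writer1.write_text(t1)
                if writer2 is not None:
                    writer2.write_text(t2)
                out_q.put(("batch", idx, None, None, stats))
            elif mode is OutputMode.WORKER_COMPRESS:
                out_q.put(("batch", idx,
                           _encode_chunk(t1, outputs.path1, True),
                           _encode_chunk(t2, outputs.path2, True)
                           if outputs.path2 is not None else None,
                           stats))
            else:
                out_q.put(("batch", idx, t1, t2, stats))
        if writer1 is not None:
            writer1.close()
        if writer2 is not None:
            writer2.close()
        out_q.put(("done", worker_id, None, None, None))
    except Exception as exc:  # pragma: no cover - transported to parent
        import traceback
        out_q.put(("error", worker_id, repr(exc),
                   traceback.format_exc(), None))


def _decode_batch(text1, text2, paired):
    if not paired:
        return [(r, None) for r in fastq.parse_fastq_text(text1)]
    if text2 is None:  # interleaved transport
        recs = fastq.parse_fastq_text(text1)
        return list(zip(recs[0::2], recs[1::2]))
    recs1 = fastq.parse_fastq_text(text1, mate=1)
    recs2 = fastq.parse_fastq_text(text2, mate=2)
    return list(zip(recs1, recs2))


def _encode_batches(inputs: PairedEndFiles, batch_size: int
                    ) -> Iterator[tuple[int, str, str | None, bool]]:
    paired = inputs.paired
    for idx, batch in enumerate(_iter_batches(inputs, batch_size)):
        if not paired:
            yield idx, "".join(r.to_fastq() for r, _ in batch), None, False
        else:
            t1 = "".join(r1.to_fastq() for r1, _ in batch)
            t2 = "".join(r2.to_fastq() for _, r2 in batch)
            yield idx, t1, t2, True


def _run_parallel(config: TrimConfig, inputs: PairedEndFiles,
                  outputs: PairedEndFiles) -> TrimStats:
    mode = config.resolved_output_mode()
    if mode is OutputMode.PARALLEL_WRITE:
        n_workers = config.threads
    else:
        n_workers = max(1, config.threads - 1)
    ctx = mp.get_context()
    in_q: mp.Queue = ctx.Queue(maxsize=2 * n_workers + 2)
    out_q: mp.Queue = ctx.Queue()

    workers = [
        ctx.Process(target=_worker_loop,
                    args=(in_q, out_q, config, mode, outputs, wid))
        for wid in range(n_workers)
    ]
    for w in workers:
        w.start()

    extra_started = threading.Event()

    def feed() -> None:
        for item in _encode_batches(inputs, config.batch_size):
            in_q.put(item)
        if mode is OutputMode.PARALLEL_WRITE:
            # reader finished: its slot is recycled into one more worker
            w = ctx.Process(target=_worker_loop,
                            args=(in_q, out_q, config, mode, outputs,
                                  n_workers))
            w.start()
            workers.append(w)
            extra_started.set()
        for _ in range(n_workers + (1 if mode is OutputMode.PARALLEL_WRITE
                                    else 0)):
            in_q.put(None)

    feeder = threading.Thread(target=feed, daemon=True)
    feeder.start()

    stats = TrimStats()
    pending: dict[int, tuple] = {}
    next_idx = 0
    done = 0
    expected_done = n_workers + (1 if mode is OutputMode.PARALLEL_WRITE else 0)

    sink1 = sink2 = None
    if mode is not OutputMode.PARALLEL_WRITE:
        pre = mode is OutputMode.WORKER_COMPRESS
        sink1 = _open_sink(outputs.path1, pre)
        if outputs.path2 is not None:
            sink2 = _open_sink(outputs.path2, pre)

    def flush() -> None:
        nonlocal next_idx
        while next_idx in pending:
            c1, c2 = pending.pop(next_idx)
            if sink1 is not None:
                sink1.write(c1 if isinstance(c1, bytes)
                            else c1.encode("ascii"))
                if sink2 is not None and c2 is not None:
                    sink2.write(c2 if isinstance(c2, bytes)
                                else c2.encode("ascii"))
            next_idx += 1

    try:
        while done < expected_done:
            kind, a, b, c, batch_stats = out_q.get()
            if kind == "error":
                raise PipelineError(f"worker {a} failed: {b}\n{c}")
            if kind == "done":
                done += 1
                if done == n_workers and mode is OutputMode.PARALLEL_WRITE \
                        and not extra_started.is_set():
                    # feeder may still be about to launch the extra worker
                    extra_started.wait(timeout=60)
                continue
            stats.merge(batch_stats)
            if mode is not OutputMode.PARALLEL_WRITE:
                pending[a] = (b, c)
                flush()
        flush()
    finally:
        if sink1 is not None:
            sink1.close()
        if sink2 is not None:
            sink2.close()
        feeder.join(timeout=60)
        for w in workers:
            w.join(timeout=60)
    return stats


def run_pipeline(config: TrimConfig, inputs: PairedEndFiles,
                 outputs: PairedEndFiles) -> TrimStats:
    """Run the full trimming pipeline.

    Output content (as a multiset of records) is independent of thread
    count and output mode; record order can differ only in
    ``PARALLEL_WRITE`` mode across the per-worker files.
    """
    for p in filter(None, (inputs.path1, inputs.path2)):
        if not Path(p).exists():
            raise PipelineError(f"input file not found: {p}")
    for p in filter(None, (outputs.path1, outputs.path2)):
        parent = Path(p).parent
        if not parent.is_dir():
            raise PipelineError(f"output directory does not exist: {parent}")
    if config.threads == 1:
        return _run_serial(config, inputs, outputs)
    return _run_parallel(config, inputs, outputs)
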