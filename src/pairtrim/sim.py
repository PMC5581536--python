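"""Ground-truth paired-end read simulation.

Emulates adapter-contaminated Illumina-style libraries: an insert is
drawn per pair from a configurable length distribution; each mate reads
the insert from its own end, and whenever the insert is shorter than the
read length the 3' adapter (then random filler) is appended so every read
reaches full length.  Per-base substitution errors are drawn from base
qualities, which come either from an empirical quality-score profile or
from a flat profile matching a target error rate.

The quality-profile utilities implement the benchmark-style error-rate
computation and inflation: a profile stores, per read position, quality
score bins (error probabilities ``e_i``) with read counts ``r_i``; the
overall error rate is the count-weighted mean of the ``e_i``, and a
profile is inflated to a target rate by adding an equal count ``C`` to
every bin, with ``C`` found by one-dimensional root finding.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .insertmatch import (
    TRUSEQ_ADAPTER_R1,
    TRUSEQ_ADAPTER_R2,
    reverse_complement,
)
from .records import ReadRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class QualityProfile:
    """Per-position quality-score distributions.

    ``bins[pos]`` is a pair of arrays ``(e, r)``: quality bins expressed
    as error probabilities, and non-negative read counts.  Every position
    must have at least one positive count.
    """

    bins: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = []
        for e, r in self.bins:
            e = np.asarray(e, dtype=float)
            r = np.asarray(r, dtype=float)
            if e.shape != r.shape or e.ndim != 1 or e.size == 0:
                raise ValueError("each position needs matching e/r arrays")
            if (r < 0).any():
                raise ValueError("counts must be non-negative")
            if r.sum() <= 0:
                raise ValueError("each position needs a positive count")
            clean.append((e, r))
        self.bins = clean

    @classmethod
    def flat(cls, error_rate: float, read_length: int) -> "QualityProfile":
        e = np.array([error_rate])
        r = np.array([1.0])
        return cls([(e.copy(), r.copy()) for _ in range(read_length)])

    def added(self, c: float) -> "QualityProfile":
        return QualityProfile([(e.copy(), r + c) for e, r in self.bins])


def profile_error_rate(profile: QualityProfile) -> float:
    """Overall error rate of a profile: E = sum(e_i r_i) / sum(r_i),
    aggregated over all positions."""
    num = sum(float(e @ r) for e, r in profile.bins)
    den = sum(float(r.sum()) for _, r in profile.bins)
    if den <= 0:
        raise ValueError("profile has all-zero counts")
    return num / den


def inflate_profile(profile: QualityProfile, target: float,
                    tol: float = 1e-9) -> tuple[QualityProfile, float]:
    """Add an equal count C >= 0 to every bin so the overall error rate
    reaches ``target``; returns (inflated profile, C).

    As C grows the rate moves monotonically from the current rate toward
    the unweighted mean of the bin error probabilities, which bounds the
    reachable range; targets outside it are rejected.
    """
    current = profile_error_rate(profile)
    n_bins = sum(e.size for e, _ in profile.bins)
    mean_e = sum(float(e.sum()) for e, _ in profile.bins) / n_bins

    def f(c: float) -> float:
        num = sum(float(e @ (r + c)) for e, r in profile.bins)
        den = sum(float((r + c).sum()) for _, r in profile.bins)
        return num / den - target

    lo, hi = sorted((current, mean_e))
    if not lo - tol <= target <= hi + tol:
        raise ValueError(
            f"target error rate {target} unreachable by count inflation; "
            f"reachable interval is [{lo:.6g}, {hi:.6g}]")
    if abs(f(0.0)) <= tol:
        return profile.added(0.0), 0.0
    c_hi = 1.0
    while f(0.0) * f(c_hi) > 0 and c_hi < 1e18:
        c_hi *= 10.0
    c = brentq(f, 0.0, c_hi, xtol=1e-15, rtol=8.9e-16)
    assert abs(f(c)) < tol
    return profile.added(c), float(c)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults match the benchmark geometry: 125 bp paired reads, TruSeq 3'
    adapters, insert lengths from a normal(mean 200, sd 60) truncated to
    [1, 400] (re-drawn until inside the interval), and a flat base-call
    error rate.
    """

    n_pairs: int
    seed: int
    read_length: int = 125
    insert_mean: float = 200.0
    insert_sd: float = 60.0
    insert_min: int = 1
    insert_max: int = 400
    adapter1: str = TRUSEQ_ADAPTER_R1
    adapter2: str = TRUSEQ_ADAPTER_R2
    target_error_rate: float = 0.002
    profile: QualityProfile | None = None
    name_prefix: str = "sim"

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.read_length < 1:
            raise ValueError("n_pairs and read_length must be >= 1")
        if self.insert_min < 1 or self.insert_max < self.insert_min:
            raise ValueError("invalid insert length bounds")
        for ad in (self.adapter1, self.adapter2):
            if len(ad) > self.read_length:
                raise ValueError("adapter longer than the read length")


@dataclass
class TruthRecord:
    """Simulator ground truth for one pair."""
    name: str
    insert_length: int
    #: position of the first adapter base in each mate (== insert length
    #: when the insert is shorter than the read; None otherwise)
    adapter_start1: int | None
    adapter_start2: int | None
    insert_seq: str = ""


def _draw_insert_lengths(rng: np.random.Generator, cfg: SimConfig
                         ) -> np.ndarray:
    out = np.empty(cfg.n_pairs, dtype=np.int64)
    need = np.ones(cfg.n_pairs, dtype=bool)
    while need.any():
        draw = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd,
                                  int(need.sum()))).astype(np.int64)
        ok = (draw >= cfg.insert_min) & (draw <= cfg.insert_max)
        idx = np.nonzero(need)[0]
        out[idx[ok]] = draw[ok]
        need[idx[ok]] = False
    return out


def _phred_from_error(e: float) -> int:
    if e <= 0:
        return 93
    return int(min(93, max(0, round(-10.0 * np.log10(e)))))


def _flat_qualities(rng: np.random.Generator, target: float,
                    shape: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-base qualities realizing a flat target error rate exactly.

    Phred scores are integers, so a single score cannot hit an arbitrary
    rate; bases are drawn from the two adjacent integer scores mixed so
    that the mean of their implied error probabilities equals the target.
    Substitution probabilities equal the stored quality's 10^(-q/10), so
    the quality strings are honest about the injected errors.
    """
    if target <= 0:
        phred = np.full(shape, 93, dtype=np.uint8)
        return np.zeros(shape), phred
    x = -10.0 * np.log10(target)
    q1 = int(np.floor(x))
    if abs(x - round(x)) < 1e-12:  # exact integer Phred
        phred = np.full(shape, int(round(x)), dtype=np.uint8)
        return np.full(shape, target), phred
    q2 = q1 + 1
    e1, e2 = 10.0 ** (-q1 / 10.0), 10.0 ** (-q2 / 10.0)
    frac_q1 = (target - e2) / (e1 - e2)
    pick1 = rng.random(shape) < frac_q1
    phred = np.where(pick1, q1, q2).astype(np.uint8)
    err = np.where(pick1, e1, e2)
    return err, phred


def _sample_position_qualities(rng, profile: QualityProfile, read_length: int,
                               n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-base error probabilities and Phred scores, shape (n, L)."""
    errs = np.empty((n, read_length))
    for pos in range(read_length):
        e, r = profile.bins[min(pos, len(profile.bins) - 1)]
        p = r / r.sum()
        errs[:, pos] = rng.choice(e, size=n, p=p)
    phred = np.clip(np.rint(-10.0 * np.log10(np.maximum(errs, 1e-10))),
                    0, 93).astype(np.uint8)
    return errs, phred


def simulate_pairs(config: SimConfig):
    """Generate read pairs with ground truth.

    Returns ``(pairs, truths)`` where ``pairs`` is a list of
    (ReadRecord, ReadRecord) and ``truths`` the matching TruthRecords.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_length
    lengths = _draw_insert_lengths(rng, config)
    a1 = np.frombuffer(config.adapter1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(config.adapter2.encode("ascii"), dtype=np.uint8)

    if config.profile is not None:
        err_all, phred_all = _sample_position_qualities(
            rng, config.profile, L, 2 * config.n_pairs)
    else:
        err_all, phred_all = _flat_qualities(
            rng, config.target_error_rate, (2 * config.n_pairs, L))

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_pairs):
        ins_len = int(lengths[i])
        insert = _BASES[rng.integers(0, 4, ins_len)]
        rc_insert = _rc_codes(insert)

        t1 = _compose(insert, a1, L, rng)
        t2 = _compose(rc_insert, a2, L, rng)
        name = f"{config.name_prefix}:{i}"
        r1 = _finish_read(t1, err_all[2 * i], phred_all[2 * i], rng,
                          name, 1)
        r2 = _finish_read(t2, err_all[2 * i + 1], phred_all[2 * i + 1], rng,
                          name, 2)
        pairs.append((r1, r2))
        astart = ins_len if ins_len < L else None
        truths.append(TruthRecord(
            name, ins_len, astart, astart,
            insert.tobytes().decode("ascii")))
    return pairs, truths


_RC_MAP = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _RC_MAP[_x] = _y


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_MAP[codes[::-1]]


def _compose(template: np.ndarray, adapter: np.ndarray, read_length: int,
             rng: np.random.Generator) -> np.ndarray:
    """Insert prefix + adapter + random filler, clipped to read length."""
    if template.shape[0] >= read_length:
        return template[:read_length].copy()
    parts = [template, adapter[:read_length - template.shape[0]]]
    have = sum(p.shape[0] for p in parts)
    if have < read_length:
        parts.append(_BASES[rng.integers(0, 4, read_length - have)])
    return np.concatenate(parts)


def _finish_read(template: np.ndarray, err: np.ndarray, phred: np.ndarray,
                 rng: np.random.Generator, name: str, mate: int
                 ) -> ReadRecord:
    """Apply substitution errors: each base is replaced, with probability
    equal to its error rate, by one of the three other nucleotides."""
    codes = template.copy()
    hit = rng.random(codes.shape[0]) < err
    if hit.any():
        idx = np.nonzero(hit)[0]
        # current base index 0..3; shift by 1..3 mod 4 for a different base
        cur = np.searchsorted(_BASES, codes[idx])
        shift = rng.integers(1, 4, idx.shape[0])
        codes[idx] = _BASES[(cur + shift) % 4]
    return ReadRecord(name, codes.tobytes().decode("ascii"),
                      phred.copy(), mate)


TRUTH_COLUMNS = ("name", "insert_length", "adapter_start1",
                 "adapter_start2", "insert_seq")


def write_truth_table(truths, path: str | Path, config: SimConfig) -> None:
    """Tab-separated truth table with a commented header recording the
    generating conditions."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write(f"# pairtrim truth table; read_length={config.read_length} "
                 f"insert=normal(mean={config.insert_mean},"
                 f"sd={config.insert_sd}) truncated "
                 f"[{config.insert_min},{config.insert_max}] "
                 f"seed={config.seed}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(f"{t.name}\t{t.insert_length}\t"
                     f"{'' if t.adapter_start1 is None else t.adapter_start1}"
                     f"\t"
                     f"{'' if t.adapter_start2 is None else t.adapter_start2}"
                     f"\t{t.insert_seq}\n")


def simulate_to_files(config: SimConfig, prefix: str | Path,
                      compress: bool = True) -> tuple[Path, Path, Path]:
    """Simulate and write ``<prefix>_1.fq[.gz]``, ``<prefix>_2.fq[.gz]``
    and ``<prefix>_truth.tsv``."""
    from .fastq import FastqWriter

    prefix = Path(prefix)
    ext = ".fq.gz" if compress else ".fq"
    p1 = prefix.parent / f"{prefix.name}_1{ext}"
    p2 = prefix.parent / f"{prefix.name}_2{ext}"
    pt = prefix.parent / f"{prefix.name}_truth.tsv"
    pairs, truths = simulate_pairs(config)
    with FastqWriter(p1) as w1, FastqWriter(p2) as w2:
        for r1, r2 in pairs:
            w1.write(r1)
            w2.write(r2)
    write_truth_table(truths, pt, config)
    return p1, p2, pt
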