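# Methods

This note documents the models and procedures implemented in `pairtrim`,
the parameters that matter, the design decisions taken where the design
was genuinely open, and what the synthetic benchmark does and does not
show about real data.

## Semi-global adapter alignment

Adapter occurrence is modelled as a semi-global alignment in edit space:
rather than maximizing an alignment score, the aligner computes edit
distances for every allowed shift of the adapter relative to the read
and accepts a shift when its *error rate* — edits divided by the number
of aligned adapter characters — is at most `max_error_rate` (default
0.1) and the aligned adapter length is at least `min_overlap` (default
3).  Among accepted shifts the one with the most matching columns wins.
This gives users one intuitive tolerance knob instead of a score matrix
and avoids the degenerate zero-length optima that unpenalized end gaps
would otherwise create.

Implementation: one DP column (of the *D*/*M*/*O* matrices) is kept at a
time; no backtrace is needed because the origin *O* is carried through
the recurrence.  A Ukkonen-style cutoff stops extending a column once
the cost exceeds the maximum edits any acceptable candidate could have
(`floor(max_error_rate * m)`); since costs along a DP path never
decrease, pruned cells can only lead to rejected candidates, so the
cutoff is result-transparent (asserted by test).  The inner loop is
numba-compiled; a pure-Python full-matrix brute force serves as the test
oracle, with edit distances additionally cross-checked against edlib.

Degenerate inputs and tie-breaks:

* Ties on match count resolve by fewer errors, then longer aligned
  adapter span, then leftmost read start, then earliest end position
  (mirrored for 5' adapters, which are scanned as the reverse problem).
  Inside a DP cell, diagonal transitions are preferred; an equal-cost
  gap transition wins only with strictly more matches.  These rules make
  the result fully deterministic; the alternatives they choose among are
  equivalent under the acceptance criterion.
* `N` in a read matches nothing unless the adapter character is `N`:
  a run of no-calls must not fake an adapter hit.  Adapter-side IUPAC
  codes match by 4-bit mask intersection.
* Base qualities play no role in alignment; only the quality trimmer and
  the overlap consensus read them.
* `min_overlap` applies to the aligned *adapter* length (the error-rate
  denominator); with indels enabled the aligned read span may differ by
  up to the edit count.
* Anchored adapters restrict candidates to alignments flush with the
  read end; anchored + indels-disabled switches to a Hamming fast path
  over the read prefix/suffix, which provably agrees with the DP under
  the same constraints (asserted by test).

## Insert matching

For a read pair whose insert is shorter than the read length, read 1 and
revcomp(read 2) overlap over the entire insert, and the bases past the
overlap are adapter (plus downstream filler).  The matcher scans every
relative shift with 3'-end overlap — an indel-free special case of the
aligner, evaluated for all shifts at once by cross-correlating one-hot
base encodings — and keeps shifts passing three thresholds:

| threshold | default | meaning |
|---|---|---|
| `min_insert_overlap` | 10 bases | smallest overlap considered |
| `max_mismatch_frac` | 0.2 | mismatches as a fraction of overlap |
| `max_random_match_prob` | 1e-6 | binomial tail P(X >= matches), X ~ B(overlap, 0.25) |

Defaults were chosen so that a random 125 bp pair passes with
probability below 1e-6 per shift (the shortest admissible overlap, 10
bases matched perfectly, has chance 0.25^10 ≈ 9.5e-7); they are
user-overridable.  The mismatch threshold is exposed as a fraction; an
absolute reading of the same knob is `ceil(frac * overlap)`.

Candidates are tested in decreasing overlap order.  A candidate implying
overhangs must be *confirmed*: each adapter is laid against its read's
overhang at the offset the candidate fixes.  Because the adapter
position is symmetric across a proper pair, confirmation in either mate
sets the trim point for both.  Overhang confirmation uses a relaxed
mismatch tolerance (0.2) with no binomial gate and no minimum length:
the offset is already constrained by the insert match (it adds no
degrees of freedom), overhangs can be as short as one base, and 3' ends
carry most sequencing error.  A candidate whose insert length reaches
the read length has no overhangs and nothing to trim; it is accepted
directly (and still supports error correction and merging).

When no candidate is confirmed, each adapter is matched independently in
its own read by the semi-global aligner.  This fallback is additionally
gated by the same binomial specificity threshold (matches vs aligned
length): an ungated fallback at `min_overlap` 3 would trim a random
3-base suffix from roughly one in sixty-four adapter-free reads, which
would dominate the error budget of a high-specificity paired-end
trimmer.  With the gate, a spurious trim requires ~10 matched bases
(chance ≈ 1e-6 per read position at the read end).  The plain
adapter-match aligner mode (`--aligner adapter`) remains ungated,
classical behaviour.

Error correction over the overlap keeps, per disagreeing column, the
base with the higher Phred quality (written complemented into read 2);
the column's quality becomes the max of the two, so correction never
lowers quality.  Quality ties follow a policy: keep both, mask both to
N, or take the read with the higher mean quality (the default when
correction is enabled).  Corrections are counted as changed base
assignments, so a tie masked to N counts twice.  Optionally, when one
mate's mean error probability exceeds 3x the other's, the poor mate's
overlap is overwritten wholesale from the better mate; and a matched
pair can be merged into a single read covering the full insert
(read-1-only prefix + consensus overlap + reverse-complemented read-2
suffix), which avoids double-counting overlapping pairs in
depth-based analyses.  Whether correction should also run after the
fallback path is underdetermined; it runs only on the insert path,
where the overlap is actually established.

## Trimming pipeline

Modifier order is fixed: fixed-base cuts, then adapter/insert trimming,
then quality trimming, then the minimum-length filter (default 25 bp;
a pair is discarded when either mate falls below it).  Fixed cuts
precede alignment because they remove technical bases; quality trimming
follows adapter removal so that low-quality overhang evidence still
participates in insert matching.  Both mates always receive the same
stack.

Quality trimming uses the partial-sum (BWA-style) rule: cut at the
position maximizing the running sum of `(cutoff - q)` accumulated from
the 3' end, trimming only when that maximum is positive; ties resolve
toward trimming less.  This equals a brute-force search over all cut
points (asserted by test).  NextSeq mode treats G bases as quality 0
during the scan, because two-channel chemistry encodes G as a dark
cycle and trailing G runs carry fabricated high qualities.  Note the
scan is global over the suffix: a long internal G run can legitimately
pull the cut point past downstream high-quality bases.

Parallel execution: a reader thread batches input (default 5000
pairs/batch) into a bounded queue; worker processes apply the full stack
to whole batches; output follows one of three modes — workers compress
(gzip members concatenate safely), the writer compresses, or every
worker writes its own files, in which case the writer slot becomes an
extra worker and one more worker starts when the reader finishes.  With
an explicit mode unset, writer compression is used below 8 threads and
worker compression at 8+, following the usual crossover on commodity
hardware.  All modes produce the same record multiset, pairs never
desynchronize within a stream, and `pairs_read == pairs_written +
pairs_discarded` holds in every run.  The bounded input queue caps
memory at roughly `2 * workers + 2` batches in flight.

## Adapter detection

From a sample of reads (the first 10,000 by default, matching how a
quick look at a FASTQ file is usually taken; a seeded random sample is
available), reads are pre-trimmed at runs of >= 8 A's (read-through
into poly-A signals the template ended) and dropped when their
nucleotide-composition Shannon entropy is below 1.0 bit.  The
composition entropy is computed over frequency fractions; with raw
counts in the logarithm the quantity would be negative for any count
above one and the 1-bit rule vacuous.  k-mers (k = 12 initially) are
counted once per supporting read; a k-mer is over-represented when its
count exceeds `N * (l - k + 1) * O / 4^k` (O = 100), i.e. 100x the
uniform-random expectation, *and* reaches at least 2 reads — for k
around 16+ the analytic threshold drops below one count, and a
singleton k-mer is never evidence.  Iteration doubles k (12, 24, 48,
capped at half the read length) on the reads linked to surviving
k-mers.  Surviving k-mers of all lengths are merged: unambiguous
(k-1)-overlaps are chained unitig-style, exact suffix/prefix overlaps of
at least min(len)-1 are unioned, and sequences contained in longer ones
are dropped, so a planted adapter is reported as one full-length
sequence rather than a pile of windows.  A merged hit's count is the
number of distinct supporting reads.  Hits are ranked with
known-contaminant matches first (>= 90% ungapped identity against the
bundled or user-supplied FASTA of common adapters), then by count x
length; at most 20 are reported.  A high-abundance sequence matching no
known adapter may simply be a genomic repeat — the report says what is
over-represented, not what is safe to trim.

## Error estimation and QC

The error estimator averages `10^(-q/10)` over all bases of the sampled
reads (default 10,000).  It is order-invariant, monotone in every
quality value, and tends to overestimate true error because base
callers are conservative near read ends.  Shadow-regression estimation
is exposed as a named option that fails fast with a pointer, not an
implementation.

QC collection is a pure observer: per-position quality counts (exact,
one bin per Phred value), per-read mean-quality histogram, per-position
base composition including N, GC histogram, and length distribution.
Summaries merge associatively (enabling per-worker accumulation) and
serialize to versioned, byte-stable JSON.  FastQC's duplication-level
and over-represented-sequence panels are intentionally out of scope.

## Synthetic benchmark

The simulator emulates an adapter-contaminated paired-end library: per
pair an integer insert length is drawn from a normal distribution (mean
200, sd 60) truncated to [1, 400] by redrawing; read 1 is the insert
prefix, read 2 the reverse-complement insert prefix, and whenever the
insert is shorter than the 125 bp read the 3' adapter (TruSeq read-1/
read-2 stems by default) then uniform-random filler pads the read.
These are the package's benchmark study conditions; the insert
distribution is configurable and recorded in the truth-table header.
Substitution errors are injected per base with probability
`10^(-q/10)` of the *stored* quality, so quality strings are honest.  A
flat target rate is realized by mixing the two adjacent integer Phred
scores in the exact proportion whose mean implied error equals the
target (a single integer score can be up to ~12% off).  Alternatively
an empirical quality profile — per-position (error-probability, count)
bins — can be supplied; its overall rate is the count-weighted mean of
the bin probabilities, and it can be inflated to a target rate by
adding an equal count C to every bin.  C is found by Brent root-finding
on the defect function (the defect is monotone in C toward the
unweighted bin mean, which bounds the reachable range; the closed-form
solution of the linear equation supplies the bracket), to |defect| <
1e-9.

What the simulator does *not* model: indel sequencing errors,
position-dependent error enrichment (unless a profile is supplied),
quality-correlated error bursts, PCR duplicates, barcode/UMI structure,
and biased base composition.  Passing the benchmark therefore
demonstrates the geometry and specificity of the trimming algorithms
under calibrated substitution noise — not performance on protocol
artifacts outside that model (e.g. bisulfite conversion, poly-G tails
are exercised separately).

The evaluator classifies each mate against the truth: *wrongly trimmed*
(no adapter present, bases removed anyway), *over-* / *under-trimmed*
(adapter present, trim point below/above the true adapter start;
correctness requires the exact position, a +-0 tolerance), else
correct.  Pairs discarded by the length filter are tallied separately,
not as trimming errors.  Read-level error percentages are reported over
mates (with a pairs-denominator variant in the JSON, since either
convention appears in the field); base-level error is (over + under
bases) / all original bases.

## Problem sizes

The bundled accuracy benchmark (`scripts/acceptance.py` and the
acceptance tests) runs 100,000 pairs per error rate (0.2%, 0.6%, 1.2%)
— about 30 s per run on one CPU; exact-recovery checks are exhaustive
over insert lengths 10..124; detection round-trips use 10,000-read
samples over multiple seeds; pipeline determinism is checked on 10,000
pairs across thread counts {1, 4} and all three output modes.

## Known limitations

* Insert matching assumes inward-facing (FR) libraries; mate-pair
  (outward-facing) layouts and 5' adapter overhangs are out of scope.
* The aligner offers no affine gap model or local alignment, and no
  anywhere-in-read adapter type.
* bzip2/lzma codecs, SAM/BAM input, demultiplexing, colorspace data,
  and report rendering beyond JSON are out of scope.
* Detection merges k-mer evidence by exact overlap only; adapters whose
  occurrences are heavily mutated may be reported as fragments.
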