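# Methods

This note documents the model behind `tg-locate`, the defaults it ships
with, the design choices that were genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Staged alignment and the orphan-read signal

The caller never maps whole libraries to the host genome. Reads are first
aligned to the transgene construct alone; a pair with exactly one
transgene-mapped mate contributes its unmapped mate — an *orphaned read* —
to the host-genome stage. Because the mapped mate lies inside the
transgene array, the orphan must derive from host sequence within one
library fragment length of an array junction (or from host sequence
homologous to part of the construct). This staging converts the insertion
site into a localized pile of single-end host alignments and discards the
overwhelming host-only background before it is ever mapped.

Orphan status is decided on primary SAM records only; secondary and
supplementary alignments are ignored. This is the conservative flag-based
reading and keeps the definition aligner-independent. Reads whose own
sequence crosses an array junction (host/transgene chimeras, or spans of
the internal copy–copy boundary that do not exist in the single-copy
reference) map to neither reference and drop out at the host stage; their
mates still count as orphans when mapped, which is correct — the fragment
straddles a junction.

Coordinates are 1-based inclusive in SAM and in the orphan table on disk,
0-based half-open everywhere internally. The orphan table is a 13-column
TSV (name, host chrom/pos/strand/MAPQ/CIGAR, transgene
name/pos/strand/MAPQ, read length, DTN, flags) — a reconstruction of the
fields the scoring stage needs; the upstream format it imitates is not
machine-readable, so this dialect is our own and is documented here.

## Quality control

A read passes QC when at least 70 of its base calls have Phred quality
≥ 30 (defaults tuned to 100-bp reads; `--min-frac` scales the rule for
other lengths). The count is absolute, not a fraction. Whether the
original filtering dropped single reads or whole pairs is ambiguous; we
drop the whole pair when either mate fails, because a half-present pair
would later masquerade as an orphan created by QC rather than by the
transgene. The filter is idempotent and the report counts partition the
input exactly.

## DTN, duplicate removal and filtering

Within each chromosome, orphans are sorted by mapping coordinate and each
read's *distance to next* (DTN) is the gap to its successor; the last read
per chromosome gets +∞. DTN = 0 marks a PCR duplicate: removing all
DTN = 0 rows retains exactly one read per distinct coordinate (the last in
stable sort order). Duplicate removal ignores strand, since DTN is defined
purely on coordinate (`--stranded-dedup` would be the obvious extension;
the block scores count coordinates, so the default matches the scoring
semantics). The MAPQ filter (< 20 dropped, strict) applies to both the
host-side and transgene-side mapping quality. Filtering is idempotent and
recomputing DTN afterwards yields strictly positive values.

## Block scoring (TISS)

Chromosomes are tiled into fixed 1-kb blocks (the last block may be
short); the block count is always derived from the reference lengths. A
retained read is assigned to the block containing its 0-based start
coordinate, so every read is counted exactly once and the score total
equals the retained read count — a conservation law asserted in the test
suite. "Strictly within boundaries" is ambiguous for reads straddling a
block edge; assignment-by-start is the default and
`require_containment=True` implements the literal reading (straddling
reads are then lost and conservation intentionally fails). The per-block
count is the transgene insertion site score; DTN enters only through
duplicate removal, since the score itself is defined as a read count.

## Randomization thresholds

The null distribution is built by pushing replicate subsamples of a
transgene-free background read table through the identical DTN → filter →
score path and retaining each replicate's genome-wide maximum block score.
Thresholds are nearest-rank empirical quantiles (99/95/90% → α =
0.01/0.05/0.10); nearest-rank is used because the scores are small
integers and interpolation would invent non-achievable values. Replicate
seeds are `base_seed + replicate_index` and are recorded in the
`ThresholdSet` provenance. Defaults are 100 replicates of 100,000 reads —
at toy-genome scale the tests and the acceptance script use 10,000-read
replicates so the per-block background intensity stays comparable (about
one read per kilobase on a 10 Mb genome). The background is any
host-mapped read table; in simulation we use uniformly placed reads (the
idealized wild-type), and with real data one would subsample the
host-mapped read set of the library itself. Whether the original
randomization re-mapped sampled reads or subsampled mapped records is
ambiguous; we subsample mapped records, which is cheaper and
distributionally equivalent under a fixed mapping.

## Cluster calling and interpretation

Significant blocks (score ≥ threshold at the chosen α, always augmented
with the global top-5 for inspection) are merged when separated by at most
`max_gap` = 2 block lengths. A cluster's hull is the coordinate span of
its member reads; reads in sub-threshold blocks immediately flanking a run
(within `max_gap` of the hull) are attached too, because they belong to
the same pile and the hull edges carry the geometry — without them,
deletion lengths are overestimated by the width of the excluded edge
blocks. The attachment reach is clamped at the midpoint toward the
neighboring cluster, so hulls never overlap.

Interpretation is geometric:

* one cluster spanning ≲ 1.5 fragment lengths → clean insertion;
* two clusters on one chromosome with inner gap ≤ `pair_distance_max`
  (default 5 × fragment mean — the scale set by validated closely linked
  insertions ~11.5 kb apart under a ~3.8-kb library) → insertion with a
  host deletion, the inner gap estimating the deletion length. This is
  explicitly a hypothesis: two closely linked independent insertions
  produce the same signature, and only molecular validation (e.g. junction
  PCR) distinguishes them, so reports carry both readings;
* significant clusters on more than one chromosome → trans candidates.

Breakpoint intervals are strand-aware. In an fr (inward) library the
forward-strand orphans lie upstream of the junction, so a plus-dominant
cluster places the breakpoint just right of its rightmost plus-read end.
In an rf (outward, circularized mate-pair) library the convention is
inverted — the mate emitted at the fragment start is reverse-complemented
— so the strand roles swap. Implementing the rule orientation-aware was
necessary: applying the fr rule to rf data points the interval away from
the junction by a full fragment length. Balanced clusters fall back to a
one-block window at a hull edge (the edge facing the partner cluster when
one exists).

Exclusion regions (`--exclude` BED, `--exclude-chrom`) support the case
where the construct contains an expression cassette derived from the host
genome: the endogenous locus then accumulates a large legitimate-looking
cluster that must be masked from ranking. Exclusion is a reporting-stage
option; the reads are never removed from the table.

## The synthetic benchmark

`simulate` builds: a uniform-random host genome in which a chosen fraction
of each chromosome is tiled with non-overlapping, 1%-mutated copies of a
single repeat unit (default 6 kb — long enough that whole reads fall
inside a unit and multi-map, emulating the LINE-rich neighborhoods where
transgenes land); a transgenic allele `host[:p] + array + host[p+del:]`
where the array is a truncated first copy plus full tandem copies; and
seeded read pairs from a weighted allele mixture (hemizygous = 50/50
transgenic/wild-type). Pair count is `round(coverage · genome_len /
(2 · read_len))`; fragment lengths are truncated normal on
`[read_len, mean + 4 sd]` with `sd = 0.05 · mean` by default (real
insert-size dispersions are library-specific and unpublished for this
protocol; 5% is a typical tight Pippin-style selection). Orientation `rf`
emits outward-facing mates (fragment-start mate on the minus strand),
`fr` standard inward-facing mates. Substitution errors only — no indels,
no chimeras, no PCR amplification bias, no real repeat consensus
sequences. Base qualities come from a sticky two-state chain (~Q38 high,
~Q20 low, switch probability 0.002/base, 5% of reads starting low) chosen
so that the Q30/70 rule has both clear passes and clear failures; it is
not a calibrated error-quality model. Every pair's source allele, fragment
and per-mate coordinates go to a sidecar truth table, keeping the FASTQ
standard.

The built-in mapper is an exact k-mer seed (k = 21, three offsets, both
strands) with full-length ungapped extension allowing ≤ ⌈0.05 L⌉
mismatches. MAPQ is binary — 60 unique best, 0 ties (one location
reported, seeded) — because the pipeline only thresholds at 20, and a
binary scale makes test expectations exact. Candidate locations are
capped (default 100 per read); past the cap a read is reported MAPQ 0 at
one found location, the usual multi-mapping shortcut. No gapped alignment,
no pairing rescue, no split reads: it exists so the pipeline runs
hermetically, and production use should feed SAM from a real aligner
(default parameters for paired-end, `--rf -X 6000` for mate-pair against
the transgene; local very-sensitive alignment for orphans against the
host).

## What the benchmark shows — and problem sizes

Passing tests demonstrate the pipeline's internal correctness (oracle
equivalence for DTN, exact dedup semantics, score conservation, threshold
calibration on its own null) and that the geometry of recovery behaves as
the method claims: at 10X mate-pair coverage on a 10 Mb host with 20%
repeat content and a hemizygous 5 × 15 kb array, the top candidate
brackets the true insertion; an 11,456-bp host deletion is recovered from
the inter-cluster gap to within well under 2 kb (on a repeat-free host —
with a repeat unit sitting on a junction the nearest mappable orphan can
be kilobases away, and that mappability limit, not the estimator, bounds
accuracy); and a 3.8-kb rf library yields two orders of magnitude more
informative orphans than a 210-bp fr library at matched coverage. They do
not demonstrate performance on real data: real genomes have structured
repeat families, GC- and PCR-biased coverage, indel errors and chimeric
artifacts, and real transgene arrays rearrange internally. Array copy
number and internal structure are out of scope entirely, as are local host
inversions (invisible to this read geometry) and split-read breakpoint
detection.

Test and acceptance runs use hosts of 2–10 Mb rather than a full genome;
these sizes keep the per-block background intensity and
fragment-to-genome ratios in the regime where the method's behavior is
informative while remaining quick to recompute. All simulations,
subsampling and tie-breaks are driven by explicit seeds; fixed seeds give
byte-identical FASTA/FASTQ/SAM/TSV/JSON outputs.
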