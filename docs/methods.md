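# Methods

## Model and procedure

The filter treats an alignment file as a stream of records, each judged
against a canonical mask geometry. The mask is the union of the input
intervals: overlapping *and* abutting intervals are merged, so per-interval
overlap sums equal exact position-set intersections (no double counting)
and the zero-threshold adjacency test is well defined against a single
geometry regardless of how the mask was supplied. Coordinates are 0-based
half-open internally (the BED convention); RepeatMasker `.out` files are
1-based inclusive and converted on parse (`start = begin − 1`,
`end = end`). All RepeatMasker repeat classes are kept by default — the
mask is meant to cover *any* annotated repeat — with `--classes` as an
opt-in restriction.

A record's reference footprint comes from its CIGAR: maximal runs of
M/=/X emit reference intervals; D (deletion) and N (splice gap) advance
the reference and split blocks, so deleted and intronic positions never
count toward overlap — overlap measures sequenced bases sitting in the
mask; I/S/H/P neither advance the reference nor split a block (an
insertion leaves the reference footprint contiguous, matching pysam's
`get_blocks` up to its cosmetic split at insertions).

The decision for threshold τ ∈ [0, 100]:

* τ > 0: remove iff `overlap_bases / denominator ≥ τ/100`, evaluated as
  the integer comparison `100·overlap ≥ τ·denominator` to avoid float
  boundary artifacts at exact ratios such as 50/100.
* τ = 0: remove iff `overlap_bases ≥ 1` **or** some aligned block exactly
  touches a mask interval end-to-start. Removed(0) therefore strictly
  contains the τ→0⁺ limit; it is the most aggressive setting.
* Unmapped records: always kept (denominator 0, fraction 0), unless the
  user opts into dropping them.

The inequality is non-strict (≥). The two natural readings — "more than
the threshold" versus "at least τ percent" — differ only on exact-ratio
reads; ≥ was chosen because it keeps τ = 100 meaningful for exactly
fully-masked reads.

The default denominator is the **aligned length** (M/=/X bases). A read's
"total length" is ambiguous for clipped alignments; aligned length keeps
the fraction in [0, 1] with 1 attainable and is invariant to soft
clipping. `--denominator read` switches to the full query length
(M/I/S/=/X) for users who want clipped bases to dilute the fraction.

Secondary and supplementary records are judged independently by the same
rule as primaries.

## Pair handling

Mate semantics are a policy choice, so all behaviours are explicit modes
rather than a guess:

* `independent` (default) — each record judged alone; single pass.
* `drop-pair` — two passes: pass 1 collects the read names with any
  failing record, pass 2 drops every record bearing a collected name.
  Memory is proportional to the number of removed names, not file size;
  the input must be a seekable file.
* `--repair-flags` — kept records whose (primary) mate was removed get
  the mate-unmapped bit set and the proper-pair bit cleared. Knowing the
  mate's verdict requires a first pass, so this option also makes
  independent mode two-pass.

Output mirrors the input container (SAM→SAM, BAM→BAM), copies the header
verbatim plus one `@PG` line recording the parameters, preserves record
order, and writes kept records byte-identically (modulo opt-in flag
repair). Mask chromosomes absent from the header are inert and produce a
warning only.

## Alignment statistics

`flagstat` follows samtools-flagstat conventions: secondary and
supplementary records are excluded from the pairing counts;
properly-paired = paired ∧ proper-pair flag ∧ mapped; singleton = paired ∧
mapped ∧ mate unmapped; mate-different-chromosome = paired ∧ both mapped ∧
references differ. All three percentages use paired-in-sequencing as the
denominator for internal consistency (conventional flagstat output does
the same), and a zero denominator yields 0 by convention. QC-fail records
are not excluded from any category. `compare_stats` tabulates one row per
condition with deltas relative to the first condition.

## Synthetic data and the independent oracle

The generator exists so every claim is testable offline on a toy genome —
by default two chromosomes of 100 kb, large enough for splice gaps yet
small enough for per-base oracles. Masks are placed uniformly
(chromosomes weighted by length, lengths uniform in [min_len, max_len],
defaults 40 regions of 100–500 bp ≈ 6 % masked — the order of magnitude
of genome-wide low-complexity annotation) then merged. Reads are placed
uniformly over valid start positions; options add splice gaps (two M
blocks separated by 20–2000 bp of N), leading soft clips (up to a third
of the read), per-record unmapped status, and engineered
mate-on-another-chromosome pairs for the statistics tests. Sequences are
random A/C/G/T with constant quality, since the filter never inspects
them. Identical seeds give byte-identical SAM/BED output.

Ground truth is computed from **explicit per-base position sets**: the
CIGAR is walked one base at a time into a Python set, mask positions are
materialized the same way, overlap is set intersection, and blocks are
re-derived as maximal runs of consecutive integers for the adjacency
test. This path is memory-heavy and desk-scale only, deliberately sharing
no code with the production interval arithmetic it validates.

What the simulation does *not* emulate: sequencing errors and quality
profiles, non-uniform coverage, realistic insert-size distributions,
multi-mappers, or expression structure. Passing tests therefore establish
the correctness of the interval logic and bookkeeping, not performance
claims on any real library.

For a single mask interval of length m well inside a chromosome and
unspliced reads of length L placed uniformly over G valid starts, the
removal probability has closed form: with k = ⌈τL/100⌉ required overlap
bases, `count = m + L − 2k + 1` qualifying starts (0 if m < k), and at
τ = 0, `count = m + L + 1` (every ≥1-base overlap plus the two abutting
placements); p = count/G. Empirical rates from the full file-level filter
are checked against this within 3 binomial standard deviations at
n = 20,000 reads.

## Numerical and design choices

* Mask queries use binary search over per-chromosome sorted start/end
  arrays — O(log n + k) per query; an abutting query widens the window by
  one base on each side, turning touching into overlap.
* Threshold comparisons are integer-exact (see above); thresholds outside
  [0, 100] are errors, as are invalid CIGARs (offending token named) and
  malformed mask lines (line number named).
* Degenerate inputs: empty mask → nothing removed at any τ (including 0:
  no adjacency is possible); header-only input → empty output with
  percent_removed defined as 0; unknown chromosome in a query → empty
  result, not an error.
* Problem sizes in the test suite and acceptance script (10⁴ reads for
  oracle agreement, 2×10⁴ for rate recovery, toy 100 kb chromosomes) were
  chosen as the smallest sizes at which the binomial tolerances are
  informative; all checks complete in well under two minutes each.

## Known limitations

* The per-base oracle does not scale beyond toy genomes; it is a testing
  device, not an API.
* `drop-pair` assumes read names identify fragments; files with duplicate
  names across fragments will over-remove.
* No mapping-quality or base-quality awareness; no sorting, indexing or
  duplicate marking — the filter slots into a pipeline between those
  steps rather than replacing them.
* Flag repair only consults primary records when deciding whether a mate
  was removed; a removed supplementary alignment alone does not trigger
  repair.
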