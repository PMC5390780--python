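# Methods

## Problem and scope

Targeted pre-tRNA 3′-end libraries amplify the 3′ half of selected
intron-containing tRNA precursors, from a primer inside the intron to the
ligated 3′ adapter. Each read therefore reports one precursor molecule's 3′
terminus. The pipeline's job is to decide, per read, where the templated
sequence ends relative to the annotated gene end and what non-templated
bases follow, and to aggregate those calls into per-gene, per-library
summaries. No differential testing between libraries is performed; the
output is descriptive.

## Reference model

Per-gene precursor references are built as `leader + gene body (introns
retained) + trailer` in sense orientation; minus-strand genes are
reverse-complemented on load, with intron intervals stated gene-relative.
Coordinates are 0-based half-open internally. Defaults: 30 nt leader,
50 nt trailer — with 100-nt reads and precursor trailers of at most a few
tens of nucleotides, 50 nt of trailer places any read 3′ end; both are
configurable. `N` bases never match during templated-extension checks.

Aligning to per-gene precursor references rather than a whole genome is a
deliberate substitution: the libraries are amplicon-targeted, so a
whole-genome search adds only the ability to detect off-target reads. That
ability is retained as QC — the assigned fraction is reported and a warning
is raised when it falls below the 96% expectation for such libraries.

## Preprocessing

* **Quality filter**: reads with mean Phred ≥ 30 are kept (inclusive
  threshold). The filter's exact historical definition (per-read mean,
  per-base, or chastity) is not recoverable for vendor pipelines; mean-Q30
  is the conventional read-level reading, and a `min` mode is exposed.
* **Adapter removal**: the read *begins* with the adapter
  `TGGAATTCTCGGGTGCCAAGGC` (reverse complement of the ligated 3′ adapter),
  so trimming searches adapter suffixes as read prefixes, longest first,
  down to a 4-base minimum overlap, tolerating `floor(0.1·overlap)`
  mismatches. Reads shorter than 15 nt after trimming are discarded; reads
  with no adapter found are kept (alignment adjudicates).
* Reads are reverse-complemented into sense orientation and identical
  sequences collapsed with counts (descending count, then lexicographic —
  deterministic output). Read counts are conserved exactly across the
  stage and checked in tests.

## Alignment

Optimal local alignment (Smith–Waterman with affine gaps) of each unique
read against each reference, via Biopython's `PairwiseAligner`. Scoring is
the classic nucleotide-BLAST convention: match +1, mismatch −3, and a gap
of length k costs `2 + k·1`. The historical E-value cutoff is replaced by a
raw score threshold (default 20, ≈20 matched bases): reproducing
Karlin–Altschul statistics is out of scope, and the contract is
oracle-equal optimal alignment, verified in the test suite against an
independent brute-force Gotoh dynamic program on random instances. The
`word_size` field is retained for provenance only — no seeding heuristic is
used, so results cannot depend on it. A read is assigned to the uniquely
top-scoring gene; ties go to an AMBIGUOUS bin and score-below-threshold
reads to UNMAPPED, both excluded from per-gene tables but reported in QC.

## 3′-end calling

From the best alignment, terminal aligned columns that mismatch the
reference are peeled into the suffix (clean 3′ boundary; internal
mismatches are tolerated as sequencing error), then the templated end is
greedily extended while read and reference agree — the
**maximal-templated-extent** rule. The remaining read tail is the
non-templated suffix; the signed end offset is measured against the gene
end. Category rules, in order: CCA exactly at the gene end → `PLUS_CCA`;
suffix = optional C/CC/CCA (only at offset 0) followed by ≥1 A →
`OLIGO_A`; CC / C at offset 0; empty suffix → `PROCESSED_EXACT` /
`TRAILER` / `TRIMMED` by offset sign; everything else → `OTHER`. The rules
partition: every assigned read gets exactly one category. Oligo-A stacked
on a (partial) CCA is counted `OLIGO_A` — the surveillance mark dominates —
with the underlying offset and suffix kept per read so reporting can be
revisited. Unrecognized suffixes of any length fall to `OTHER`; recognized
oligo-A runs are deliberately not length-capped, since a long A-tail is
still an oligo-A call.

**Templated/added ambiguity.** When a gene's trailer itself begins with
C/CC/CCA (or A), a read's addition is indistinguishable from trailer
sequence. Templated-first is the default because it never invents an
addition the genome can explain; affected genes carry a per-call
`ambiguous_trailer` flag, and `--added-first` implements the opposite
policy (the deepest re-split of templated trailer bases that still parses
as a recognized addition is taken).

Intron containment (used for the end-processed share filter) requires ≥6
aligned bases inside an annotated intron; genes without introns warn once
and flag False.

## Summaries

* Category percentages per gene: `100·count/total assigned to that gene`
  (one-decimal display; full precision in TSVs).
* End-processed shares: the {–, C, CC, CCA} counts renormalized to 100%.
  Scale-invariant, so the same function serves raw counts and
  already-tabulated percentages (`fig2-from-table`). Oligo-adenylated
  reads are excluded from the denominator: the share is meant to read out
  CCA-nucleotidyltransferase progress among intact matured ends, and
  including the surveillance-marked pool would conflate the two — this
  exclusion is the main source of small discrepancies when comparing
  share arithmetic with percentage tables that list oligo-A separately.
  By default shares are computed over intron-containing reads only
  (matching the targeted design); `--fig2-all-reads` drops that filter.
* Processing efficiency: end-processed / trailer-containing / trimmed /
  oligo-A / other fractions of assigned reads.

## Simulator

The generator inverts the library chemistry: a fragment starts uniformly
inside the intron and ends according to its category; the read is
`adapter + reverse_complement(fragment)`, padded to 100 nt by extending
the fragment 5′ with templated reference sequence (reads anchor at the RNA
3′ end) or truncated keeping the 3′-most portion. Defaults:

| parameter | default | rationale |
|---|---|---|
| reads per library | 50,000 | 10,000/gene gives ≤1% binomial SE on mid-range proportions |
| read length | 100 nt | single-end library design |
| substitution error | 0.001 | typical post-filter Illumina error rate |
| category mixture | TRAILER .35, OLIGO_A .10, PLUS_C .03, PLUS_CC .07, PLUS_CCA .25, PROCESSED_EXACT .05, TRIMMED .15 | trailer-dominant with a substantial CCA ladder, the shape seen in targeted precursor libraries |
| oligo-A length | geometric, mean 3 | short surveillance tails |
| trailer length in reads | uniform 1–20 nt | within the 50-nt annotated trailer |
| trim depth | uniform 1–10 nt | shallow 3′ resection |
| quality model | Q37, 1% of reads Q20 | two-level; exists to exercise the filter |

Fixture genes are five synthetic intron-containing tRNA-like genes
(80–110 nt bodies, one 14–32 nt intron, two genes on the minus strand)
with pairwise-disjoint 8-mer content so best-hit assignment is
unambiguous. Trailers start with `G` so no C/CC/CCA or oligo-A addition at
the gene end can be absorbed by templated extension (an `--ambiguous`
variant with a CCA-leading trailer exists for policy tests). Ground truth
is stated in the classifier's canonical coordinates: draws whose
constructed 3′ split is not canonical (e.g. an A-run abutting a templated
A) are resampled, keeping truth unambiguous. All randomness flows from one
seeded numpy generator consumed in read order, so identical seeds give
byte-identical FASTQ/truth files.

**What the simulator does not model**: PCR duplicates, ligation bias,
reverse-transcription misincorporation at modified nucleotides, indels
(substitution-only by default), off-target transcripts, or real tRNA
sequences. Passing round-trip and proportion-recovery tests therefore
demonstrates the pipeline's internal correctness under the stated error
model, not robustness to every artifact of real libraries — in particular,
modification-induced mismatch clusters near the 3′ end would inflate
`OTHER` on real data.

## Numerical and degenerate-input choices

Empty FASTQ → empty tables with a warning, exit 0. Genes with zero
assigned reads → NA rows. All-zero end-processed ladder → NA shares with a
warning. Alignment ties within one reference resolve to the first optimal
path reported by the aligner; this can only move the boundary between
equivalent splits, which the canonical maximal-templated-extent pass then
normalizes. Percent tables are asserted to sum to 100 ± 0.05 (rounding
only); shares to 100 ± 0.01.

## Problem sizes used in validation

Round-trip: 10,000 noise-free reads over 5 genes (accuracy is exact, so
size only bounds the variety of sampled fragments). Proportion recovery:
20 seeds × 50,000 reads at error 0.001, 700 (gene, category, seed) cells,
≥95% required within 3 binomial SE. Oracle equivalence: 500 random
read/reference instances (reads ≤40 nt, references ≤120 nt). The
acceptance script reports the same statistics at 5 seeds.

## Known limitations

Single best-hit assignment cannot resolve multi-copy gene families with
near-identical 3′ halves (ties are binned AMBIGUOUS rather than
fractionally assigned). The raw-score threshold is not an E-value: for
very short references the false-positive behavior differs from
BLAST's. The end-processed share denominators differ between
tabulated-percentage inputs and recomputed counts whenever the tabulated
values were themselves rounded, so shares recomputed from one-decimal
percentages can differ from count-level shares by a point or two.
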