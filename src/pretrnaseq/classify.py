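"""3'-end calling: templated extent, non-templated suffix, category.

The central object is the signed 3'-end offset of a read relative to the
annotated gene end: 0 means the templated portion of the read stops
exactly at the last gene base (an end-processed precursor), positive
offsets extend into the genomic trailer (unprocessed), negative offsets
stop inside the gene body (trimmed species or fragments).  Read bases 3'
of the templated extent form the non-templated suffix, classified into
the CCA-intermediate ladder (+C, +CC, +CCA), oligo-adenylation, or OTHER.

Two non-obvious rules:

* CCA (full or partial) only counts when it sits exactly at the gene end
  (offset 0) — a "CCA" two bases into the trailer is not a
  nucleotidyltransferase product and falls to OTHER.
* Bases that the genome can explain are templated first
  (maximal-templated-extent).  When a genomic trailer itself begins with
  C/CC/CCA this systematically absorbs would-be additions; such genes are
  flagged so the ambiguity is visible.  ``added_first=True`` flips the
  policy (suffix-candidate bases are peeled before templated extension).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .align import (
    AMBIGUOUS,
    UNMAPPED,
    AlignmentHit,
    AlignmentScoring,
    _cache,
    _extract_hit,
    resolve_assignment,
)
from .preprocess import UniqueRead
from .reference import PrecursorReference

log = logging.getLogger(__name__)


class Category(str, Enum):
    TRAILER = "TRAILER"
    OLIGO_A = "OLIGO_A"
    PLUS_C = "PLUS_C"
    PLUS_CC = "PLUS_CC"
    PLUS_CCA = "PLUS_CCA"
    PROCESSED_EXACT = "PROCESSED_EXACT"
    TRIMMED = "TRIMMED"
    OTHER = "OTHER"

    def __str__(self) -> str:  # plain value in reports
        return self.value


#: categories whose templated 3' end coincides with the gene end
END_PROCESSED = (
    Category.PROCESSED_EXACT,
    Category.PLUS_C,
    Category.PLUS_CC,
    Category.PLUS_CCA,
)


@dataclass
class ThreePrimeCall:
    """Per-unique-read verdict."""

    gene_id: str
    end_offset: int
    non_templated_suffix: str
    intron_containing: bool
    category: Category
    count: int
    seq: str = ""
    ambiguous_trailer: bool = False


def classify_suffix(end_offset: int, suffix: str) -> Category:
    """Map (signed end offset, non-templated suffix) to a category.

    Decision order matters: a full CCA at the gene end wins over the
    oligo-A rule (CCA ends in A but is the mature 3' terminus, not a
    degradation mark); any other suffix ending in >=1 A whose pre-run
    remainder is empty — or is a partial/full CCA sitting exactly at the
    gene end — is oligo-adenylated.
    """
    if set(suffix) - set("ACGT"):
        return Category.OTHER
    if end_offset == 0 and suffix == "CCA":
        return Category.PLUS_CCA
    a_run = len(suffix) - len(suffix.rstrip("A"))
    if a_run >= 1:
        remainder = suffix[: len(suffix) - a_run]
        if remainder == "" or (end_offset == 0 and remainder in ("C", "CC", "CCA")):
            return Category.OLIGO_A
    if end_offset == 0 and suffix == "CC":
        return Category.PLUS_CC
    if end_offset == 0 and suffix == "C":
        return Category.PLUS_C
    if suffix == "":
        if end_offset == 0:
            return Category.PROCESSED_EXACT
        return Category.TRAILER if end_offset > 0 else Category.TRIMMED
    return Category.OTHER


def _aligned_columns(hit: AlignmentHit) -> list[tuple[int, int]]:
    cols = []
    for (t0, t1), (q0, q1) in hit.blocks:
        cols.extend(zip(range(t0, t1), range(q0, q1)))
    return cols


def call_three_prime(
    hit: AlignmentHit,
    read: UniqueRead | str,
    ref: PrecursorReference,
    added_first: bool = False,
) -> tuple[int, str]:
    """Split the read 3' end into templated extent and non-templated suffix.

    Terminal aligned columns that mismatch the reference are peeled back
    into the suffix; the templated end is then greedily extended forward
    while read and reference agree (maximal templated extent; 'N' in the
    reference never matches).  With ``added_first`` the greedy extension
    is skipped for bases that would begin a C/CC/CCA or A-run suffix.
    """
    seq = read.seq if isinstance(read, UniqueRead) else read
    cols = _aligned_columns(hit)
    # peel terminal mismatches/insertions into the suffix
    while cols:
        t, q = cols[-1]
        if ref.seq[t] == seq[q] and ref.seq[t] != "N":
            break
        cols.pop()
    if not cols:
        return (-ref.gene_end, seq)  # nothing templated; caller -> OTHER
    t_last, q_last = cols[-1]
    while (
        q_last + 1 < len(seq)
        and t_last + 1 < len(ref.seq)
        and ref.seq[t_last + 1] == seq[q_last + 1]
        and ref.seq[t_last + 1] != "N"
    ):
        t_last += 1
        q_last += 1
    if added_first:
        # peel templated trailer bases back into the suffix when the
        # deeper split still reads as a recognized 3' addition
        best = (t_last, q_last)
        t, q = t_last, q_last
        for _ in range(6):
            if t < ref.gene_end or q < 0:
                break
            t -= 1
            q -= 1
            cand_offset = (t + 1) - ref.gene_end
            cand_suffix = seq[q + 1 :]
            if classify_suffix(cand_offset, cand_suffix) in (
                Category.PLUS_C,
                Category.PLUS_CC,
                Category.PLUS_CCA,
                Category.OLIGO_A,
            ):
                best = (t, q)
        t_last, q_last = best
    suffix = seq[q_last + 1 :]
    end_offset = (t_last + 1) - ref.gene_end
    return end_offset, suffix


def check_intron(
    hit: AlignmentHit,
    ref: PrecursorReference,
    min_overlap: int = 6,
    _warned: set = set(),
) -> bool:
    """True iff the alignment overlaps an intron by >= min_overlap bases."""
    if not ref.intron_offsets:
        if ref.gene_id not in _warned:
            log.warning("gene %s has no introns; intron flag always False", ref.gene_id)
            _warned.add(ref.gene_id)
        return False
    r0, r1 = hit.ref_interval
    for i0, i1 in ref.intron_offsets:
        if min(r1, i1) - max(r0, i0) >= min_overlap:
            return True
    return False


def trailer_ambiguity_flag(ref: PrecursorReference) -> bool:
    """Genes whose trailer begins with C, CC or CCA absorb additions
    into the templated extent under the templated-first policy."""
    trailer = ref.seq[ref.gene_end :]
    return trailer.startswith("C")


@dataclass
class ClassifyStats:
    n_unique: int = 0
    n_reads: int = 0
    n_assigned: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0


def classify_reads(
    unique_reads: list[UniqueRead],
    refs: list[PrecursorReference],
    scoring: AlignmentScoring | None = None,
    intron_min_overlap: int = 6,
    added_first: bool = False,
) -> tuple[list[ThreePrimeCall], ClassifyStats]:
    """Align, assign, and 3'-classify every unique read.

    Reads with no reference scoring above threshold are counted unmapped;
    score ties across genes are counted ambiguous; both are excluded from
    per-gene tables but tracked in the stats.  Suffixes that do not parse
    into a recognized addition (however long) fall to OTHER.
    """
    scoring = scoring or AlignmentScoring()
    aligner = _cache.get(scoring)
    by_id = {ref.gene_id: ref for ref in refs}
    calls: list[ThreePrimeCall] = []
    stats = ClassifyStats(n_unique=len(unique_reads))
    for u in unique_reads:
        stats.n_reads += u.count
        if not u.seq or set(u.seq) <= {"N"}:
            stats.n_unmapped += u.count
            continue
        scores = {ref.gene_id: int(aligner.score(ref.seq, u.seq)) for ref in refs}
        assignment = resolve_assignment(scores, scoring.min_score)
        if assignment == UNMAPPED:
            stats.n_unmapped += u.count
            continue
        if assignment == AMBIGUOUS:
            stats.n_ambiguous += u.count
            continue
        ref = by_id[assignment]
        hit = _extract_hit(aligner, ref, u.seq, scores[assignment])
        end_offset, suffix = call_three_prime(hit, u, ref, added_first=added_first)
        category = classify_suffix(end_offset, suffix)
        calls.append(
            ThreePrimeCall(
                gene_id=assignment,
                end_offset=end_offset,
                non_templated_suffix=suffix,
                intron_containing=check_intron(hit, ref, intron_min_overlap),
                category=category,
                count=u.count,
                seq=u.seq,
                ambiguous_trailer=trailer_ambiguity_flag(ref),
            )
        )
        stats.n_assigned += u.count
    return calls, stats
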