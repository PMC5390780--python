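"""Normalized summaries of 3'-end calls.

Three views, matching how targeted pre-tRNA libraries are reported:

* per-gene category percentages over *all* reads assigned to the gene
  (the "percentage of all reads aligned to particular tRNA" convention);
* shares among end-processed reads only — the {-, +C, +CC, +CCA} ladder
  renormalized to 100%, which tracks CCA-nucleotidyltransferase progress
  independent of how many precursors still carry trailers;
* a processing-efficiency partition (end-processed vs trailer-containing
  vs trimmed) plus mapping QC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .classify import END_PROCESSED, Category, ThreePrimeCall

log = logging.getLogger(__name__)

#: column order for Table-1-style reports
CATEGORY_ORDER = [
    Category.OLIGO_A,
    Category.PLUS_C,
    Category.PLUS_CC,
    Category.PLUS_CCA,
    Category.PROCESSED_EXACT,
    Category.TRAILER,
    Category.TRIMMED,
    Category.OTHER,
]

#: the four end-processed forms, in ladder order (- , C, CC, CCA)
END_PROCESSED_ORDER = [
    Category.PROCESSED_EXACT,
    Category.PLUS_C,
    Category.PLUS_CC,
    Category.PLUS_CCA,
]

DEFAULT_MAPPING_EXPECTATION = 0.96


@dataclass
class CategoryCounts:
    gene_id: str
    library_id: str
    counts: dict[Category, int] = field(default_factory=dict)

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())


def tabulate(
    calls: list[ThreePrimeCall],
    library_id: str,
    intron_only: bool = False,
) -> list[CategoryCounts]:
    """Aggregate calls per gene, weighted by collapsed-read multiplicity.

    ``intron_only`` restricts to reads flagged intron-containing (the
    filter used for end-processed-share reporting on targeted libraries).
    """
    by_gene: dict[str, CategoryCounts] = {}
    for call in calls:
        if intron_only and not call.intron_containing:
            continue
        cc = by_gene.setdefault(
            call.gene_id, CategoryCounts(call.gene_id, library_id)
        )
        cc.counts[call.category] = cc.counts.get(call.category, 0) + call.count
    return [by_gene[g] for g in sorted(by_gene)]


def table1_percentages(cc: CategoryCounts) -> dict[Category, float]:
    """Category percentages of all reads assigned to the gene."""
    total = cc.total_assigned
    if total == 0:
        return {cat: math.nan for cat in CATEGORY_ORDER}
    return {
        cat: 100.0 * cc.counts.get(cat, 0) / total for cat in CATEGORY_ORDER
    }


def end_processed_shares(
    values: dict[Category, float] | CategoryCounts,
) -> dict[Category, float]:
    """Shares of the {-, C, CC, CCA} ladder among end-processed reads.

    Accepts raw counts or already-normalized percentages; the result is
    identical (scale invariance), since only the ratio of the four
    end-processed bins matters.  Oligo-adenylated reads are excluded from
    the denominator.
    """
    if isinstance(values, CategoryCounts):
        values = {cat: float(values.counts.get(cat, 0)) for cat in END_PROCESSED_ORDER}
    four = {cat: float(values.get(cat, 0.0)) for cat in END_PROCESSED_ORDER}
    denom = sum(four.values())
    if denom <= 0:
        log.warning("end_processed_shares: no end-processed reads")
        return {cat: math.nan for cat in END_PROCESSED_ORDER}
    return {cat: 100.0 * v / denom for cat, v in four.items()}


def processing_efficiency(cc: CategoryCounts) -> dict[str, float]:
    """Fractions of end-processed / trailer / trimmed / oligo-A / other."""
    total = cc.total_assigned
    if total == 0:
        return {k: math.nan for k in ("end_processed", "trailer_containing", "trimmed", "oligoA", "other")}
    end_proc = sum(cc.counts.get(cat, 0) for cat in END_PROCESSED)
    return {
        "end_processed": end_proc / total,
        "trailer_containing": cc.counts.get(Category.TRAILER, 0) / total,
        "trimmed": cc.counts.get(Category.TRIMMED, 0) / total,
        "oligoA": cc.counts.get(Category.OLIGO_A, 0) / total,
        "other": cc.counts.get(Category.OTHER, 0) / total,
    }


@dataclass
class MappingQC:
    n_processed: int
    n_assigned: int
    n_ambiguous: int
    assigned_fraction: float
    expectation: float
    below_expectation: bool


def mapping_qc(
    n_processed: int,
    n_assigned: int,
    n_ambiguous: int,
    expectation: float = DEFAULT_MAPPING_EXPECTATION,
) -> MappingQC:
    """Report the fraction of preprocessed reads assigned to a gene.

    Warns (never fails) below the expectation — targeted libraries are
    expected to map almost completely (>=96% of processed reads).
    """
    if n_processed < n_assigned + n_ambiguous:
        raise ValueError("assigned + ambiguous exceeds processed reads")
    frac = n_assigned / n_processed if n_processed else math.nan
    below = bool(n_processed) and frac < expectation
    if below:
        log.warning(
            "mapping rate %.3f below the %.0f%% expectation for targeted "
            "pre-tRNA libraries", frac, 100 * expectation,
        )
    return MappingQC(n_processed, n_assigned, n_ambiguous, frac, expectation, below)


# ---------------------------------------------------------------------------
# DataFrame report builders


def table1_frame(counts: list[CategoryCounts]) -> pd.DataFrame:
    rows = []
    for cc in counts:
        pct = table1_percentages(cc)
        row = {"library_id": cc.library_id, "gene_id": cc.gene_id,
               "total": cc.total_assigned}
        row.update({cat.value: pct[cat] for cat in CATEGORY_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)


def fig2_frame(counts: list[CategoryCounts]) -> pd.DataFrame:
    rows = []
    for cc in counts:
        shares = end_processed_shares(cc)
        row = {"library_id": cc.library_id, "gene_id": cc.gene_id}
        row.update({cat.value: shares[cat] for cat in END_PROCESSED_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)


def efficiency_frame(counts: list[CategoryCounts]) -> pd.DataFrame:
    rows = []
    for cc in counts:
        row = {"library_id": cc.library_id, "gene_id": cc.gene_id,
               "total": cc.total_assigned}
        row.update(processing_efficiency(cc))
        rows.append(row)
    return pd.DataFrame(rows)
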