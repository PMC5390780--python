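"""Compare pipeline calls against simulator ground truth.

Raw read identifiers do not survive collapsing, so evaluation maps each
surviving raw read onto its collapsed sense sequence (replaying the
deterministic trim + reverse-complement) and looks the call up by
sequence.  Quality-discarded reads are excluded from the denominator:
the simulator marks whole reads low-quality at random, independent of
category, so the exclusion is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import Category, ThreePrimeCall
from .pipeline import RunConfig
from .preprocess import RawRead, trim_adapter
from .reference import reverse_complement
from .simulate import TruthRecord


@dataclass
class TruthComparison:
    n_evaluated: int
    n_gene_correct: int
    n_category_correct: int
    n_both_correct: int
    #: per (gene, category) truth and called counts, for proportion checks
    truth_counts: dict[tuple[str, Category], int]
    called_counts: dict[tuple[str, Category], int]

    @property
    def category_accuracy(self) -> float:
        return self.n_category_correct / self.n_evaluated if self.n_evaluated else float("nan")

    @property
    def both_accuracy(self) -> float:
        return self.n_both_correct / self.n_evaluated if self.n_evaluated else float("nan")


def compare_to_truth(
    reads: list[RawRead],
    truths: list[TruthRecord],
    calls: list[ThreePrimeCall],
    config: RunConfig | None = None,
) -> TruthComparison:
    """Per-read truth-vs-call comparison for a simulated library."""
    config = config or RunConfig()
    by_seq = {c.seq: c for c in calls}
    n_eval = n_gene = n_cat = n_both = 0
    truth_counts: dict[tuple[str, Category], int] = {}
    called_counts: dict[tuple[str, Category], int] = {}
    for read, truth in zip(reads, truths):
        if read.quals and sum(read.quals) / len(read.quals) < config.q_threshold:
            continue
        trimmed, verdict = trim_adapter(
            read, config.adapter, config.min_overlap,
            config.max_mismatch_frac, config.min_length,
        )
        if verdict == "too_short":
            continue
        seq = reverse_complement(trimmed.seq)
        call = by_seq.get(seq)
        if call is None:
            n_eval += 1  # unmapped/ambiguous: evaluated, wrong
            truth_counts[(truth.gene_id, truth.true_category)] = (
                truth_counts.get((truth.gene_id, truth.true_category), 0) + 1
            )
            continue
        n_eval += 1
        truth_counts[(truth.gene_id, truth.true_category)] = (
            truth_counts.get((truth.gene_id, truth.true_category), 0) + 1
        )
        called_counts[(call.gene_id, call.category)] = (
            called_counts.get((call.gene_id, call.category), 0) + 1
        )
        gene_ok = call.gene_id == truth.gene_id
        cat_ok = call.category is truth.true_category
        n_gene += gene_ok
        n_cat += cat_ok
        n_both += gene_ok and cat_ok
    return TruthComparison(
        n_evaluated=n_eval,
        n_gene_correct=n_gene,
        n_category_correct=n_cat,
        n_both_correct=n_both,
        truth_counts=truth_counts,
        called_counts=called_counts,
    )
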