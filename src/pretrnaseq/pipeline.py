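"""End-to-end pipeline: FASTQ -> preprocessing -> calls -> summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import AlignmentScoring
from .classify import ClassifyStats, ThreePrimeCall, classify_reads
from .preprocess import (
    DEFAULT_ADAPTER,
    DEFAULT_MAX_MISMATCH_FRAC,
    DEFAULT_MIN_LENGTH,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_Q_THRESHOLD,
    PreprocessStats,
    RawRead,
    preprocess_fastq,
    preprocess_reads,
)
from .reference import build_precursor_reference, load_gene_models
from .summarize import (
    DEFAULT_MAPPING_EXPECTATION,
    MappingQC,
    efficiency_frame,
    fig2_frame,
    mapping_qc,
    table1_frame,
    tabulate,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables in one place (YAML-compatible flat keys)."""

    adapter: str = DEFAULT_ADAPTER
    q_threshold: int = DEFAULT_Q_THRESHOLD
    quality_mode: str = "mean"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC
    min_length: int = DEFAULT_MIN_LENGTH
    leader_len: int = 30
    trailer_len: int = 50
    match: int = 1
    mismatch: int = -3
    gap_open: int = 2
    gap_extend: int = 1
    min_score: int = 20
    intron_min_overlap: int = 6
    added_first: bool = False
    fig2_intron_only: bool = True
    mapping_expectation: float = DEFAULT_MAPPING_EXPECTATION

    def scoring(self) -> AlignmentScoring:
        return AlignmentScoring(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            min_score=self.min_score,
        )


@dataclass
class PipelineResult:
    library_id: str
    calls: list[ThreePrimeCall]
    preprocess_stats: PreprocessStats
    classify_stats: ClassifyStats
    qc: MappingQC
    table1: pd.DataFrame = field(default_factory=pd.DataFrame)
    fig2: pd.DataFrame = field(default_factory=pd.DataFrame)
    efficiency: pd.DataFrame = field(default_factory=pd.DataFrame)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seq": c.seq,
                    "count": c.count,
                    "gene_id": c.gene_id,
                    "end_offset": c.end_offset,
                    "suffix": c.non_templated_suffix,
                    "intron_containing": c.intron_containing,
                    "category": c.category.value,
                    "ambiguous_trailer": c.ambiguous_trailer,
                }
                for c in self.calls
            ]
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.calls_frame().to_csv(out_dir / "calls.tsv", sep="\t", index=False)
        self.table1.to_csv(out_dir / "table1.tsv", sep="\t", index=False, float_format="%.6f")
        self.fig2.to_csv(out_dir / "fig2_shares.tsv", sep="\t", index=False, float_format="%.6f")
        self.efficiency.to_csv(
            out_dir / "processing_efficiency.tsv", sep="\t", index=False, float_format="%.6f"
        )
        qc = pd.DataFrame(
            [
                {
                    "library_id": self.library_id,
                    "n_input": self.preprocess_stats.n_input,
                    "n_quality_discarded": self.preprocess_stats.n_quality_discarded,
                    "n_length_discarded": self.preprocess_stats.n_length_discarded,
                    "n_processed": self.classify_stats.n_reads,
                    "n_assigned": self.classify_stats.n_assigned,
                    "n_unmapped": self.classify_stats.n_unmapped,
                    "n_ambiguous": self.classify_stats.n_ambiguous,
                    "assigned_fraction": self.qc.assigned_fraction,
                    "below_expectation": self.qc.below_expectation,
                }
            ]
        )
        qc.to_csv(out_dir / "qc.tsv", sep="\t", index=False, float_format="%.6f")


def run_reads(
    reads: list[RawRead],
    models,
    config: RunConfig | None = None,
    library_id: str = "library",
) -> PipelineResult:
    """Run the pipeline on in-memory reads (the simulate -> run path)."""
    config = config or RunConfig()
    unique, pstats = preprocess_reads(
        reads,
        adapter=config.adapter,
        q_threshold=config.q_threshold,
        quality_mode=config.quality_mode,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        min_length=config.min_length,
    )
    return _classify_and_summarize(unique, pstats, models, config, library_id)


def run_fastq(
    fastq: str | Path,
    genome: str | Path,
    annotation: str | Path,
    config: RunConfig | None = None,
    library_id: str = "library",
) -> PipelineResult:
    config = config or RunConfig()
    models = load_gene_models(genome, annotation, config.leader_len, config.trailer_len)
    unique, pstats = preprocess_fastq(
        fastq,
        adapter=config.adapter,
        q_threshold=config.q_threshold,
        quality_mode=config.quality_mode,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        min_length=config.min_length,
    )
    return _classify_and_summarize(unique, pstats, models, config, library_id)


def _classify_and_summarize(unique, pstats, models, config, library_id):
    refs = [build_precursor_reference(m) for m in models]
    calls, cstats = classify_reads(
        unique,
        refs,
        scoring=config.scoring(),
        intron_min_overlap=config.intron_min_overlap,
        added_first=config.added_first,
    )
    counts_all = tabulate(calls, library_id)
    counts_fig2 = tabulate(calls, library_id, intron_only=config.fig2_intron_only)
    qc = mapping_qc(
        cstats.n_reads, cstats.n_assigned, cstats.n_ambiguous,
        expectation=config.mapping_expectation,
    )
    log.info(
        "%s: %d reads in, %d assigned (%.1f%%), %d unmapped, %d ambiguous",
        library_id, cstats.n_reads, cstats.n_assigned,
        100 * (qc.assigned_fraction or 0), cstats.n_unmapped, cstats.n_ambiguous,
    )
    return PipelineResult(
        library_id=library_id,
        calls=calls,
        preprocess_stats=pstats,
        classify_stats=cstats,
        qc=qc,
        table1=table1_frame(counts_all),
        fig2=fig2_frame(counts_fig2),
        efficiency=efficiency_frame(counts_all),
    )
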