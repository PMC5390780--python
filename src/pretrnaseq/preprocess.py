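"""Raw-read preprocessing: quality filter, 5' adapter removal, collapse.

The targeted library design puts the sequencing adapter at the read 5' end:
the RNA fragment receives a 3' adapter, is reverse-transcribed and
sequenced so that each read begins with the reverse complement of that
adapter followed by the reverse complement of the fragment.  Preprocessing
therefore (1) drops low-quality reads, (2) strips the adapter prefix,
(3) reverse-complements into RNA sense orientation, and (4) collapses
identical sequences into unique reads with multiplicities.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .reference import reverse_complement

log = logging.getLogger(__name__)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGC"
DEFAULT_MIN_LENGTH = 15
DEFAULT_MIN_OVERLAP = 4
DEFAULT_MAX_MISMATCH_FRAC = 0.1
DEFAULT_Q_THRESHOLD = 30


@dataclass
class RawRead:
    read_id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"{self.read_id}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed, adapter-free, sense-oriented sequence with multiplicity."""

    seq: str
    count: int


@dataclass
class PreprocessStats:
    """Read accounting across the preprocessing stages.

    Conservation invariant: n_input == n_quality_discarded
    + n_length_discarded + sum of UniqueRead counts.
    """

    n_input: int = 0
    n_quality_discarded: int = 0
    n_length_discarded: int = 0
    n_adapter_trimmed: int = 0
    n_no_adapter: int = 0
    n_unique: int = 0
    n_collapsed: int = 0
    mode: str = "mean"
    extra: dict = field(default_factory=dict)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a (possibly gzipped) Sanger/Illumina-1.8+ FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield RawRead(
                read_id=entry.name,
                seq=entry.sequence.upper(),
                quals=list(entry.get_quality_array()),
            )


def quality_filter(
    reads: Iterable[RawRead],
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    mode: str = "mean",
    stats: PreprocessStats | None = None,
) -> Iterator[RawRead]:
    """Retain reads whose mean (or minimum) Phred score is >= q_threshold.

    The threshold is inclusive.  ``mode`` is "mean" (read-level average,
    the default) or "min" (every base must reach the threshold).
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown quality filter mode {mode!r}")
    n_discard = 0
    for read in reads:
        if not read.quals:
            n_discard += 1
            continue
        if mode == "mean":
            ok = sum(read.quals) / len(read.quals) >= q_threshold
        else:
            ok = min(read.quals) >= q_threshold
        if ok:
            yield read
        else:
            n_discard += 1
    if stats is not None:
        stats.n_quality_discarded += n_discard
    log.info("quality_filter: discarded %d reads below Q%d (%s)", n_discard, q_threshold, mode)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def trim_adapter(
    read: RawRead,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[RawRead | None, str]:
    """Remove the adapter from the read 5' end.

    Tries the full adapter as the read prefix first, then progressively
    shorter adapter *suffixes* down to ``min_overlap`` bases (a fragment
    longer than the read pushes part of the adapter off the 5' end is not
    possible here, but a short leading adapter remnant is).  Up to
    floor(max_mismatch_frac * overlap) mismatches are tolerated.

    Returns ``(trimmed_read, verdict)`` with verdict one of ``"trimmed"``,
    ``"untrimmed"`` (no adapter found; read passed through unmodified) or
    ``"too_short"`` (trimmed read below ``min_length``; dropped, read is
    None).
    """
    if not adapter or set(adapter) - set("ACGT"):
        raise ValueError("adapter must be non-empty uppercase ACGT")
    alen = len(adapter)
    for ov in range(min(alen, len(read.seq)), min_overlap - 1, -1):
        tail = adapter[alen - ov:]
        allowed = int(max_mismatch_frac * ov)
        if _count_mismatches(read.seq[:ov], tail, allowed) <= allowed:
            if len(read.seq) - ov < min_length:
                return None, "too_short"
            return (
                RawRead(read.read_id, read.seq[ov:], read.quals[ov:]),
                "trimmed",
            )
    return read, "untrimmed"


def collapse_reads(seqs: Iterable[str]) -> list[UniqueRead]:
    """Collapse identical sequences; descending count, then lexicographic."""
    counts = Counter(seqs)
    return [
        UniqueRead(seq=s, count=c)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def preprocess_reads(
    reads: Iterable[RawRead],
    adapter: str = DEFAULT_ADAPTER,
    q_threshold: int = DEFAULT_Q_THRESHOLD,
    quality_mode: str = "mean",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[list[UniqueRead], PreprocessStats]:
    """Full preprocessing chain: filter, trim, orient, collapse."""
    stats = PreprocessStats(mode=quality_mode)
    sense_seqs: list[str] = []
    n_input = 0

    def _counted(rs: Iterable[RawRead]) -> Iterator[RawRead]:
        nonlocal n_input
        for r in rs:
            n_input += 1
            yield r

    for read in quality_filter(_counted(reads), q_threshold, quality_mode, stats):
        trimmed, verdict = trim_adapter(
            read, adapter, min_overlap, max_mismatch_frac, min_length
        )
        if verdict == "too_short":
            stats.n_length_discarded += 1
            continue
        if verdict == "trimmed":
            stats.n_adapter_trimmed += 1
        else:
            stats.n_no_adapter += 1
        sense_seqs.append(reverse_complement(trimmed.seq))

    unique = collapse_reads(sense_seqs)
    stats.n_input = n_input
    stats.n_unique = len(unique)
    stats.n_collapsed = sum(u.count for u in unique)
    return unique, stats


def preprocess_fastq(path: str | Path, **kwargs) -> tuple[list[UniqueRead], PreprocessStats]:
    return preprocess_reads(read_fastq(path), **kwargs)


def write_collapsed_fasta(unique: list[UniqueRead], path: str | Path) -> None:
    """Dump collapsed reads as FASTA with 'read<i>_x<count>' headers."""
    with open(path, "w") as fh:
        for i, u in enumerate(unique, 1):
            fh.write(f">read{i}_x{u.count}\n{u.seq}\n")
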