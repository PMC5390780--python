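"""Local alignment of sense reads against precursor references.

Scoring follows the classic nucleotide-BLAST convention: match +1,
mismatch -3, affine gaps where a gap of length k costs ``gap_open +
k * gap_extend`` (defaults 2 and 1, so a single-base gap costs 3).  The
E-value cutoff of the original BLAST workflow is replaced by a raw-score
threshold; the contract here is optimal local alignment under these
scores, which Bio.Align.PairwiseAligner computes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .preprocess import UniqueRead
from .reference import PrecursorReference


@dataclass
class AlignmentScoring:
    """blastn-style scoring constants.

    ``word_size`` is retained for provenance/reporting; the aligner is a
    full dynamic program so seeding never changes results.  ``min_score``
    stands in for an E-value cutoff (default 20 ~ 20 matched bases).
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = 2
    gap_extend: int = 1
    word_size: int = 8
    min_score: int = 20

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive, mismatch negative")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        # first gap base costs open+extend, each further base costs extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class AlignmentHit:
    """Best local alignment of a read against one reference."""

    gene_id: str
    read_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    score: int
    n_mismatch: int
    n_gap: int
    #: aligned blocks as ((ref_start, ref_end), (read_start, read_end)) pairs
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)


AMBIGUOUS = "AMBIGUOUS"
UNMAPPED = "UNMAPPED"


class _AlignerCache:
    """One PairwiseAligner per scoring; avoids rebuilding in hot loops."""

    def __init__(self) -> None:
        self._key: tuple | None = None
        self._aligner: Align.PairwiseAligner | None = None

    def get(self, scoring: AlignmentScoring) -> Align.PairwiseAligner:
        key = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
        if key != self._key:
            self._aligner = scoring.make_aligner()
            self._key = key
        return self._aligner


_cache = _AlignerCache()


def _extract_hit(
    aligner: Align.PairwiseAligner,
    ref: PrecursorReference,
    seq: str,
    score: int,
) -> AlignmentHit:
    aln = aligner.align(ref.seq, seq)[0]
    ref_blocks, read_blocks = aln.aligned
    blocks = [
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(ref_blocks, read_blocks)
    ]
    n_mismatch = 0
    for (t0, t1), (q0, q1) in blocks:
        n_mismatch += sum(
            1 for a, b in zip(ref.seq[t0:t1], seq[q0:q1]) if a != b
        )
    n_gap = 0
    for i in range(1, len(blocks)):
        (t0, _), (q0, _) = blocks[i]
        (_, t1p), (_, q1p) = blocks[i - 1]
        n_gap += (t0 - t1p) + (q0 - q1p)
    return AlignmentHit(
        gene_id=ref.gene_id,
        read_interval=(blocks[0][1][0], blocks[-1][1][1]),
        ref_interval=(blocks[0][0][0], blocks[-1][0][1]),
        score=int(score),
        n_mismatch=n_mismatch,
        n_gap=n_gap,
        blocks=blocks,
    )


def score_against_refs(
    seq: str,
    refs: list[PrecursorReference],
    scoring: AlignmentScoring,
) -> dict[str, int]:
    """Optimal local-alignment score of ``seq`` against every reference."""
    aligner = _cache.get(scoring)
    return {ref.gene_id: int(aligner.score(ref.seq, seq)) for ref in refs}


def align_read(
    read: UniqueRead | str,
    refs: list[PrecursorReference],
    scoring: AlignmentScoring | None = None,
) -> AlignmentHit | None:
    """Best hit of the read across references, or None if unmapped.

    Ties across genes are broken by reference order here; use
    :func:`resolve_assignment` when tie detection matters.
    """
    scoring = scoring or AlignmentScoring()
    seq = read.seq if isinstance(read, UniqueRead) else read
    if not refs:
        raise ValueError("refs must be non-empty")
    if not seq or set(seq) <= {"N"}:
        return None
    aligner = _cache.get(scoring)
    best_ref: PrecursorReference | None = None
    best_score = scoring.min_score - 1
    for ref in refs:
        s = int(aligner.score(ref.seq, seq))
        if s > best_score:
            best_score, best_ref = s, ref
    if best_ref is None:
        return None
    return _extract_hit(aligner, best_ref, seq, best_score)


def resolve_assignment(scores: dict[str, int], min_score: int) -> str:
    """Pick the uniquely top-scoring gene, else AMBIGUOUS/UNMAPPED."""
    passing = {g: s for g, s in scores.items() if s >= min_score}
    if not passing:
        return UNMAPPED
    top = max(passing.values())
    winners = [g for g, s in passing.items() if s == top]
    return winners[0] if len(winners) == 1 else AMBIGUOUS
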