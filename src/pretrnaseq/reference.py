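"""tRNA gene models and precursor reference sequences.

A nuclear tRNA gene is transcribed with a 5' leader and a 3' trailer, and
(for roughly a fifth of yeast genes) retains an intron in the precursor.
The CCA amino-acid attachment site is NOT genomically encoded; it is added
post-transcriptionally by the CCA-nucleotidyltransferase.  Everything in
this module is therefore purely genomic: a gene body (introns included),
plus flanking leader/trailer sequence against which read 3' ends are
interpreted.

Coordinates are 0-based half-open throughout.  All models are stored in
sense orientation: minus-strand genes are reverse-complemented on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: genomic flank defaults: 50 nt of trailer places any 100-nt read 3' end,
#: given precursor trailers of a few to ~30 nt in vivo.
DEFAULT_LEADER_LEN = 30
DEFAULT_TRAILER_LEN = 50

_ISOTYPE_RE = re.compile(r"^t([A-Za-z])\(([ACGTU]{3})\)")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the {A,C,G,T,N} alphabet."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGTN character(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation."""


@dataclass
class TRNAGeneModel:
    """One tRNA gene, sense-oriented, with genomic flanks.

    ``intron_intervals`` are gene-relative (0-based half-open, relative to
    the sense gene start), sorted and disjoint.  ``leader_flank`` /
    ``trailer_flank`` are the genomic sequences immediately 5' / 3' of the
    gene in sense orientation; the trailer is what a 3'-unprocessed
    precursor read continues into.
    """

    gene_id: str
    isotype: str
    chrom: str
    strand: str
    gene_interval: tuple[int, int]
    intron_intervals: list[tuple[int, int]]
    gene_seq: str
    leader_flank: str
    trailer_flank: str

    def __post_init__(self) -> None:
        start, end = self.gene_interval
        if start >= end:
            raise AnnotationError(
                f"{self.gene_id}: malformed gene interval [{start}, {end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if len(self.gene_seq) != end - start:
            raise AnnotationError(
                f"{self.gene_id}: gene_seq length {len(self.gene_seq)} != "
                f"interval length {end - start}"
            )
        for s in (self.gene_seq, self.leader_flank, self.trailer_flank):
            bad = set(s) - _VALID
            if bad:
                raise AnnotationError(
                    f"{self.gene_id}: invalid base(s) {sorted(bad)}"
                )
        prev_end = 0
        for i0, i1 in self.intron_intervals:
            if not (0 < i0 < i1 < len(self.gene_seq)):
                raise AnnotationError(
                    f"{self.gene_id}: intron [{i0}, {i1}) outside gene body "
                    f"of length {len(self.gene_seq)}"
                )
            if i0 < prev_end:
                raise AnnotationError(
                    f"{self.gene_id}: intron intervals overlap or unsorted"
                )
            prev_end = i1


@dataclass
class PrecursorReference:
    """Leader + gene body (introns retained) + trailer, sense orientation.

    ``gene_end`` is the coordinate every signed 3'-end offset is measured
    against: a read whose last templated base sits at ``gene_end - 1`` has
    offset 0 (exactly end-processed).
    """

    gene_id: str
    seq: str
    gene_start: int
    gene_end: int
    intron_offsets: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.gene_start < self.gene_end <= len(self.seq):
            raise AnnotationError(
                f"{self.gene_id}: gene span [{self.gene_start}, "
                f"{self.gene_end}) outside reference of length {len(self.seq)}"
            )


def isotype_from_gene_id(gene_id: str) -> str:
    """Parse 'tL(CAA)A'-style names into an 'L-CAA' isotype; 'NA' otherwise."""
    m = _ISOTYPE_RE.match(gene_id)
    if not m:
        return "NA"
    return f"{m.group(1).upper()}-{m.group(2).replace('U', 'T')}"


def _parse_introns(text: str) -> list[tuple[int, int]]:
    if text in (".", ""):
        return []
    out = []
    for chunk in text.split(","):
        try:
            a, b = chunk.split("-")
            out.append((int(a), int(b)))
        except ValueError as exc:
            raise AnnotationError(f"bad intron interval {chunk!r}") from exc
    return out


def load_gene_models(
    genome: str | Path,
    annotation: str | Path,
    leader_len: int = DEFAULT_LEADER_LEN,
    trailer_len: int = DEFAULT_TRAILER_LEN,
) -> list[TRNAGeneModel]:
    """Load gene models from a genome FASTA plus a BED-like annotation.

    The annotation is tab-separated BED6 (chrom, start, end, name, score,
    strand) with a seventh column of gene-relative intron intervals as
    comma-separated ``start-end`` pairs ('.' for none).  Intron intervals
    are sense-relative regardless of strand.  Flanks are clipped at
    chromosome ends.
    """
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}
    models: list[TRNAGeneModel] = []
    with open(annotation) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{annotation} line {lineno}: expected >=6 columns"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            introns = _parse_introns(fields[6]) if len(fields) > 6 else []
            if chrom not in chroms:
                raise AnnotationError(
                    f"{annotation} line {lineno} ({name}): chromosome "
                    f"{chrom!r} not in genome FASTA"
                )
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise AnnotationError(
                    f"{annotation} line {lineno} ({name}): start >= end"
                )
            cseq = chroms[chrom]
            if end > len(cseq):
                raise AnnotationError(
                    f"{annotation} line {lineno} ({name}): interval beyond "
                    f"chromosome end"
                )
            body = cseq[start:end]
            if strand == "+":
                leader = cseq[max(0, start - leader_len):start]
                trailer = cseq[end:end + trailer_len]
            else:
                body = reverse_complement(body)
                # sense 5' flank lies genomically downstream of a minus gene
                leader = reverse_complement(cseq[end:end + leader_len])
                trailer = reverse_complement(cseq[max(0, start - trailer_len):start])
            models.append(
                TRNAGeneModel(
                    gene_id=name,
                    isotype=isotype_from_gene_id(name),
                    chrom=chrom,
                    strand=strand,
                    gene_interval=(start, end),
                    intron_intervals=introns,
                    gene_seq=body,
                    leader_flank=leader,
                    trailer_flank=trailer,
                )
            )
    return models


def write_annotation(models: list[TRNAGeneModel], path: str | Path) -> None:
    """Write models back to the BED-like annotation dialect of this package."""
    with open(path, "w") as fh:
        for m in models:
            introns = ",".join(f"{a}-{b}" for a, b in m.intron_intervals) or "."
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(m.gene_interval[0]),
                        str(m.gene_interval[1]),
                        m.gene_id,
                        "0",
                        m.strand,
                        introns,
                    ]
                )
                + "\n"
            )


def build_precursor_reference(model: TRNAGeneModel) -> PrecursorReference:
    """Concatenate leader + gene body + trailer into one sense reference."""
    gene_start = len(model.leader_flank)
    gene_end = gene_start + len(model.gene_seq)
    seq = model.leader_flank + model.gene_seq + model.trailer_flank
    return PrecursorReference(
        gene_id=model.gene_id,
        seq=seq,
        gene_start=gene_start,
        gene_end=gene_end,
        intron_offsets=[(a + gene_start, b + gene_start) for a, b in model.intron_intervals],
    )
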