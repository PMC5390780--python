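"""Synthetic targeted pre-tRNA libraries with known ground truth.

The generator is the inverse of the library chemistry this pipeline is
built for: an RNA fragment starting inside the intron of an
intron-containing precursor and ending at its (possibly modified) 3'
terminus is ligated to a 3' adapter and reverse-transcribed, so the
sequenced read is ``adapter + reverse_complement(fragment)`` — reads
anchor at the RNA 3' end.  Every read carries a truth record (gene,
category, signed end offset, non-templated suffix) so the whole pipeline
is testable without any deposited data.

Ground truth is stated in the same canonical coordinates the classifier
uses (maximal templated extent): a sampled fragment whose constructed
3' split is not canonical — e.g. an oligo-A run abutting a templated A —
is resampled, keeping truth unambiguous.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import Category, classify_suffix
from .preprocess import DEFAULT_ADAPTER, RawRead
from .reference import (
    PrecursorReference,
    TRNAGeneModel,
    build_precursor_reference,
    load_gene_models,
    reverse_complement,
    write_annotation,
)

FIXTURE_GENE_IDS = ["tI(UAU)S", "tF(GAA)S", "tK(UUU)S", "tL(CAA)S", "tW(CCA)S"]

#: default ground-truth category mixture: trailer-dominant with a
#: substantial CCA ladder, loosely shaped after targeted pre-tRNA
#: libraries (see docs/methods.md)
DEFAULT_CATEGORY_MIXTURE: dict[Category, float] = {
    Category.TRAILER: 0.35,
    Category.OLIGO_A: 0.10,
    Category.PLUS_C: 0.03,
    Category.PLUS_CC: 0.07,
    Category.PLUS_CCA: 0.25,
    Category.PROCESSED_EXACT: 0.05,
    Category.TRIMMED: 0.15,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Ground-truth mixture and noise model for one simulated library."""

    n_reads: int = 50_000
    gene_mixture: dict[str, float] | None = None  # None -> uniform
    category_mixture: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIXTURE)
    )
    read_length: int = 100
    substitution_error: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    oligoa_mean: float = 3.0  # geometric, support >= 1
    trailer_max: int = 20  # uniform [1, min(trailer_max, T)]
    trim_max: int = 10  # uniform [1, trim_max]
    q_high: int = 37
    q_low: int = 20
    low_q_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        tot = sum(self.category_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"category_mixture sums to {tot}, expected 1")
        if self.gene_mixture is not None:
            tot = sum(self.gene_mixture.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"gene_mixture sums to {tot}, expected 1")
        if not 0.0 <= self.substitution_error <= 1.0:
            raise ValueError("substitution_error must be in [0, 1]")


@dataclass
class TruthRecord:
    read_id: str
    gene_id: str
    true_category: Category
    true_end_offset: int
    true_suffix: str


@dataclass
class FixtureGenome:
    """A synthetic single-chromosome genome with five tRNA-like genes."""

    chrom_name: str
    chrom_seq: str
    rows: list[tuple]  # (chrom, start, end, gene_id, strand, introns)

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
        bed = out_dir / "genes.bed"
        with open(fasta, "w") as fh:
            fh.write(f">{self.chrom_name}\n")
            for i in range(0, len(self.chrom_seq), 70):
                fh.write(self.chrom_seq[i : i + 70] + "\n")
        with open(bed, "w") as fh:
            for chrom, start, end, gene_id, strand, introns in self.rows:
                intron_s = ",".join(f"{a}-{b}" for a, b in introns) or "."
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t{strand}\t{intron_s}\n"
                )
        return fasta, bed

    def gene_models(
        self, leader_len: int = 30, trailer_len: int = 50
    ) -> list[TRNAGeneModel]:
        with tempfile.TemporaryDirectory() as td:
            fasta, bed = self.write(td)
            return load_gene_models(fasta, bed, leader_len, trailer_len)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def make_fixture_genes(seed: int, ambiguous: bool = False) -> FixtureGenome:
    """Five synthetic intron-containing tRNA-like genes on one chromosome.

    Gene bodies are 80-110 nt with a single 14-32 nt intron and pairwise
    disjoint 8-mer content (unambiguous best-hit assignment).  Trailer
    flanks start with 'G', so no non-templated C/CC/CCA or oligo-A at the
    gene end can be absorbed by templated extension; with ``ambiguous``
    the first gene's trailer instead begins with "CCA" for
    ambiguity-policy tests.  Two genes are placed on the minus strand.
    """
    rng = np.random.default_rng(seed)
    seen_kmers: set[str] = set()
    chrom_parts: list[str] = []
    rows: list[tuple] = []
    pos = 0
    spacer = _random_seq(rng, 25)
    chrom_parts.append(spacer)
    pos += len(spacer)
    for idx, gene_id in enumerate(FIXTURE_GENE_IDS):
        for _attempt in range(100):
            glen = int(rng.integers(80, 111))
            body = _random_seq(rng, glen)
            if not (_kmers(body) & seen_kmers):
                break
        else:
            raise SimulationError("could not build 8-mer-distinct gene bodies")
        seen_kmers |= _kmers(body)
        ilen = int(rng.integers(14, 33))
        istart = int(rng.integers(30, glen - ilen - 12 + 1))
        introns = [(istart, istart + ilen)]
        upstream = _random_seq(rng, 40)
        trailer_head = "CCA" if (ambiguous and idx == 0) else "G"
        downstream = trailer_head + _random_seq(rng, 60 - len(trailer_head))
        cassette = upstream + body + downstream
        strand = "-" if idx in (1, 3) else "+"
        if strand == "+":
            gstart = pos + len(upstream)
            gend = gstart + glen
            chrom_parts.append(cassette)
        else:
            gstart = pos + len(downstream)
            gend = gstart + glen
            chrom_parts.append(reverse_complement(cassette))
        rows.append(("chrSim", gstart, gend, gene_id, strand, introns))
        pos += len(cassette)
        gap = _random_seq(rng, 20)
        chrom_parts.append(gap)
        pos += len(gap)
    return FixtureGenome("chrSim", "".join(chrom_parts), rows)


@dataclass
class SimFragment:
    """A sense RNA fragment: templated ref[a:b] plus a non-templated tail."""

    ref_start: int  # a
    templated_end: int  # b (canonical: maximal templated extent)
    tail: str
    gene_id: str
    true_category: Category

    def seq(self, ref: PrecursorReference) -> str:
        return ref.seq[self.ref_start : self.templated_end] + self.tail


def _canonicalize(ref: PrecursorReference, b: int, tail: str) -> tuple[int, str]:
    """Shift tail bases that the genome can explain into the templated part."""
    seq = ref.seq
    while tail and b < len(seq) and tail[0] == seq[b] and seq[b] != "N":
        b += 1
        tail = tail[1:]
    return b, tail


def simulate_fragment(
    ref: PrecursorReference,
    category: Category,
    rng: np.random.Generator,
    config: SimulationConfig,
    max_retries: int = 50,
) -> SimFragment:
    """Draw one fragment of the requested truth category.

    Fragments start uniformly inside the (first) intron.  Draws whose
    canonical 3' split does not classify as the requested category
    (templated coincidence) are resampled.
    """
    if not ref.intron_offsets:
        raise SimulationError(f"{ref.gene_id}: no intron to anchor fragments")
    i0, i1 = ref.intron_offsets[0]
    trailer_len = len(ref.seq) - ref.gene_end
    for _ in range(max_retries):
        a = int(rng.integers(i0, i1))
        if category is Category.PROCESSED_EXACT:
            b, tail = ref.gene_end, ""
        elif category is Category.TRAILER:
            tlen = int(rng.integers(1, min(config.trailer_max, trailer_len) + 1))
            b, tail = ref.gene_end + tlen, ""
        elif category is Category.TRIMMED:
            d = int(rng.integers(1, config.trim_max + 1))
            b, tail = ref.gene_end - d, ""
            if b <= a:
                continue
        elif category in (Category.PLUS_C, Category.PLUS_CC, Category.PLUS_CCA):
            tail = {"PLUS_C": "C", "PLUS_CC": "CC", "PLUS_CCA": "CCA"}[category.value]
            b = ref.gene_end
        elif category is Category.OLIGO_A:
            k = int(rng.geometric(1.0 / config.oligoa_mean))
            u = rng.random()
            if u < 0.4:
                b, base_tail = ref.gene_end, ""
            elif u < 0.6:
                tlen = int(rng.integers(1, min(config.trailer_max, trailer_len) + 1))
                b, base_tail = ref.gene_end + tlen, ""
            elif u < 0.8:
                d = int(rng.integers(1, config.trim_max + 1))
                b, base_tail = ref.gene_end - d, ""
                if b <= a:
                    continue
            else:
                b, base_tail = ref.gene_end, "CCA"
            tail = base_tail + "A" * k
        else:
            raise SimulationError(f"cannot simulate category {category}")
        b, tail = _canonicalize(ref, b, tail)
        if classify_suffix(b - ref.gene_end, tail) is category:
            return SimFragment(a, b, tail, ref.gene_id, category)
    raise SimulationError(
        f"{ref.gene_id}: could not realize {category} in {max_retries} draws"
    )


def wrap_as_read(
    fragment: SimFragment,
    ref: PrecursorReference,
    config: SimulationConfig,
    rng: np.random.Generator,
    read_id: str = "read",
) -> RawRead:
    """Package a fragment as a sequencer read.

    read = adapter + reverse_complement(fragment), padded to the read
    length by extending the fragment 5' with templated reference bases
    (reads anchor at the RNA 3' end) or truncated keeping the 3'-most
    fragment portion; substitution errors and a two-level quality model
    are applied.
    """
    insert_len = config.read_length - len(config.adapter)
    frag_len = (fragment.templated_end - fragment.ref_start) + len(fragment.tail)
    a = fragment.ref_start
    if frag_len < insert_len:
        a = max(0, a - (insert_len - frag_len))
    sense = ref.seq[a : fragment.templated_end] + fragment.tail
    seq = (config.adapter + reverse_complement(sense))[: config.read_length]
    if config.substitution_error > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(arr)) < config.substitution_error)[0]
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
        seq = arr.tobytes().decode()
    q = config.q_low if rng.random() < config.low_q_fraction else config.q_high
    return RawRead(read_id=read_id, seq=seq, quals=[q] * len(seq))


def simulate_library(
    config: SimulationConfig,
    models: list[TRNAGeneModel],
) -> tuple[list[RawRead], list[TruthRecord]]:
    """Draw a full library: genes by gene_mixture, ends by category_mixture.

    Deterministic for a given config seed: all randomness flows from one
    numpy Generator consumed in read order.
    """
    refs = {m.gene_id: build_precursor_reference(m) for m in models}
    gene_ids = sorted(refs)
    if config.gene_mixture is None:
        gene_p = np.full(len(gene_ids), 1.0 / len(gene_ids))
    else:
        gene_p = np.array([config.gene_mixture.get(g, 0.0) for g in gene_ids])
    cats = [c for c in DEFAULT_CATEGORY_MIXTURE if config.category_mixture.get(c, 0) > 0]
    cat_p = np.array([config.category_mixture[c] for c in cats])
    cat_p = cat_p / cat_p.sum()

    rng = np.random.default_rng(config.seed)
    gene_draws = rng.choice(len(gene_ids), size=config.n_reads, p=gene_p)
    cat_draws = rng.choice(len(cats), size=config.n_reads, p=cat_p)

    reads: list[RawRead] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_reads):
        gene_id = gene_ids[int(gene_draws[i])]
        category = cats[int(cat_draws[i])]
        ref = refs[gene_id]
        frag = simulate_fragment(ref, category, rng, config)
        read_id = f"sim{i:07d}"
        reads.append(wrap_as_read(frag, ref, config, rng, read_id))
        truths.append(
            TruthRecord(
                read_id=read_id,
                gene_id=gene_id,
                true_category=category,
                true_end_offset=frag.templated_end - ref.gene_end,
                true_suffix=frag.tail,
            )
        )
    return reads, truths


def write_fastq(reads: list[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{quals}\n")


def write_truth(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\ttrue_category\ttrue_end_offset\ttrue_suffix\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.gene_id}\t{t.true_category.value}\t"
                f"{t.true_end_offset}\t{t.true_suffix}\n"
            )
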