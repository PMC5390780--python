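from __future__ import annotations

import numpy as np
import pytest

from pretrnaseq import (
    SimulationConfig,
    build_precursor_reference,
    make_fixture_genes,
    simulate_fragment,
    simulate_library,
    wrap_as_read,
)
from pretrnaseq.classify import Category
from pretrnaseq.preprocess import trim_adapter
from pretrnaseq.reference import reverse_complement
from pretrnaseq.simulate import FIXTURE_GENE_IDS, write_fastq


class TestFixtureGenes:
    def test_models_validate_and_have_introns(self, fixture_models):
        assert [m.gene_id for m in fixture_models] == FIXTURE_GENE_IDS
        for m in fixture_models:
            assert 80 <= len(m.gene_seq) <= 110
            (i0, i1) = m.intron_intervals[0]
            assert 14 <= i1 - i0 <= 32

    def test_gene_bodies_are_8mer_distinct(self, fixture_models):
        kmer_sets = []
        for m in fixture_models:
            ks = {m.gene_seq[i : i + 8] for i in range(len(m.gene_seq) - 7)}
            for other in kmer_sets:
                assert not (ks & other)
            kmer_sets.append(ks)

    def test_deterministic(self, tmp_path):
        a = make_fixture_genes(seed=4)
        b = make_fixture_genes(seed=4)
        assert a.chrom_seq == b.chrom_seq and a.rows == b.rows
        fa1, _ = a.write(tmp_path / "x")
        fa2, _ = b.write(tmp_path / "y")
        assert fa1.read_bytes() == fa2.read_bytes()

    def test_ambiguous_variant_has_one_cca_trailer(self, ambiguous_genome):
        refs = [build_precursor_reference(m) for m in ambiguous_genome.gene_models()]
        n_cca = sum(r.seq[r.gene_end :].startswith("CCA") for r in refs)
        assert n_cca == 1

    def test_mixed_strands(self, fixture_genome):
        strands = {row[4] for row in fixture_genome.rows}
        assert strands == {"+", "-"}


class TestSimulateFragment:
    @pytest.mark.parametrize("category", [
        Category.PROCESSED_EXACT, Category.TRAILER, Category.TRIMMED,
        Category.PLUS_C, Category.PLUS_CC, Category.PLUS_CCA, Category.OLIGO_A,
    ])
    def test_truth_is_canonical(self, fixture_refs, category):
        rng = np.random.default_rng(2)
        cfg = SimulationConfig(n_reads=1, seed=2)
        for ref in fixture_refs:
            for _ in range(20):
                frag = simulate_fragment(ref, category, rng, cfg)
                assert frag.true_category is category
                i0, i1 = ref.intron_offsets[0]
                assert i0 <= frag.ref_start < i1
                if category is Category.PLUS_CCA:
                    assert frag.tail == "CCA"
                    assert frag.templated_end == ref.gene_end
                if category is Category.TRAILER:
                    assert frag.templated_end > ref.gene_end and frag.tail == ""

    def test_oligo_a_suffix_ends_in_a_run(self, fixture_refs):
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(seed=3)
        for _ in range(50):
            frag = simulate_fragment(fixture_refs[0], Category.OLIGO_A, rng, cfg)
            assert frag.tail.endswith("A")
            assert frag.tail.rstrip("A") in ("", "C", "CC", "CCA")


class TestWrapAsRead:
    def test_round_trip_at_zero_error(self, fixture_refs):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(substitution_error=0.0, low_q_fraction=0.0, seed=5)
        ref = fixture_refs[0]
        frag = simulate_fragment(ref, Category.PLUS_CCA, rng, cfg)
        read = wrap_as_read(frag, ref, cfg, rng)
        assert len(read.seq) == cfg.read_length
        trimmed, verdict = trim_adapter(read, cfg.adapter)
        assert verdict == "trimmed"
        sense = reverse_complement(trimmed.seq)
        # the recovered insert is the fragment, 5'-extended with templated
        # reference sequence to fill the read
        assert sense.endswith(frag.tail)
        assert sense in ref.seq[: frag.templated_end] + frag.tail

    def test_long_fragment_keeps_three_prime_end(self, fixture_refs):
        rng = np.random.default_rng(6)
        cfg = SimulationConfig(substitution_error=0.0, low_q_fraction=0.0, seed=6)
        ref = fixture_refs[0]
        frag = simulate_fragment(ref, Category.TRAILER, rng, cfg)
        frag.ref_start = 0  # force a fragment longer than the insert space
        read = wrap_as_read(frag, ref, cfg, rng)
        insert = reverse_complement(read.seq[len(cfg.adapter) :])
        assert insert == ref.seq[: frag.templated_end][-len(insert) :]

    def test_error_rate_one_changes_bases(self, fixture_refs):
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(substitution_error=1.0, low_q_fraction=0.0, seed=7)
        ref = fixture_refs[0]
        frag = simulate_fragment(ref, Category.PROCESSED_EXACT, rng, cfg)
        clean = wrap_as_read(frag, ref, SimulationConfig(substitution_error=0.0), rng)
        noisy = wrap_as_read(frag, ref, cfg, rng)
        assert all(a != b for a, b in zip(clean.seq, noisy.seq))


class TestSimulateLibrary:
    def test_seed_determinism_byte_identical(self, fixture_models, tmp_path):
        cfg = SimulationConfig(n_reads=500, seed=7)
        r1, t1 = simulate_library(cfg, fixture_models)
        r2, t2 = simulate_library(cfg, fixture_models)
        f1, f2 = tmp_path / "a.fq", tmp_path / "b.fq"
        write_fastq(r1, f1)
        write_fastq(r2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert t1 == t2

    def test_pure_category_mixture(self, fixture_models):
        cfg = SimulationConfig(
            n_reads=100, seed=8,
            category_mixture={Category.PLUS_CCA: 1.0},
        )
        _, truths = simulate_library(cfg, fixture_models)
        assert all(t.true_category is Category.PLUS_CCA for t in truths)

    def test_degenerate_gene_mixture(self, fixture_models):
        gene = sorted(m.gene_id for m in fixture_models)[0]
        cfg = SimulationConfig(
            n_reads=100, seed=9,
            gene_mixture={gene: 1.0},
        )
        _, truths = simulate_library(cfg, fixture_models)
        assert {t.gene_id for t in truths} == {gene}

    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            SimulationConfig(category_mixture={Category.PLUS_CCA: 0.9})
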