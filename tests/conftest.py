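from __future__ import annotations

import pytest

from pretrnaseq import build_precursor_reference, make_fixture_genes

TOY_CHROM = "AAAACCCGGGTTTAAACCC"


@pytest.fixture(scope="session")
def toy_genome_dir(tmp_path_factory):
    """The hand-checkable toy genome: one 19-nt chromosome."""
    d = tmp_path_factory.mktemp("toy")
    (d / "genome.fa").write_text(f">chrT\n{TOY_CHROM}\n")
    return d


@pytest.fixture(scope="session")
def fixture_genome():
    return make_fixture_genes(seed=1)


@pytest.fixture(scope="session")
def fixture_models(fixture_genome):
    return fixture_genome.gene_models()


@pytest.fixture(scope="session")
def fixture_refs(fixture_models):
    return [build_precursor_reference(m) for m in fixture_models]


@pytest.fixture(scope="session")
def ambiguous_genome():
    return make_fixture_genes(seed=1, ambiguous=True)
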