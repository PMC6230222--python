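import pytest

from bipromstate.annotation import GeneModel, TranscriptModel
from bipromstate.simulate import SimConfig, generate_annotation, generate_sc_expression


def make_gene(gene_id, strand, exon_sets, chrom="chr1", biotype="protein_coding"):
    """Gene from a list of per-transcript exon lists (0-based half-open)."""
    txs = [
        TranscriptModel(f"{gene_id}.t{i + 1}", gene_id, chrom, strand, exons)
        for i, exons in enumerate(exon_sets)
    ]
    return GeneModel(gene_id, chrom, strand, txs, biotype)


@pytest.fixture(scope="session")
def small_config():
    """Reduced study for fast tests; archetypes keep their defaults."""
    return SimConfig(n_bp_per_state=12, n_cells=20, seed=7)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def small_expression(small_config, small_annotation):
    return generate_sc_expression(small_config, small_annotation)
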