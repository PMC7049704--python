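import pytest

from leakyscan import SimConfig, generate_end_reads, generate_expression, generate_genome
from leakyscan.simulate import default_kozak_truth


@pytest.fixture(scope="session")
def truth_model():
    return default_kozak_truth()


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study: genome, annotation, ground truth."""
    config = SimConfig(n_genes=60, seed=1)
    genome, genes, truth = generate_genome(config)
    return config, genome, genes, truth


@pytest.fixture(scope="session")
def small_sim_reads(small_sim):
    config, genome, genes, truth = small_sim
    reads = generate_end_reads(truth, genes, genome, config)
    return config, genome, genes, truth, reads


@pytest.fixture(scope="session")
def medium_sim():
    """A mid-sized study with expression, for group statistics."""
    config = SimConfig(n_genes=800, seed=1)
    genome, genes, truth = generate_genome(config)
    expr = generate_expression(truth, config)
    return config, genome, genes, truth, expr
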