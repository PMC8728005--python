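import numpy as np
import pytest

from redwoodkit import synthetic_data as sd


@pytest.fixture
def sim_seed() -> int:
    return 42


@pytest.fixture
def scaffold_sim(sim_seed):
    cfg = sd.ScaffoldConfig()
    records, truth = sd.gen_scaffolds(cfg, sim_seed)
    return cfg, records, truth


@pytest.fixture
def gene_sim(sim_seed):
    cfg = sd.GeneModelConfig()
    models, genome, truth, evidence = sd.gen_gene_models(cfg, sim_seed)
    return cfg, models, genome, truth, evidence


@pytest.fixture
def ortho_sim(sim_seed):
    cfg = sd.OrthogroupConfig()
    matrix, truth = sd.gen_orthogroups(cfg, sim_seed)
    return cfg, matrix, truth


@pytest.fixture
def variant_sim():
    # small table for unit tests; acceptance uses the full default size
    cfg = sd.VariantConfig(n_loci=2_000, scaffold_length=100_000)
    return cfg, sd.gen_variants(cfg, 7)
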