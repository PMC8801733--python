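import numpy as np
import pytest

from ltrdyn.simulate import (SimConfig, make_design, simulate_counts,
                             simulate_genome, simulate_methylome, simulate_sirna)


@pytest.fixture(scope="session")
def sim_dataset():
    """One mid-sized synthetic dataset shared by read-only tests."""
    cfg = SimConfig(seed=11)
    genome, genes, copies, truth = simulate_genome(cfg)
    return cfg, genome, genes, copies, truth


@pytest.fixture(scope="session")
def sim_counts(sim_dataset):
    cfg, genome, genes, copies, truth = sim_dataset
    design = make_design()
    rng = np.random.default_rng(12)
    gene_cm, te_cm, truth = simulate_counts(copies, genes, design, cfg, truth, rng)
    return design, gene_cm, te_cm, truth
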