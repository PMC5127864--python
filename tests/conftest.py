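import numpy as np
import pytest

from viropan.synthetic_data import (
    SimulationConfig,
    emit_hit_table,
    emit_proteomes,
    emit_reference_hits,
    simulate_gene_content,
    simulate_tree,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small noise-free simulation shared across tests: 6 taxa, 40 root
    families, no spurious hits."""
    cfg = SimulationConfig(
        n_taxa=6, n_families_root=40, gain_rate=0.05, loss_rate=0.05,
        spurious_hit_rate=0.0, seed=7,
    )
    tree = simulate_tree(cfg.n_taxa, cfg.seed)
    truth = simulate_gene_content(tree, cfg)
    proteomes = emit_proteomes(truth, cfg)
    allvall = emit_hit_table(proteomes, truth, cfg)
    refhits = emit_reference_hits(proteomes, truth, cfg)
    return cfg, truth, proteomes, allvall, refhits


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
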