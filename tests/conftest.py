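import numpy as np
import pytest

import mitophylo as mp
from mitophylo.simulate import SimConfig, evolve_sequences, simulate_tree, synth_genome


@pytest.fixture(scope="session")
def table2_genome():
    """The bundled genome-organization table (sequence-free mode)."""
    return mp.read_feature_table(mp.bundled_annotation_path())


@pytest.fixture(scope="session")
def synthetic_genome():
    """A default-layout synthetic annotated mitogenome."""
    return synth_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_dataset():
    """A 6-taxon tree plus a TN93 alignment evolved along it."""
    cfg = SimConfig(seed=7, n_taxa=6, seq_length=8000)
    streams = cfg.streams()
    tree = simulate_tree(cfg, rng=streams["tree"])
    aln = evolve_sequences(tree, cfg, rng=streams["sequences"])
    return cfg, tree, aln


@pytest.fixture
def rng():
    return np.random.default_rng(42)
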