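import numpy as np
import pytest

import roguenet as rn
from helpers import fig2_sample, make_sample


@pytest.fixture
def fig2():
    """Two trees differing only in where taxon x attaches."""
    return fig2_sample()


@pytest.fixture
def identical_sample():
    """Twenty copies of one resolved 10-taxon tree."""
    nwk = rn.random_resolved_newick([f"t{i}" for i in range(10)], seed=42)
    return make_sample([nwk] * 20)


@pytest.fixture
def noisy_sample():
    """A 12-taxon, 60-tree sample with NNI noise and one planted rogue."""
    cfg = rn.SimulationConfig(n_taxa=12, n_trees=60, rogue_taxa=("r1",),
                              core_perturb_rate=0.3, seed=7)
    sample, truth = rn.simulate_sample(cfg)
    return sample, truth


def random_sample(seed, n_taxa=10, n_trees=40, perturb=0.5, rogues=()):
    cfg = rn.SimulationConfig(n_taxa=n_taxa, n_trees=n_trees,
                              rogue_taxa=tuple(rogues),
                              core_perturb_rate=perturb, seed=seed)
    sample, _ = rn.simulate_sample(cfg)
    return sample
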