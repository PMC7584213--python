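import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

import karyorate as kr
from karyorate.likelihood import TipObservation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def cherry():
    """Two-tip tree, both branches 50 Myr."""
    return kr.Phylogeny.from_newick("(t1:50,t2:50);")


@pytest.fixture
def small_space():
    return kr.build_state_space(1, 3)


@pytest.fixture
def tiny_dataset():
    """Eight-taxon dataset with both regimes and one multi-record taxon."""
    obs = [
        TipObservation("t1", 4, kr.MONOCENTRIC),
        TipObservation("t2", 5, kr.MONOCENTRIC),
        TipObservation("t3", 5, kr.MONOCENTRIC),
        TipObservation("t4", 6, kr.MONOCENTRIC),
        TipObservation("t5", 6, kr.HOLOCENTRIC),
        TipObservation("t5", 7, kr.HOLOCENTRIC),
        TipObservation("t6", 7, kr.HOLOCENTRIC),
        TipObservation("t7", 8, kr.HOLOCENTRIC),
        TipObservation("t8", 8, kr.HOLOCENTRIC),
    ]
    return kr.ChromosomeDataset.from_observations(obs)


@pytest.fixture
def tiny_trees(rng):
    base = kr.simulate_yule_tree(8, 1.0, rng, height_target=80.0)
    return kr.emulate_posterior_trees(base, 3, 0.05, rng)


@pytest.fixture
def tiny_tip_data(tiny_dataset):
    return {taxon: recs[0] for taxon, recs in tiny_dataset.records.items()}
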