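import warnings

import numpy as np
import pytest

from methmotif.synthdata import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully featured cohort: quick to simulate, rich enough to screen."""
    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=80_000,
        n_cpgs=500,
        n_samples=80,
        n_motifs_decoy=6,
        n_motifs_planted=2,
        n_causal_survival_cpgs=50,
        n_diffmeth_cpgs=60,
        n_tf_nodes=12,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
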