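import numpy as np
import pandas as pd
import pytest

import dosagefx as d


@pytest.fixture(scope="session")
def genome():
    """Small genome with all six arms, fixed seed."""
    return d.build_genome(
        {"X": 120, "2L": 120, "2R": 120, "3L": 120, "3R": 120, "4": 20}, seed=11
    )


@pytest.fixture(scope="session")
def model(genome):
    return d.EffectModel.default(genome, seed=12, n_stable=30)


@pytest.fixture(scope="session")
def trisomy_counts(genome, model):
    """Trisomy-2L female vs diploid female, 3 replicates each."""
    return d.simulate_counts(
        genome,
        model,
        [("trisomy2L_female", 3, 1), ("diploid_female", 3, 1)],
        seed=13,
    )


def nb_counts(rng, mu, alpha, n):
    """Plain NB count matrix draw used by oracle-driven tests."""
    r = 1.0 / alpha
    return np.column_stack([rng.negative_binomial(r, r / (r + mu)) for _ in range(n)])


@pytest.fixture
def nb_matrix():
    return nb_counts
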