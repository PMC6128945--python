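"""Shared fixtures and deterministic test settings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from basinflow import GenotypeMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(calls, pops, locus_ids=None, positions=None):
    """Build a GenotypeMatrix from a dense call array and population labels.

    `calls` is (n_individuals, n_loci); `pops` one label per individual.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_loci = calls.shape
    individuals = [f"ind{i}" for i in range(n_ind)]
    populations = dict(zip(individuals, pops))
    if locus_ids is None:
        locus_ids = [f"L{j}" for j in range(n_loci)]
    if positions is None:
        positions = [1] * n_loci
    loci = pd.DataFrame(
        {"locus_id": locus_ids, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(individuals, populations, loci, calls)


@pytest.fixture
def two_pop_fixed_difference():
    """Two populations fixed for opposite alleles at every locus."""
    calls = np.array(
        [[0, 0, 0], [0, 0, 0], [0, 0, 0], [2, 2, 2], [2, 2, 2], [2, 2, 2]]
    )
    return make_matrix(calls, ["A"] * 3 + ["B"] * 3)


@pytest.fixture
def random_two_pop():
    """Two populations drawn from one panmictic pool (exchangeable)."""
    rng = np.random.default_rng(7)
    freqs = rng.uniform(0.1, 0.9, size=60)
    calls = rng.binomial(2, freqs[None, :], size=(12, 60))
    return make_matrix(calls, ["A"] * 6 + ["B"] * 6)
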