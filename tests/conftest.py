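"""Shared fixtures and the individual-level simulation oracle."""

import numpy as np
import pytest

from evocea.markov_engine import RiskModel, RunConfig, cycle_matrices
from evocea.state_space import build_state_space
from evocea.synthetic_data import (
    gen_default_parameters,
    gen_life_table,
    gen_population,
)


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture(scope="session")
def params():
    return gen_default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return gen_life_table(seed=1)


@pytest.fixture(scope="session")
def peace():
    return gen_population("PEACE")


@pytest.fixture(scope="session")
def berson():
    return gen_population("BERSON")


def microsimulate(config: RunConfig, space, risks: RiskModel,
                  n_patients: int, seed: int) -> np.ndarray:
    """Individual-level oracle: simulate ``n_patients`` through the same
    per-cycle transition matrices the cohort engine uses and return the
    empirical occupancy fractions, shape (horizon + 1, n_states)."""
    rng = np.random.default_rng(seed)
    matrices = cycle_matrices(config, space, risks)
    n_states = len(space)
    state = np.full(n_patients, space.index(config.entry_state), dtype=int)
    occupancy = np.zeros((config.horizon + 1, n_states))
    occupancy[0] = np.bincount(state, minlength=n_states) / n_patients
    for t, tm in enumerate(matrices):
        cdf = np.cumsum(tm.matrix, axis=1)
        u = rng.random(n_patients)
        rows = cdf[state]
        state = (u[:, None] > rows).sum(axis=1)
        occupancy[t + 1] = np.bincount(state, minlength=n_states) / n_patients
    return occupancy
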