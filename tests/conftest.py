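"""Shared fixtures: small structure sets and a calibrated toy seed cell."""

import dataclasses

import numpy as np
import pytest

import mutatorsim as ms
from mutatorsim import cell as cm
from mutatorsim.design import DesignConfig, design_seed_genome


@pytest.fixture(scope="session")
def tiny_set():
    """200 deterministic compact conformations (lexicographic canonical)."""
    return ms.enumerate_compact_conformations(limit=200)


@pytest.fixture(scope="session")
def em085():
    return ms.load_mj_energy_model(0.85)


@pytest.fixture(scope="session")
def toy_seed(tiny_set, em085):
    """A designed, calibrated seed cell on the tiny structure set.

    Returns (cell, params, env) with G_ref and b0 calibrated so that the
    seed is exactly wild-type (m = m_min) and b = d.
    """
    rng = np.random.default_rng(1234)
    env = cm.CellEnv(tiny_set, em085)
    genome, _ = design_seed_genome(tiny_set, em085, DesignConfig(), rng)
    params = ms.RunConfig().fitness_params()
    seed, reason = cm.develop(genome, np.full(4, 0.1), env, params)
    assert seed is not None, reason
    params = dataclasses.replace(
        params, G_ref=seed.G44, b0=params.d / (seed.G1 * seed.G23)
    )
    seed, reason = cm.develop(genome, np.full(4, 0.1), env, params)
    assert seed is not None, reason
    return seed, params, env
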