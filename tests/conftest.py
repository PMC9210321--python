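"""Shared fixtures: synthetic data sets reused across the suite.

The two expensive fixtures (a structured-fitness simulation and an
all-neutral simulation, both fitted with the negative-binomial model) are
session-scoped so the joint fits run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pepfit import SimulationConfig, fit_experiment, simulate


@pytest.fixture(scope="session")
def recovery_sim():
    """n=500 lineages, depth 1e5, kappa=2, composition-linked fitness, NB fit."""
    cfg = SimulationConfig(n_lineages=500, depth=100_000, kappa=2.0, seed=7)
    sim = simulate(cfg)
    fit = fit_experiment(sim["experiment"], model="negative_binomial")
    return cfg, sim, fit


@pytest.fixture(scope="session")
def neutral_sim():
    """Same conditions but all true fitness = 1 (type-I error checks)."""
    cfg = SimulationConfig(
        n_lineages=500, depth=100_000, kappa=2.0, seed=11,
        true_effects={}, noise_sd=0.0,
    )
    sim = simulate(cfg)
    fit = fit_experiment(sim["experiment"], model="negative_binomial")
    return cfg, sim, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
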