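"""Shared fixtures.

The acceptance tests share one benchmark-scale sweep (30 replicates of
equilibrium / mu=15 / mu=5 data at T = 5 on the packaged 413-edge graph)
so the expensive data generation and plmDCA fits run once per session.
All seeds are fixed constants chosen up front.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import phylodca as pdca

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Master seeds for the shared benchmark-scale datasets (fixed up front).
SWEEP_SEED = 0
MU_GRID_SEED = 1


@pytest.fixture(scope="session")
def graph():
    return pdca.benchmark_graph()


@pytest.fixture(scope="session")
def spec(graph):
    return pdca.HamiltonianSpec(graph=graph)


@pytest.fixture(scope="session")
def small_graph():
    """Deterministic 10-site ER graph for fast end-to-end tests."""
    return pdca.sample_er_graph(10, 0.3, rng=7)


@pytest.fixture(scope="session")
def benchmark_sweep(graph):
    """30 replicates x {equilibrium, mu=15, mu=5} at T = 5, all methods.

    Used by the acceptance tests for criteria 1, 2 and 5.
    """
    config = pdca.ExperimentConfig(
        graph=graph,
        temperatures=(5.0,),
        mus=(pdca.EQUILIBRIUM, 15, 5),
        n_generations=11,
        n_replicates=30,
        equilibrium_proposal="wolff_cluster",
        master_seed=SWEEP_SEED,
    )
    df = pdca.run_sweep(config)
    assert not df["failed"].any(), "some sweep cells failed"
    return df


@pytest.fixture(scope="session")
def mu_grid_sweep(graph):
    """10 replicates over the mu grid {2, 5, 15, 100} at T = 5 (criterion 7)."""
    config = pdca.ExperimentConfig(
        graph=graph,
        temperatures=(5.0,),
        mus=(2, 5, 15, 100),
        n_generations=11,
        n_replicates=10,
        master_seed=MU_GRID_SEED,
    )
    df = pdca.run_sweep(config)
    assert not df["failed"].any(), "some sweep cells failed"
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
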