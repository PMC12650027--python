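"""Shared fixtures: small worlds and short simulations kept desk-scale."""

import dataclasses

import numpy as np
import pytest

from learnwalks.agent import Environment, run_walk_series
from learnwalks.config import nominal_config
from learnwalks.world import OdourField, generate_terrain


def small_config(**agent_overrides):
    """Nominal model parameters on a small, fast world for unit tests."""
    cfg = nominal_config()
    world = dataclasses.replace(cfg.world, n_objects=15, extent=4.0,
                                scatter_radius=1.5, n_az=48, n_el=13)
    mb = dataclasses.replace(cfg.mb, n_kc=400)
    agent = dataclasses.replace(cfg.agent, np1=30, scans_per_walk=(2, 4, 6, 8),
                                max_homing_steps=600, **agent_overrides)
    return cfg.replace(world=world, mb=mb, agent=agent)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_env(small_cfg):
    return Environment.from_config(small_cfg, 42)


@pytest.fixture(scope="session")
def small_mesh():
    return generate_terrain(3, n_objects=20, extent=5.0, scatter_radius=2.0)


@pytest.fixture(scope="session")
def odour_field():
    return OdourField(sigma=0.2)


@pytest.fixture(scope="session")
def small_series(small_env):
    """One short 4-walk series on the small world (shared across tests)."""
    records, snapshots, state = run_walk_series(small_env, 123)
    return records, snapshots, state
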