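"""Shared fixtures: a small deterministic synthetic cohort and its profiles."""

from __future__ import annotations

import numpy as np
import pytest

import lesionforest as lf
from lesionforest.synthetic_cohort import SimulationConfig


@pytest.fixture(scope="session")
def default_sim():
    """One default-shaped cohort (55 patients, G=2) reused read-only."""
    return lf.simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_dataset(default_sim):
    return default_sim.dataset()


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    profiles = lf.compute_depth_profiles(default_dataset)
    return lf.profiles_frame(profiles, default_dataset.group_map.view_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
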