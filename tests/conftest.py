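"""Shared fixtures: synthetic sessions at the study's default scale and a
small session for fast structural tests.

Heavy objects (full 600-trial / 350-unit sessions, the RT-binned rate
tensor) are session-scoped so every test shares one copy.
"""

from __future__ import annotations

import numpy as np
import pytest

from popdyn import geometry
from popdyn.rates import compute_rate_tensor
from popdyn.simulate import SimulationConfig, simulate_session

#: base seed for all simulated fixtures
SEED = 11


def _full_config(hypothesis: str) -> SimulationConfig:
    return SimulationConfig(hypothesis=hypothesis, seed=SEED)


@pytest.fixture(scope="session")
def sim1_session():
    return simulate_session(_full_config("sim1_no_prestim"))


@pytest.fixture(scope="session")
def sim2_session():
    return simulate_session(_full_config("sim2_choice_bias"))


@pytest.fixture(scope="session")
def sim3_session():
    return simulate_session(_full_config("sim3_rt_covariation"))


@pytest.fixture(scope="session")
def small_session():
    """A reduced sim3 session for structural and I/O tests."""
    cfg = SimulationConfig(
        hypothesis="sim3_rt_covariation",
        n_increased=16,
        n_decreased=8,
        n_perimovement=6,
        n_trials=60,
        seed=SEED + 1,
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def sim3_rt_tensor(sim3_session):
    """RT-binned, choice-split trial-averaged rate tensor for sim3."""
    return compute_rate_tensor(sim3_session, grouping="rt")


@pytest.fixture(scope="session")
def sim3_trajectories(sim3_rt_tensor):
    """Six-PC trajectories per RT bin and choice, middle bin as reference."""
    pcs = geometry.fit_pca_tensor(sim3_rt_tensor)
    trajset = geometry.project(sim3_rt_tensor, pcs, n_dims=6)
    trajset.reference_index = len(sim3_rt_tensor.condition_labels) // 2
    return trajset
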