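"""Shared fixtures: small simulated studies and hand-built latents."""

from __future__ import annotations

import numpy as np
import pytest

from assessgame.game_engine import generate_target_path
from assessgame.pipeline import score_study
from assessgame.session_model import AffectedSideMap, JointId, all_joints
from assessgame.simulator import ParticipantLatent, SimulationConfig, simulate_cohorts


def make_latent(
    pid: str = "p001",
    sigma_track: float = 0.0,
    lag: float = 0.0,
    c_mirror: float = 0.0,
    c_adjacent: float = 0.0,
    c_other: float = 0.0,
    fidget_sd: float = 0.0,
    occasion: str = "test",
    group: str = "patient",
    age: float = 12.0,
    rom: tuple[float, float] = (0.0, 50.0),
) -> ParticipantLatent:
    """A participant with fully controlled latent parameters."""
    return ParticipantLatent(
        participant_id=pid,
        group=group,
        occasion=occasion,
        age=age,
        sigma_track=sigma_track,
        lag=lag,
        c_mirror=c_mirror,
        c_adjacent=c_adjacent,
        c_other=c_other,
        fidget_sd=fidget_sd,
        trunk=0.0,
        asymmetry=1.0,
        affected=AffectedSideMap("left"),
        rom={j: rom for j in all_joints()},
    )


@pytest.fixture(scope="session")
def short_config() -> SimulationConfig:
    """Shortened phases keep unit tests fast; study structure unchanged."""
    return SimulationConfig(
        n_adults=8,
        n_controls=6,
        n_patients=6,
        seed=123,
        accommodation_duration=5.0,
        test_duration=12.0,
    )


@pytest.fixture(scope="session")
def small_study(short_config):
    return simulate_cohorts(short_config)


@pytest.fixture(scope="session")
def small_scored(small_study):
    return score_study(small_study, seed=123)


@pytest.fixture()
def short_path():
    return generate_target_path(duration=12.0, n_curves=3, seed=5, sampling_rate=50.0)


@pytest.fixture()
def short_sim_config() -> SimulationConfig:
    return SimulationConfig(
        accommodation_duration=5.0, test_duration=12.0, missing_rate=0.0
    )
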