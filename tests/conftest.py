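"""Shared fixtures: small mazes, short trials, and a reusable mini-cohort."""

import numpy as np
import pytest

from audiomaze.maze import MazeSpec, build_maze
from audiomaze.simulate import AgentParams, simulate_trial


@pytest.fixture(scope="session")
def straight_maze():
    return build_maze("straight")


@pytest.fixture(scope="session")
def l_maze():
    return build_maze("L")


@pytest.fixture(scope="session")
def short_maze():
    """A 3 m corridor in the standard room — short enough to exit."""
    walls = [
        ((3.4, 0.5), (3.4, 3.5)),
        ((4.6, 0.5), (4.6, 3.5)),
        ((3.4, 0.5), (4.6, 0.5)),
    ]
    maze = MazeSpec(
        walls=walls,
        shape_id="short",
        start_position=(4.0, 1.0),
        start_heading=np.pi / 2,
        exit_segment=((3.4, 3.5), (4.6, 3.5)),
    )
    return maze


@pytest.fixture(scope="session")
def sample_trial(l_maze):
    """One 300-step map-updating walk, reused by read-only tests."""
    agent = AgentParams(policy="map_update")
    record, final_map = simulate_trial(l_maze, agent, seed=42, step_cap=300)
    return record, final_map


@pytest.fixture(scope="session")
def sample_series(sample_trial):
    record, _ = sample_trial
    return record.to_motion_series()
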