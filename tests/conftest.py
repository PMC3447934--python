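"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from qdtrack import AnalysisConfig, Trajectory


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


def make_traj(xy: np.ndarray, dt: float = 0.1, traj_id: str = "t", start: int = 0) -> Trajectory:
    xy = np.asarray(xy, dtype=float)
    return Trajectory(
        id=traj_id,
        frames=np.arange(start, start + len(xy)),
        x=xy[:, 0],
        y=xy[:, 1],
        dt=dt,
    )


def line_traj(n: int, v: float = 1.0, dt: float = 0.1, angle: float = 0.0) -> Trajectory:
    """Noise-free ballistic trajectory at speed v."""
    t = np.arange(n) * dt
    xy = np.column_stack([v * t * np.cos(angle), v * t * np.sin(angle)])
    return make_traj(xy, dt=dt)


def brownian_xy(n: int, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Plain-numpy Brownian positions, independent of the package generator."""
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n - 1, 2))
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
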