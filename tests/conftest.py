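"""Shared fixtures: programmatically built trajectories and small cohorts."""

import numpy as np
import pytest

from cionetho import SimConfig, Trajectory


def make_traj(x_mm, y_mm, fps=30.0, gaps=None, animal_id="t"):
    """Build a Trajectory from position arrays (mm)."""
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    n = len(x)
    gap = np.zeros(n, dtype=bool)
    if gaps is not None:
        gap[np.asarray(gaps)] = True
        x = x.copy()
        y = y.copy()
        x[gap] = np.nan
        y[gap] = np.nan
    return Trajectory(
        t=np.arange(n) / fps, x=x, y=y, fps=fps, gap_mask=gap, animal_id=animal_id
    )


def straight_line(speed_um_s, n=900, fps=30.0, angle=0.0, origin=(0.0, 0.0)):
    """Constant-velocity trajectory at the given speed (um/s)."""
    step = speed_um_s / fps * 1e-3  # mm per frame
    d = np.arange(n) * step
    return make_traj(
        origin[0] + d * np.cos(angle), origin[1] + d * np.sin(angle), fps=fps
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_config():
    """Single near-stationary regime; tiny and fast to simulate."""
    from cionetho import ModeRegime

    reg = ModeRegime("still", 0.0, 0.5, 1.0, 5.0)
    return SimConfig(
        regimes=[reg],
        fps=30.0,
        duration=20.0,
        undulation_amp=0.0,
        undulation_freq=5.0,
        dropout_rate=0.0,
        wall_bias=0.0,
        seed=0,
    )
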