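import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from trajkin import MotionRecipe, SkeletonSequence, generate_wipe_sequence
from trajkin.kinematics import RelativeTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle_trajectory():
    """360 points on the unit circle centred at the origin, 1° steps."""
    th = np.deg2rad(np.arange(361, dtype=float))
    pts = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    return RelativeTrajectory("unit_circle", 0, pts, 30.0)


@pytest.fixture
def box_grid_trajectory():
    """Deterministic grid filling an axis-aligned box, centre off-origin.

    Half-sizes a > b > c and an off-axis centre keep the cross product of the
    cloud centre with the main axis well-posed.
    """
    a, b, c = 0.30, 0.20, 0.10
    xs = np.linspace(-a, a, 7)
    ys = np.linspace(-b, b, 5)
    zs = np.linspace(-c, c, 3)
    grid = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    return RelativeTrajectory("box", 0, grid + [0.1, 0.8, 0.05], 30.0), (a, b, c)


@pytest.fixture
def wipe_sequence():
    return generate_wipe_sequence(MotionRecipe(duration=10.0, seed=7))


@pytest.fixture
def clean_wipe_sequence():
    return generate_wipe_sequence(
        MotionRecipe(duration=10.0, jitter=0.0, depth_noise=0.0, seed=7)
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix via QR with positive diagonal."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
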