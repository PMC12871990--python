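import numpy as np
import pytest

from cellph import Contour, NucleusCenter


@pytest.fixture
def square():
    return Contour(np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]]), id="square")


@pytest.fixture
def circle64():
    t = 2 * np.pi * np.arange(64) / 64
    return Contour(np.column_stack([10 * np.cos(t), 10 * np.sin(t)]), id="circle64")


@pytest.fixture
def centre_origin():
    return NucleusCenter(0.0, 0.0)


def rigid(points: np.ndarray, angle: float, shift) -> np.ndarray:
    """Rotate by `angle` and translate by `shift`."""
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return points @ R.T + np.asarray(shift, dtype=float)


def polygon_contour(radii, id="poly", phase=0.0) -> Contour:
    """Star polygon whose vertex i has radius radii[i] at angle 2*pi*i/n."""
    r = np.asarray(radii, dtype=float)
    theta = 2 * np.pi * np.arange(len(r)) / len(r) + phase
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]), id=id)


def random_diagram(rng, max_points=5):
    """Random persistence diagram array with birth <= death."""
    m = int(rng.integers(0, max_points + 1))
    births = rng.uniform(0, 5, m)
    deaths = births + rng.uniform(0, 5, m)
    return np.column_stack([births, deaths])
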