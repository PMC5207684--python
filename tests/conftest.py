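import numpy as np
import pytest
from scipy import integrate

from gazetherm.panels import DirectionPanel, GazePanel


def two_spin_alignment_quad(beta: float) -> float:
    """Quadrature oracle for <s1.s2> of two XY spins with coupling/T = beta.

    The relative angle phi has density ~ exp(beta cos phi); the alignment
    is the circular average of cos phi under that density.
    """
    z = integrate.quad(lambda p: np.exp(beta * np.cos(p)), 0, 2 * np.pi)[0]
    num = integrate.quad(lambda p: np.cos(p) * np.exp(beta * np.cos(p)),
                         0, 2 * np.pi)[0]
    return num / z


def two_spin_heat_capacity_quad(j: float, t: float) -> float:
    """Quadrature oracle for C_V of the two-spin XY model at coupling j,
    temperature t (energy E = -j cos phi)."""
    b = j / t
    z = integrate.quad(lambda p: np.exp(b * np.cos(p)), 0, 2 * np.pi)[0]
    e1 = integrate.quad(lambda p: -j * np.cos(p) * np.exp(b * np.cos(p)),
                        0, 2 * np.pi)[0] / z
    e2 = integrate.quad(lambda p: (j * np.cos(p)) ** 2
                        * np.exp(b * np.cos(p)), 0, 2 * np.pi)[0] / z
    return (e2 - e1 ** 2) / t ** 2


def make_panel(x: np.ndarray, y: np.ndarray, rate_hz: float = 250.0,
               missing: np.ndarray | None = None) -> GazePanel:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if missing is None:
        missing = np.zeros_like(x, dtype=bool)
    times = np.arange(x.shape[1]) * 1000.0 / rate_hz
    ids = [f"s{i:02d}" for i in range(x.shape[0])]
    return GazePanel(times, x, y, missing, ids)


def panel_from_angles(angles: np.ndarray,
                      valid: np.ndarray | None = None) -> DirectionPanel:
    """DirectionPanel from an (n_subjects, n_samples) array of angles."""
    angles = np.asarray(angles, dtype=float)
    sigma = np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    if valid is None:
        valid = np.ones(angles.shape, dtype=bool)
    sigma = np.where(valid[..., None], sigma, 0.0)
    ids = [f"s{i:02d}" for i in range(angles.shape[0])]
    return DirectionPanel(sigma, valid, ids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
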