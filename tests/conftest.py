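import numpy as np
import pytest

from serialcoal import DemographicModel, EpochParams
from serialcoal.simulate import random_epoch


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def d1_epoch():
    """Single deme, gamma = 1: branch length is 2 x Exp(1), density e^{-b/2}/2."""
    return EpochParams(0.0, np.inf, M=[[0.0]], gamma=[1.0])


@pytest.fixture
def sym2_epoch():
    """Symmetric two-deme island: m = 1 both ways, gamma = (1, 1), B* = [[4,5],[5,4]]."""
    return EpochParams(0.0, np.inf, M=[[0.0, 1.0], [1.0, 0.0]], gamma=[1.0, 1.0])


@pytest.fixture
def three_epoch_model():
    """Asymmetric two-deme model with epoch changes at t = 1 and t = 2."""
    return DemographicModel(
        [
            EpochParams(0.0, 1.0, M=[[0, 1.0], [2.0, 0]], gamma=[1.0, 0.5]),
            EpochParams(1.0, 2.0, M=[[0, 0.5], [0.3, 0]], gamma=[0.8, 1.2]),
            EpochParams(2.0, np.inf, M=[[0, 1.0], [1.0, 0]], gamma=[1.0, 1.0]),
        ]
    )


def random_model(rng, d=None, n_epochs=None, boundary_step=0.25):
    """Random multi-epoch model with boundaries on a coarse time grid, so the
    default pdf grids stay commensurate with epoch durations."""
    if d is None:
        d = int(rng.integers(1, 4))
    if n_epochs is None:
        n_epochs = int(rng.integers(1, 4))
    bounds = np.cumsum(rng.integers(1, 5, size=n_epochs - 1)) * boundary_step
    starts = np.concatenate([[0.0], bounds])
    ends = np.concatenate([bounds, [np.inf]])
    return DemographicModel(
        [
            random_epoch(d, rng, t_start=s, t_end=e)
            for s, e in zip(starts, ends)
        ]
    )
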