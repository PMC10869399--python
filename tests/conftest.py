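import numpy as np
import pytest

import vcbm


@pytest.fixture
def mech():
    """Scaled mechanics used throughout the tests: 1 mm cells, 24 h maturation."""
    return vcbm.MechanicsConfig(s=1.0, t_age=24.0, lam=0.25)


@pytest.fixture
def calib():
    return vcbm.VolumeCalibration(cell_diameter=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hex_patch(s: float = 1.0) -> np.ndarray:
    """A 7-point hexagonal patch: centre (index 0) plus 6 ring points at radius s."""
    ang = np.arange(6) * np.pi / 3.0
    ring = s * np.column_stack([np.cos(ang), np.sin(ang)])
    return np.vstack([[0.0, 0.0], ring])


def pair_state(gap: float, mech: vcbm.MechanicsConfig) -> vcbm.TissueState:
    """An isolated two-cell state at the given separation, both cells mature."""
    from vcbm.simulator import _complete_adjacency

    pos = np.array([[0.0, 0.0], [gap, 0.0]])
    return vcbm.TissueState(
        positions=pos,
        kinds=np.array([vcbm.TUMOUR, vcbm.TUMOUR], dtype=np.int8),
        t_d=np.array([vcbm.MATURE, vcbm.MATURE]),
        adjacency=_complete_adjacency(2),
    )
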