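import numpy as np
import pytest

from coopmove.games import GameSpec
from coopmove.movement import MovementSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def pgg():
    return GameSpec(kind="public_goods", R=10.0, V=2.0, C=1.0)


@pytest.fixture
def hd():
    return GameSpec(kind="hawk_dove", R=10.0, V=2.0, C=1.0)


def mechanism_specs(N, h, theta_scale=1.0):
    """One spec per mechanism at the given size and home fidelity."""
    return [
        MovementSpec("independent", h, N),
        MovementSpec("follow_majority", h, N),
        MovementSpec("polya_urn", h, N, B=2.0),
        MovementSpec("wheel", h, N, theta=theta_scale * np.pi / N),
    ]
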