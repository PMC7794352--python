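import numpy as np
import pytest

from srintools import ProbeImageStack


def random_valid_stack(rng, shape=(32, 32)):
    """Random stack in which most pixels carry detectable signal.

    P0 is low background, P1 sits well above it, P2-P4 range from below
    background to above the P1 level so that all clipping branches are
    exercised.
    """
    h, w = shape
    p0 = rng.uniform(0, 50, (h, w))
    p1 = p0 + rng.uniform(80, 200, (h, w))
    probes = [p0 + rng.uniform(-30, 250, (h, w)).clip(min=-p0 * 0 + 0) for _ in range(3)]
    probes = [np.clip(p, 0, None) for p in probes]
    return ProbeImageStack.from_arrays(p0, p1, *probes)


def constant_stack(p0, p1, p2, p3, p4, shape=(4, 4)):
    """Stack of constant images, one value per round."""
    mk = lambda v: np.full(shape, float(v))
    return ProbeImageStack.from_arrays(mk(p0), mk(p1), mk(p2), mk(p3), mk(p4))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def valid_stack(rng):
    return random_valid_stack(rng)
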