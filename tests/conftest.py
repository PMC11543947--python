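import numpy as np
import pytest

from seedbench.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0, hi=20, conf_choices=None):
    """Integer-coordinate box with strictly positive extent."""
    x0, y0 = rng.integers(lo, hi - 1, size=2)
    x1 = rng.integers(x0 + 1, hi + 1)
    y1 = rng.integers(y0 + 1, hi + 1)
    conf = None
    if conf_choices is not None:
        conf = float(rng.choice(conf_choices))
    return Box(float(x0), float(y0), float(x1), float(y1), conf)
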