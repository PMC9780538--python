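import numpy as np
import pytest

from awaremdp import CurveShape, preset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def fig6_small():
    """Figure-6 configuration with a small ensemble for fast unit tests."""
    return preset("fig6", seed=101, N=200)


@pytest.fixture
def symmetric_shape():
    """Mirror-symmetric curve shapes: intuitive(u) = analytical(1 - u)."""
    return CurveShape(sharp_analytical=5.0, sharp_intuitive=5.0)
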