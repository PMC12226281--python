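import numpy as np
import pytest

from netgic.weighted_model import (
    KernelWeighting,
    build_weighted_design,
    gaussian_kernel_weights,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_weighting(weights):
    """KernelWeighting with prescribed normalized weights (all retained)."""
    w = np.asarray(weights, dtype=float)
    return KernelWeighting(h=1.0, raw_weights=w, retained=np.arange(w.size),
                           normalized_weights=w)


def random_instance(rng, n=30, p=5, h=None):
    """A random (y, R, weighting, design) tuple for solver tests."""
    m = rng.uniform(-1, 1, n)
    R = rng.standard_normal((n, p))
    y = R @ rng.standard_normal(p) + 0.5 * rng.standard_normal(n)
    w = gaussian_kernel_weights(m, float(m[0]), 0.8 if h is None else h)
    return y, R, w, build_weighted_design(y, R, w)


@pytest.fixture
def instance_factory(rng):
    def make(n=30, p=5, h=None):
        return random_instance(rng, n=n, p=p, h=h)
    return make
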