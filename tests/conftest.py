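import numpy as np
import pytest

from cropdet import nn


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def randomize_bn_stats(module, rng):
    """Give every batch-norm nontrivial running statistics and affine
    parameters so fusion equivalence is tested away from the identity."""
    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m._set_buffer("running_mean", rng.normal(0.0, 0.3, m.ch))
            m._set_buffer("running_var", rng.uniform(0.5, 1.5, m.ch))
            m.weight.data = rng.normal(1.0, 0.2, m.ch)
            m.bias.data = rng.normal(0.0, 0.2, m.ch)
    return module


@pytest.fixture()
def randomize_bn():
    return randomize_bn_stats
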