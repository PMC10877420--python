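import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(f, t, eps=1e-6):
    """Central finite differences of a scalar-tensor-valued callable with
    respect to tensor t (used as the independent gradient oracle)."""
    g = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = t.data[i]
        t.data[i] = orig + eps
        fp = float(f().data)
        t.data[i] = orig - eps
        fm = float(f().data)
        t.data[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
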