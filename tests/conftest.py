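import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def finite_difference(f, x, eps=1e-3):
    """Central-difference gradient of scalar f w.r.t. array x (in place)."""
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = float(x[i])
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
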