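import numpy as np
import pytest

from vesselsr.synthetic import VesselTreeParams, generate_fundus


@pytest.fixture(scope="session")
def default_fundus():
    """One default-parameter synthetic fundus (seed 0), shared read-only."""
    return generate_fundus(VesselTreeParams(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f wrt array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
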