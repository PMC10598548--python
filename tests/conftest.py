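import numpy as np
import pytest

from ecskat.dataset import Dataset
from ecskat.null_model import fit_null


def make_instance(rng, n=60, p=5, m=2, trait_type="continuous"):
    """Random small dataset + null fit for oracle checks."""
    G = rng.binomial(2, rng.uniform(0.05, 0.4, size=p), size=(n, p)).astype(float)
    while np.any(np.ptp(G, axis=0) == 0):  # avoid monomorphic columns in tiny draws
        G = rng.binomial(2, rng.uniform(0.05, 0.4, size=p), size=(n, p)).astype(float)
    X = rng.standard_normal((n, m)) if m else np.empty((n, 0))
    eta = 0.3 + (X @ rng.standard_normal(m) if m else 0.0)
    if trait_type == "continuous":
        y = eta + rng.standard_normal(n)
    else:
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        if y.sum() in (0, n):
            y[:2] = [0.0, 1.0]
    ds = Dataset(y=y, X=X, G=G, trait_type=trait_type)
    return ds, fit_null(ds)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def instance(rng):
    return make_instance(rng)
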