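import numpy as np
import pytest

from omifuse.preprocess import OmicsLayer


def make_layer(values, name="layer", patients=None, features=None,
               normalized=False, mask=None):
    """Build an OmicsLayer from a raw array with generated identifiers."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return OmicsLayer(
        name=name,
        patients=patients or [f"P{i}" for i in range(n)],
        features=features or [f"{name}_f{j}" for j in range(m)],
        values=values,
        mask=np.ones_like(values, dtype=bool) if mask is None else mask,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_layer(rng):
    """A 10-patient, 5-feature standardized random layer."""
    x = rng.normal(size=(10, 5))
    x = (x - x.mean(0)) / x.std(0)
    return make_layer(x, name="rand", normalized=True)
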