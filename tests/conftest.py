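import dataclasses

import numpy as np
import pytest

from anfisbpso import anfis
from anfisbpso.preprocessing import BINARY, CONTINUOUS, Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 samples, one binary + two continuous features, linear target."""
    b = (rng.random(20) < 0.4).astype(float)
    c1 = rng.normal(10.0, 2.0, 20)
    c2 = rng.normal(-3.0, 1.0, 20)
    y = 0.5 * b + 0.3 * c1 - 0.8 * c2 + rng.normal(0, 0.1, 20)
    return Dataset(
        X=np.column_stack([b, c1, c2]),
        y=y,
        names=("b", "c1", "c2"),
        kinds=(BINARY, CONTINUOUS, CONTINUOUS),
    )


@pytest.fixture
def toy_model():
    """2-input, 2-MF model (4 rules) with fixed nontrivial consequents."""
    model = anfis.build_model(2, anfis.AnfisConfig(n_mfs=2))
    consequent = 0.1 * np.arange(model.consequent.size, dtype=float).reshape(
        model.consequent.shape
    )
    return dataclasses.replace(model, consequent=consequent)
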