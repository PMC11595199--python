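import numpy as np
import pandas as pd
import pytest

from plperm.data_io import Dataset, DescriptorTable
from plperm.synthetic_data import generate_reference_like


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table():
    return DescriptorTable(
        ["a", "b", "c"],
        ["M_w", "TPSA"],
        np.array([[300.0, 50.0], [500.0, 100.0], [700.0, 250.0]]),
    )


@pytest.fixture
def reference_like():
    return generate_reference_like(seed=42)


@pytest.fixture
def linear_frame(rng):
    """60x5 descriptor frame with y = 1 + 2a - b + small noise."""
    X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
    y = 1.0 + 2.0 * X["a"].to_numpy() - X["b"].to_numpy() + rng.normal(0, 0.05, 60)
    return X, y


def make_dataset_from_arrays(ids, names, values, response, roles) -> Dataset:
    return Dataset(DescriptorTable(ids, names, np.asarray(values, float)),
                   np.asarray(response, float), list(roles))
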