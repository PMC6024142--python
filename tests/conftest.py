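import numpy as np
import pandas as pd
import pytest

from fullsubsets.synthetic import scenario_library


@pytest.fixture(scope="session")
def scenarios():
    return scenario_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180520)


@pytest.fixture()
def simple_gaussian_data(rng):
    """One smooth signal, one noise predictor, one 2-level factor."""
    n = 150
    x1 = rng.uniform(-2, 2, n)
    x2 = rng.normal(size=n)
    f = rng.choice(["a", "b"], n)
    y = np.sin(1.5 * x1) + 0.5 * (f == "b") + rng.normal(0, 0.3, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "f": f, "y": y})
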