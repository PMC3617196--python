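import numpy as np
import pandas as pd
import pytest

from proteopanel import QuantMatrix, SimConfig, simulate_study


@pytest.fixture
def labels_6_14():
    samples = [f"s{i:02d}" for i in range(20)]
    return pd.Series(["AR"] * 6 + ["NR"] * 14, index=samples)


@pytest.fixture
def random_matrix(labels_6_14):
    """Null 50 x 20 log2-ratio matrix, fully observed."""
    rng = np.random.default_rng(42)
    vals = pd.DataFrame(
        rng.normal(0, 0.36, size=(50, 20)),
        index=[f"g{i}" for i in range(50)],
        columns=labels_6_14.index,
    )
    return QuantMatrix(vals)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study exercising every pipeline stage."""
    return simulate_study(SimConfig(n_pgcs=120, planted=((5, 1.46), (20, -1.56)), seed=11))
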