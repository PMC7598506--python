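"""Shared fixtures for the test suite."""

import numpy as np
import pandas as pd
import pytest

from sedtemp.accelerometry import EpochStream


def make_stream(x, y=None, z=None, start="2014-03-10 00:00:00", child_id="c0001"):
    """EpochStream from raw count arrays on the 10-s grid."""
    x = np.asarray(x, dtype=int)
    n = len(x)
    y = np.zeros(n, dtype=int) if y is None else np.asarray(y, dtype=int)
    z = np.zeros(n, dtype=int) if z is None else np.asarray(z, dtype=int)
    ts = pd.date_range(start, periods=n, freq="10s")
    return EpochStream(child_id, pd.DataFrame({"timestamp": ts, "x": x, "y": y, "z": z}))


@pytest.fixture
def rng():
    return np.random.default_rng(20140310)


@pytest.fixture(scope="session")
def mixed_dataset():
    """Moderate random-intercept dataset with one linear covariate."""
    rng = np.random.default_rng(7)
    n_g, n_per = 60, 6
    g = np.repeat(np.arange(n_g), n_per)
    x = rng.normal(size=n_g * n_per)
    u = rng.normal(scale=2.0, size=n_g)
    y = 10.0 + 1.5 * x + u[g] + rng.normal(scale=1.0, size=n_g * n_per)
    return pd.DataFrame(
        {"y": y, "x": x, "child_id": [f"c{i:03d}" for i in g]}
    )
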