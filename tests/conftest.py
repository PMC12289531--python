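import numpy as np
import pytest

import turnoverkit as tk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_day_grid():
    return np.array([0.0, 1.0, 3.0, 7.0, 14.0, 21.0])


def make_series(params, times, group="PF", parent="prot", pep="pep1",
                sigma=0.0, rng=None):
    """Noisy (or exact) one-compartment series for tests."""
    mu = tk.predict_labeling(params, times)
    if sigma > 0:
        mu = np.clip(mu + sigma * rng.standard_normal(times.size), 0.0, 1.0)
    return tk.PeptideTimeCourse(pep, parent, group, times, mu)


@pytest.fixture
def series_factory():
    return make_series
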