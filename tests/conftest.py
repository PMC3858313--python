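"""Shared fixtures: simulated ISI series at reference parameter points.

Session-scoped because the integrations are the expensive part; every
test treats the fixture contents as read-only.
"""

import numpy as np
import pytest

from hrchaos import HRParams, simulate_isis

# Reference points in the (I, r) plane: the narrow chaotic window and the
# period-1 / period-2 bands that enclose it in r.
CHAOTIC_POINT = {"I": 2.53, "r": 0.0245}
PERIOD1_POINT = {"I": 2.53, "r": 0.031}
PERIOD2_POINT = {"I": 2.53, "r": 0.018}


@pytest.fixture(scope="session")
def chaotic_isis():
    return simulate_isis(HRParams(**CHAOTIC_POINT), n_isis=520, t_end=30000.0)


@pytest.fixture(scope="session")
def period1_isis():
    return simulate_isis(HRParams(**PERIOD1_POINT), n_isis=200, t_end=10000.0)


@pytest.fixture(scope="session")
def period2_isis():
    return simulate_isis(HRParams(**PERIOD2_POINT), n_isis=200, t_end=10000.0)


@pytest.fixture(scope="session")
def iid_series():
    rng = np.random.default_rng(42)
    return rng.uniform(20.0, 60.0, size=800)
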