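import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cmparams import CMSeries, TargetSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def sbp_target():
    return TargetSpec("SBP", high=140.0)


@pytest.fixture
def worked_series():
    """The 4-reading SBP series used as the hand-derived golden example."""
    return CMSeries.from_pairs("p1", "SBP", [(0, 130.0), (10, 150.0), (20, 160.0), (30, 135.0)])


def random_series(rng: np.random.Generator, patient_id="p", cm="SBP",
                  min_n=0, max_n=60) -> CMSeries:
    """A random measurement series with irregular integer visit days."""
    n = int(rng.integers(min_n, max_n + 1))
    days = np.cumsum(rng.integers(1, 90, size=n)) if n else []
    values = 130.0 + rng.normal(0.0, 18.0, size=n).round(1) if n else []
    return CMSeries.from_pairs(patient_id, cm, list(zip(days, values)))


@pytest.fixture
def series_factory():
    return random_series
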