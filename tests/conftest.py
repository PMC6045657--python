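import datetime as dt

import numpy as np
import pandas as pd
import pytest

from axenic.dams_io import BeamCountSeries

BASE_SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


def make_series(counts, fly_id="f1", group="CV", lights_on=dt.time(8, 0),
                start="2018-01-01 08:00"):
    """Beam-count series on a 1-min grid starting at lights-on by default."""
    counts = np.asarray(counts, dtype=float)
    grid = pd.date_range(start, periods=len(counts), freq="min")
    return BeamCountSeries(fly_id=fly_id, group=group, timestamps=grid,
                           counts=counts, lights_on=lights_on)


@pytest.fixture
def series_factory():
    return make_series
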