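import io

import numpy as np
import pytest

from copycatdetect import DailyCountSeries, parse_event_dates, simulate_homogeneous


@pytest.fixture
def small_calendar():
    """Three events over a fixed 10-day window."""
    csv = "date\n2017-01-03\n2017-01-03\n2017-01-07\n"
    return parse_event_dates(io.StringIO(csv),
                             window_start="2017-01-01", window_end="2017-01-10")


@pytest.fixture
def small_counts():
    return DailyCountSeries(counts=np.array([0, 0, 2, 0, 0, 0, 1, 0, 0, 0]))


@pytest.fixture
def homogeneous_series():
    """A long homogeneous daily count series at the study's overall rate."""
    return simulate_homogeneous(0.163, 4018, seed=12345)
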