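import numpy as np
import pytest

from moodews import AnalysisSegment, BeepGrid, EmaSeries, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def grid49():
    """Seven monitoring weeks at 5 beeps/day (245 slots)."""
    return BeepGrid(days=49, beeps_per_day=5)


@pytest.fixture
def control_segment():
    return AnalysisSegment("P00", "control", 0, 245)


def make_series(values, grid, patient="P00", state="cheerful"):
    return EmaSeries(patient, state, np.asarray(values, dtype=float), grid)


@pytest.fixture
def make_ema():
    return make_series
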