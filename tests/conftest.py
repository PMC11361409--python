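import numpy as np
import pandas as pd
import pytest

import classair as ca

START = pd.Timestamp("2021-06-01 00:00:00")


@pytest.fixture
def start():
    return START


@pytest.fixture
def constant_series():
    """20 min of constant value 7 at 10-s resolution, valve-switched."""
    ts = START + pd.to_timedelta(np.arange(120) * 10, unit="s")
    return ca.ConcentrationSeries(ts, np.full(120, 7.0), "total_ufp", "mixed")


@pytest.fixture
def quiet_zone():
    """Classroom-scale zone with moderate exchange and deposition."""
    return ca.ZoneConfig(volume=250.0, aer=1.0, deposition=0.5)


@pytest.fixture
def quiet_source():
    """Noise-free, plume-free outdoor driver for deterministic checks."""
    return ca.OutdoorSourceConfig(baseline=5000.0, diurnal_amplitude=0.0,
                                  plume_rate=0.0, noise_cv=0.0)


def make_series(values, channel="total_ufp", location="indoor", dt_s=10.0,
                start=START, quality=None):
    values = np.asarray(values, dtype=float)
    ts = start + pd.to_timedelta(np.arange(len(values)) * dt_s, unit="s")
    return ca.ConcentrationSeries(ts, values, channel, location, quality)
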