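import numpy as np
import pandas as pd
import pytest

from traymass import (
    ActuatorSchedule,
    GrowthModel,
    SimConfig,
    TempProfile,
    TraySeries,
)

ZERO_COEFFS = ((0.0, 0.0),) * 4


@pytest.fixture
def steady_config():
    """Constant-load tray: 20 plants' substrate, no growth, no disturbances."""
    return SimConfig(
        seed=1234,
        duration_days=1.0,
        growth=GrowthModel(asymptote_g=0.0),
        temp_profile=TempProfile(amplitude_c=0.0),
        temp_coeffs=ZERO_COEFFS,
        actuator=None,
        noise_sigma_g=0.0,
        spike_rate_per_day=0.0,
        harvest_events=(),
    )


@pytest.fixture
def calibration_config():
    """Temperature-calibration run: constant mass over the diurnal cycle."""
    return SimConfig(
        seed=1234,
        duration_days=1.0,
        growth=GrowthModel(asymptote_g=0.0),
        actuator=None,
        harvest_events=(),
    )


def make_series(
    cells,
    temperature=None,
    actuators=None,
    interval_s=15.0,
    mask=None,
):
    """Build a TraySeries from raw arrays on a 15 s grid."""
    cells = np.asarray(cells, dtype=float)
    n = len(cells)
    index = pd.Timestamp("2025-01-01T00:00:00Z") + pd.to_timedelta(
        np.arange(n) * interval_s, unit="s"
    )
    if temperature is None:
        temperature = np.full(n, 20.0)
    return TraySeries(
        index=index,
        cells=cells,
        temperature=np.asarray(temperature, dtype=float),
        actuators=actuators or {},
        mask=mask,
    )


def hampel_oracle(x, window, threshold=3.0):
    """Brute-force rolling median/MAD reference for the Hampel filter."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window % 2 == 0:
        window += 1
    half = window // 2
    out = x.copy()
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        win = x[max(0, i - half): i + half + 1]
        med = np.median(win)
        mad = np.median(np.abs(win - med))
        if abs(x[i] - med) > threshold * 1.4826 * mad:
            out[i] = med
            flags[i] = True
    return out, flags
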