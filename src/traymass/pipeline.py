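"""Signal-conditioning pipeline: raw cell readings -> clean tray mass.

Stage order is fixed: Hampel outlier rejection per cell, linear temperature
correction per cell, summation to tray mass M_T, actuator-shift correction
to M_u, and 4th-order Butterworth low-pass filtering to M_f. Intermediate
series are all retained in the returned :class:`BiomassSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .calibrate import ActuatorModel, TempCalibration
from .errors import CalibrationError, InvalidSpecError
from .series import N_CELLS, BiomassSeries, TraySeries

#: Gaussian-consistency factor for the median absolute deviation.
MAD_SCALE = 1.4826

#: Default outlier-rejection window: 150 s of 15 s samples, centred.
DEFAULT_HAMPEL_WINDOW = 11
DEFAULT_HAMPEL_THRESHOLD = 3.0


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design: order, cutoff (1/min), and mode.

    ``zero-phase`` applies the filter forward-backward (no lag on slow
    trends, magnitude response squared); ``causal`` applies it once with
    the filter's group delay. Default: order 4, cutoff 0.025 /min (a 40 min
    time constant), zero-phase.
    """

    order: int = 4
    cutoff_per_min: float = 0.025
    mode: str = "zero-phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidSpecError("filter order must be >= 1")
        if self.cutoff_per_min <= 0:
            raise InvalidSpecError("cutoff must be positive")
        if self.mode not in ("zero-phase", "causal"):
            raise InvalidSpecError("mode must be 'zero-phase' or 'causal'")

    def design(self, interval_s: float):
        """(b, a) coefficients for a grid with the given sample interval."""
        nyquist = 60.0 / interval_s / 2.0  # 1/min
        if self.cutoff_per_min >= nyquist:
            raise InvalidSpecError(
                f"cutoff {self.cutoff_per_min}/min >= Nyquist {nyquist}/min"
            )
        return signal.butter(self.order, self.cutoff_per_min / nyquist)


def hampel_clean(
    series: np.ndarray,
    window: int = DEFAULT_HAMPEL_WINDOW,
    threshold: float = DEFAULT_HAMPEL_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Hampel filter: replace rolling-median outliers, return flags.

    A sample deviating from the centred rolling median by more than
    ``threshold`` times the scaled median absolute deviation (MAD x 1.4826)
    of its window is replaced by that median. Windows are truncated at the
    series edges rather than padded.

    Returns ``(cleaned, flags)`` with ``flags[i]`` True where sample i was
    replaced.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if window < 3:
        raise InvalidSpecError("hampel window must span at least 3 samples")
    if window % 2 == 0:
        window += 1  # centred window needs odd length
    half = window // 2

    med = np.empty(n)
    mad = np.empty(n)
    if n >= window:
        from numpy.lib.stride_tricks import sliding_window_view

        views = sliding_window_view(x, window)
        core_med = np.median(views, axis=1)
        core_mad = np.median(np.abs(views - core_med[:, None]), axis=1)
        med[half:n - half] = core_med
        mad[half:n - half] = core_mad
        edge_idx = list(range(half)) + list(range(n - half, n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        win = x[max(0, i - half): i + half + 1]
        med[i] = np.median(win)
        mad[i] = np.median(np.abs(win - med[i]))

    flags = np.abs(x - med) > threshold * MAD_SCALE * mad
    cleaned = np.where(flags, med, x)
    return cleaned, flags


def temperature_correct(
    reading: np.ndarray,
    temperature: np.ndarray,
    calib: TempCalibration | None,
) -> np.ndarray:
    """Remove the modelled drift: S_T = S - (c_T (T - T0) + c_T0)."""
    if calib is None:
        raise CalibrationError("no temperature calibration for this cell")
    return np.asarray(reading, dtype=float) - calib.drift(temperature)


def tray_mass(corrected_cells: np.ndarray) -> np.ndarray:
    """Tray mass M_T: sum of the four temperature-corrected cell outputs."""
    cells = np.asarray(corrected_cells, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != N_CELLS:
        raise InvalidSpecError(f"expected an (n, {N_CELLS}) array of cell series")
    return cells.sum(axis=1)


def correlation(mass: np.ndarray, u: np.ndarray) -> float:
    """Pearson correlation between the mass series and an actuator state."""
    mass = np.asarray(mass, dtype=float)
    u = np.asarray(u, dtype=float)
    if len(mass) != len(u):
        raise InvalidSpecError("series must have equal length")
    if np.ptp(mass) == 0 or np.ptp(u) == 0:
        raise CalibrationError("correlation undefined for a zero-variance input")
    return float(np.corrcoef(mass, u)[0, 1])


def actuator_correct(mass: np.ndarray, u: np.ndarray, delta: float) -> np.ndarray:
    """Remove the actuator shift: M_u = M_T - delta * u.

    With a negative delta (readings biased low while the actuator runs)
    the corrected mass is larger during active intervals.
    """
    return np.asarray(mass, dtype=float) - delta * np.asarray(u, dtype=float)


def actuator_correct_piecewise(
    mass: pd.Series, u: np.ndarray, models: list[ActuatorModel]
) -> np.ndarray:
    """Apply a sequence of re-estimated deltas, each from its window end on.

    Samples before the first estimate use that first estimate (the offline
    convention); afterwards the most recent model governs.
    """
    if not models:
        return mass.to_numpy().copy()
    out = mass.to_numpy().astype(float).copy()
    deltas = np.full(len(mass), models[0].delta)
    for m in models:
        if m.estimated_at is not None:
            deltas[np.asarray(mass.index > m.estimated_at)] = m.delta
    return out - deltas * np.asarray(u, dtype=float)


def lowpass(mass: np.ndarray, spec: FilterSpec, interval_s: float) -> np.ndarray:
    """Low-pass filter the tray mass on a uniform grid.

    Zero-phase mode runs the Butterworth design forward and backward
    (squared magnitude, no phase lag); causal mode is a single streaming
    pass. DC gain is exactly 1 in both.
    """
    mass = np.asarray(mass, dtype=float)
    b, a = spec.design(interval_s)
    if spec.mode == "zero-phase":
        padlen = min(len(mass) - 1, 3 * (max(len(a), len(b)) - 1))
        return signal.filtfilt(b, a, mass, padlen=padlen)
    zi = signal.lfilter_zi(b, a) * mass[0]  # settle at the initial level
    out, _ = signal.lfilter(b, a, mass, zi=zi)
    return out


def lowpass_segmented(
    mass: np.ndarray,
    spec: FilterSpec,
    interval_s: float,
    break_indices: list[int] | None = None,
) -> np.ndarray:
    """Low-pass filter piecewise between known step discontinuities.

    A zero-phase filter smears a step (e.g. a harvest drop) symmetrically
    into the past; filtering each inter-event segment independently keeps
    the mass just before an event untouched by it. ``break_indices`` are
    the first samples of new segments.
    """
    mass = np.asarray(mass, dtype=float)
    bounds = sorted({0, len(mass), *(break_indices or [])})
    out = np.empty_like(mass)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 2:
            out[lo:hi] = mass[lo:hi]
        else:
            out[lo:hi] = lowpass(mass[lo:hi], spec, interval_s)
    return out


def run_pipeline(
    series: TraySeries,
    temp_calibs: dict[int, TempCalibration],
    actuator_models: dict[str, ActuatorModel | list[ActuatorModel]] | None = None,
    filter_spec: FilterSpec | None = None,
    hampel_window: int = DEFAULT_HAMPEL_WINDOW,
    hampel_threshold: float = DEFAULT_HAMPEL_THRESHOLD,
) -> tuple[BiomassSeries, dict]:
    """Full conditioning chain on one tray recording.

    Applies, in order: Hampel per cell, temperature correction per cell,
    summation, actuator correction per recorded actuator (a single model
    or a list of re-estimated models applied piecewise), and the low-pass
    filter. With no actuator models, M_u = M_T. Returns the
    :class:`BiomassSeries` plus a stage-summary dict.
    """
    filter_spec = filter_spec or FilterSpec()
    n = len(series)
    cleaned = np.empty_like(series.cells)
    n_flagged = 0
    for i in range(N_CELLS):
        cleaned[:, i], flags = hampel_clean(
            series.cells[:, i], hampel_window, hampel_threshold
        )
        n_flagged += int(flags.sum())

    corrected = np.empty_like(cleaned)
    for i in range(N_CELLS):
        if i not in temp_calibs:
            raise CalibrationError(f"missing temperature calibration for cell {i}")
        corrected[:, i] = temperature_correct(
            cleaned[:, i], series.temperature, temp_calibs[i]
        )

    m_raw = tray_mass(cleaned)
    m_temp = tray_mass(corrected)

    m_act = m_temp.copy()
    act_summary = {}
    for name, model in (actuator_models or {}).items():
        if name not in series.actuators:
            raise CalibrationError(f"actuator channel '{name}' absent from series")
        u = series.actuators[name]
        if isinstance(model, list):
            m_act = actuator_correct_piecewise(
                pd.Series(m_act, index=series.index), u, model
            )
            act_summary[name] = {"deltas": [m.delta for m in model]}
        else:
            m_act = actuator_correct(m_act, u, model.delta)
            act_summary[name] = {"deltas": [model.delta]}

    m_filt = lowpass(m_act, filter_spec, series.interval_s)

    report = {
        "samples": n,
        "outliers_flagged": n_flagged,
        "temperature": {
            i: {"c_t": c.c_t, "c_t0": c.c_t0, "r_squared": c.r_squared}
            for i, c in temp_calibs.items()
        },
        "actuators": act_summary,
        "filter": {
            "order": filter_spec.order,
            "cutoff_per_min": filter_spec.cutoff_per_min,
            "mode": filter_spec.mode,
        },
    }
    biomass = BiomassSeries(
        index=series.index,
        m_raw=m_raw,
        m_temp=m_temp,
        m_act=m_act,
        m_filt=m_filt,
        mask=series.mask.copy(),
    )
    return biomass, report
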