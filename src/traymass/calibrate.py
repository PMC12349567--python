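"""Estimation of all correction parameters for a load-cell tray.

Covers the one-time span calibration against a known reference mass, the
per-setup zero (tare) offsets, the per-cell linear temperature-drift model
S = load + c_T (T - T0) + c_T0 fitted by ordinary least squares, and the
actuator disturbance delta estimated as the mean contrast between active
and inactive samples — including its regular re-estimation during
operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError
from .series import N_CELLS, TraySeries

log = logging.getLogger(__name__)

#: Samples this close to an actuator on/off edge are excluded from the
#: state-contrast means, to keep mechanical transients out of the estimate.
EDGE_GUARD_SAMPLES = 2


@dataclass(frozen=True)
class SpanCalibration:
    """Conversion from raw digitizer units to grams for one cell."""

    cell_id: int
    factor: float  # g per raw unit
    tare_offset: float  # raw units
    reference_mass: float  # g

    def convert(self, raw) -> float:
        """Raw reading -> grams."""
        return (np.asarray(raw, dtype=float) - self.tare_offset) * self.factor


@dataclass(frozen=True)
class TempCalibration:
    """Per-cell linear temperature-drift model.

    ``c_t`` (g/degC) and ``c_t0`` (g) parameterize the additive drift
    c_t * (T - t0) + c_t0 relative to the reference temperature ``t0`` at
    zero calibration. Standard errors are the closed-form OLS ones.
    """

    cell_id: int
    c_t: float
    c_t0: float
    t0: float
    r_squared: float
    c_t_stderr: float = float("nan")
    c_t0_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise CalibrationError("r_squared must lie in [0, 1]")

    def drift(self, temperature) -> np.ndarray:
        """Predicted additive drift (g) at the given temperature(s)."""
        return self.c_t * (np.asarray(temperature, dtype=float) - self.t0) + self.c_t0


@dataclass(frozen=True)
class ActuatorModel:
    """Estimated additive shift of the tray reading while an actuator runs."""

    actuator_id: str
    delta: float  # g
    rho_before: float
    rho_after: float
    estimated_at: pd.Timestamp | None = None
    window: pd.Timedelta | None = None

    def __post_init__(self) -> None:
        for rho in (self.rho_before, self.rho_after):
            if np.isfinite(rho) and not (-1.0 - 1e-9 <= rho <= 1.0 + 1e-9):
                raise CalibrationError("correlation coefficients must lie in [-1, 1]")
        if (
            np.isfinite(self.rho_before)
            and np.isfinite(self.rho_after)
            and abs(self.rho_after) > abs(self.rho_before)
        ):
            log.warning(
                "actuator '%s': |rho| increased after compensation (%.3f -> %.3f)",
                self.actuator_id, self.rho_before, self.rho_after,
            )


def fit_span(
    known_mass: float,
    raw_reading_loaded: float,
    raw_reading_empty: float,
    cell_id: int = 0,
) -> SpanCalibration:
    """Span calibration from one known reference mass.

    The factor converts the raw digitizer difference between the loaded and
    empty cell into grams; the reference should sit near half the cell's
    rated payload for best linearity.
    """
    diff = raw_reading_loaded - raw_reading_empty
    if diff == 0 or known_mass == 0:
        raise CalibrationError(
            "degenerate span calibration: zero reading difference or zero mass"
        )
    return SpanCalibration(
        cell_id=cell_id,
        factor=known_mass / diff,
        tare_offset=raw_reading_empty,
        reference_mass=known_mass,
    )


def tare(series: TraySeries, window: pd.Timedelta | None = None) -> np.ndarray:
    """Per-cell zero offsets (g): mean reading over an empty-tray window.

    ``window`` selects the leading portion of the series; None uses it all.
    Subtracting the returned offsets makes the empty-tray mean zero.
    """
    if window is None:
        sel = np.ones(len(series), dtype=bool)
    else:
        sel = np.asarray(series.index <= series.index[0] + window)
    if not sel.any():
        raise CalibrationError("tare window contains no samples")
    return series.cells[sel].mean(axis=0)


def fit_temperature_model(
    series: TraySeries,
    cell: int,
    t0: float,
    reference_mass: float | None = None,
) -> TempCalibration:
    """OLS fit of one cell's drift against (T - t0) under constant true load.

    Regresses the cell reading on the centred temperature; the slope is
    c_T. The intercept equals true load + c_T0, so the static offset c_T0
    is only identifiable when ``reference_mass`` (the known constant load
    on the cell, in grams) is supplied; otherwise c_T0 is reported as 0 and
    the offset is left to be absorbed downstream by the substrate-mass
    initialization.
    """
    if not 0 <= cell < N_CELLS:
        raise CalibrationError(f"cell must be in 0..{N_CELLS - 1}")
    x = series.temperature - t0
    y = series.cells[:, cell]
    if np.ptp(x) == 0:
        raise CalibrationError(
            "temperature channel is constant: drift model unidentifiable"
        )
    fit = stats.linregress(x, y)
    c_t0 = fit.intercept - reference_mass if reference_mass is not None else 0.0
    return TempCalibration(
        cell_id=cell,
        c_t=fit.slope,
        c_t0=c_t0,
        t0=t0,
        r_squared=fit.rvalue**2,
        c_t_stderr=fit.stderr,
        c_t0_stderr=fit.intercept_stderr,
    )


def _state_means(mass: np.ndarray, u: np.ndarray, edge_guard: int):
    u = np.asarray(u)
    keep = np.ones(len(u), dtype=bool)
    if edge_guard > 0 and len(u) > 1:
        edges = np.flatnonzero(np.diff(u) != 0)
        for e in edges:
            lo = max(0, e - edge_guard + 1)
            hi = min(len(u), e + edge_guard + 1)
            keep[lo:hi] = False
    on = keep & (u == 1)
    off = keep & (u == 0)
    if not on.any() or not off.any():
        return None
    return float(mass[on].mean()), float(mass[off].mean())


def estimate_actuator_delta(
    mass: np.ndarray,
    u: np.ndarray,
    edge_guard: int = EDGE_GUARD_SAMPLES,
) -> float:
    """Actuator shift delta (g): mean(mass | u=1) - mean(mass | u=0).

    Samples within ``edge_guard`` samples of a state transition are excluded
    so switch-on transients do not bias the contrast.
    """
    mass = np.asarray(mass, dtype=float)
    means = _state_means(mass, u, edge_guard)
    if means is None:
        raise CalibrationError(
            "actuator delta unidentifiable: need samples in both states"
        )
    on_mean, off_mean = means
    return on_mean - off_mean


def reestimate_delta(
    mass: pd.Series,
    u: pd.Series,
    cadence: pd.Timedelta = pd.Timedelta(hours=24),
    actuator_id: str = "actuator",
    edge_guard: int = EDGE_GUARD_SAMPLES,
) -> list[ActuatorModel]:
    """Rolling re-estimation of the actuator delta at a fixed cadence.

    The series is cut into consecutive ``cadence`` windows; each yields one
    :class:`ActuatorModel` stamped at the window end, whose delta governs
    the correction of subsequent data. A window with only one actuator
    state retains the previous delta (logged, not fatal). Correlations
    before/after use the windowed mass.
    """
    if mass.index[-1] - mass.index[0] < cadence:
        raise CalibrationError("series shorter than the re-estimation cadence")
    models: list[ActuatorModel] = []
    prev_delta: float | None = None
    start = mass.index[0]
    n_windows = int(np.ceil((mass.index[-1] - start) / cadence))
    for k in range(n_windows):
        lo, hi = start + k * cadence, start + (k + 1) * cadence
        sel = (mass.index >= lo) & (mass.index < hi)
        if not sel.any():
            continue
        m_win = mass.to_numpy()[sel]
        u_win = u.to_numpy()[sel]
        means = _state_means(m_win, u_win, edge_guard)
        if means is None:
            if prev_delta is None:
                log.warning("window %d: single-state, no previous delta; skipped", k)
                continue
            log.warning("window %d: single-state, retaining delta %.3f g", k, prev_delta)
            delta = prev_delta
        else:
            delta = means[0] - means[1]
        rho_before = _safe_corr(m_win, u_win)
        rho_after = _safe_corr(m_win - delta * u_win, u_win)
        models.append(
            ActuatorModel(
                actuator_id=actuator_id,
                delta=delta,
                rho_before=rho_before,
                rho_after=rho_after,
                estimated_at=mass.index[sel][-1],
                window=cadence,
            )
        )
        prev_delta = delta
    return models


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
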