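"""Per-plant biomass accounting from the clean tray-mass series.

Turns the filtered tray mass M_f into an average fresh mass per plant,
m_lc = (M_f - n m_sub) / n, by subtracting the wet-substrate share of the
current plant count n(t) kept in a plant-event ledger. Also provides the
adjustment of manual whole-pot measurements to leaf mass, the sensor
accuracy/resolution arithmetic, harvest error metrics and a generic
regression evaluator of sensor versus manual mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LedgerError
from .series import BiomassSeries

EVENT_KINDS = ("harvest", "thinning", "transplant")


@dataclass(frozen=True)
class LedgerEvent:
    timestamp: pd.Timestamp
    plants_removed: int
    kind: str = "harvest"

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise LedgerError(f"unknown event kind '{self.kind}'")


@dataclass
class PlantLedger:
    """Time-indexed plant count with substrate and basket bookkeeping.

    ``n0`` plants are present at the trial start; each event removes
    ``plants_removed`` plants (and their wet rockwool plugs, ``m_sub`` g
    each) from the tray. ``m_basket`` is the net-pot mass that appears in
    manual whole-pot measurements but is part of the tray tare otherwise.
    """

    n0: int
    m_sub: float | None = None  # g per plant, wet
    m_basket: float = 0.0  # g
    events: list[LedgerEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)
        count = self.n0
        for ev in self.events:
            count -= ev.plants_removed
            if count < 0:
                raise LedgerError(
                    f"event at {ev.timestamp} drives the plant count negative"
                )

    def count(self, t: pd.Timestamp) -> int:
        """Plant count n(t): n0 minus removals at or before t."""
        count = self.n0
        for ev in self.events:
            if ev.timestamp <= t:
                count -= ev.plants_removed
        return count


@dataclass(frozen=True)
class HarvestRecord:
    """Destructive reference measurement of one harvested plant."""

    plant_id: str
    day: float
    m_man: float  # whole measurement incl. substrate + basket, g
    m_leaf: float  # wet leaf (shoot) mass, g
    m_root: float  # wet root mass, g
    m_dry: float | None = None  # dry leaf mass, g

    def __post_init__(self) -> None:
        if self.m_leaf < 0 or self.m_root < 0:
            raise LedgerError("leaf and root masses must be non-negative")
        if self.m_dry is not None and self.m_dry > self.m_leaf:
            raise LedgerError("dry leaf mass cannot exceed wet leaf mass")


@dataclass(frozen=True)
class AdjustmentFactors:
    """Factors turning a whole-pot manual measurement into leaf mass.

    ``c_man`` is the leaf share of total plant mass; ``c_sample`` the ratio
    of the harvested sample's net plant mass to the destructively measured
    leaf+root mass (corrects for the sample not representing the tray).
    """

    c_man: float
    c_sample: float

    def __post_init__(self) -> None:
        for name in ("c_man", "c_sample"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise LedgerError(f"{name} must lie in (0, 1], got {v}")


def init_substrate_mass(m_filt_at_start: float, n0: int) -> float:
    """Average wet-substrate mass per plant at transplant: M_f(start) / n0.

    Valid while seedling mass is negligible against the wet plug.
    """
    if n0 <= 0:
        raise LedgerError("initial plant count must be positive")
    return m_filt_at_start / n0


def ledger_count(ledger: PlantLedger, t: pd.Timestamp) -> int:
    """Plant count at time t (delegates to :meth:`PlantLedger.count`)."""
    return ledger.count(t)


def mass_per_plant(m_filt: float, ledger: PlantLedger, t: pd.Timestamp) -> float:
    """Average per-plant fresh mass m_lc = (M_f - n m_sub) / n at time t."""
    n = ledger.count(t)
    if n <= 0:
        raise LedgerError("no plants on the tray at the requested time")
    if ledger.m_sub is None:
        raise LedgerError("substrate mass per plant not initialized")
    return (m_filt - n * ledger.m_sub) / n


def mass_at(
    biomass: BiomassSeries,
    t: pd.Timestamp,
    pre_window: pd.Timedelta = pd.Timedelta(minutes=10),
) -> float:
    """Filtered tray mass read just before ``t``, averaged over ``pre_window``.

    Harvest epochs are step disturbances the low-pass filter smears; the
    value immediately before the event, averaged over a short window, is
    the mass the event acted on.
    """
    sel = np.asarray((biomass.index <= t) & (biomass.index > t - pre_window))
    if not sel.any():
        raise LedgerError("no samples in the pre-event window")
    return float(biomass.m_filt[sel].mean())


def compute_adjustment_factors(
    harvests: list[HarvestRecord],
    manual_at_harvest: float,
    ledger: PlantLedger,
) -> AdjustmentFactors:
    """Fit c_man and c_sample from destructive harvest measurements.

    c_man = mean(m_leaf) / (mean(m_leaf) + mean(m_root));
    c_sample = (mean(m_man) - m_sub - m_basket) / (mean(m_leaf) + mean(m_root)),
    where ``manual_at_harvest`` is the mean whole-pot manual measurement at
    the harvest epoch.
    """
    if not harvests:
        raise LedgerError("need at least one harvest record")
    if ledger.m_sub is None:
        raise LedgerError("substrate mass per plant not initialized")
    leaf = float(np.mean([h.m_leaf for h in harvests]))
    root = float(np.mean([h.m_root for h in harvests]))
    total = leaf + root
    if total == 0:
        raise LedgerError("zero total plant mass in harvest records")
    c_man = leaf / total
    c_sample = (manual_at_harvest - ledger.m_sub - ledger.m_basket) / total
    return AdjustmentFactors(c_man=c_man, c_sample=c_sample)


def adjust_manual(
    m_man: float, factors: AdjustmentFactors, ledger: PlantLedger
) -> float:
    """Adjusted manual leaf mass: (c_man / c_sample) (m_man - m_sub - m_basket)."""
    if factors.c_sample == 0:
        raise LedgerError("c_sample must be non-zero")
    if ledger.m_sub is None:
        raise LedgerError("substrate mass per plant not initialized")
    return factors.c_man / factors.c_sample * (m_man - ledger.m_sub - ledger.m_basket)


def sensor_accuracy(
    full_scale: float, accuracy_pct: float, n_cells: int = 4
) -> tuple[float, float]:
    """(per-cell, tray) absolute accuracy in grams.

    Per cell: full scale x accuracy percentage. The tray figure is the
    worst-case sum over the cells, e.g. four 5 kg cells at +-0.02% give
    +-1 g each and +-4 g for the tray.
    """
    if full_scale < 0 or accuracy_pct < 0 or n_cells < 1:
        raise LedgerError("accuracy arithmetic needs non-negative inputs")
    per_cell = full_scale * accuracy_pct / 100.0
    return per_cell, n_cells * per_cell


def per_plant_resolution(tray_accuracy: float, n: int) -> float:
    """Smallest detectable per-plant mass change: tray accuracy / n plants."""
    if n <= 0:
        raise LedgerError("plant count must be positive")
    return tray_accuracy / n


def harvest_error(m_lc_at_harvest: float, m_leaf_mean: float) -> tuple[float, float]:
    """(absolute g, relative %) error of the sensor against mean leaf mass."""
    abs_err = abs(m_lc_at_harvest - m_leaf_mean)
    if m_leaf_mean == 0:
        raise LedgerError("relative error undefined for zero reference mass")
    return abs_err, 100.0 * abs_err / m_leaf_mean


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    mae: float  # g, mean |residual| of the fit
    rmse: float  # g
    n: int


def evaluate_regression(sensor, reference) -> RegressionResult:
    """OLS of manual reference mass on sensor mass, with fit diagnostics.

    Perfect sensing gives slope 1, intercept 0, R^2 = 1; MAE/RMSE are the
    residual errors of the fitted line in grams.
    """
    x = np.asarray(sensor, dtype=float)
    y = np.asarray(reference, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise LedgerError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise LedgerError("degenerate regression: constant sensor values")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(x),
    )
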