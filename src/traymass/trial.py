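"""End-to-end trial orchestration: calibrate -> process -> evaluate.

Mirrors the four-phase operation of the tray sensor: after installation
(span + tare, assumed done upstream of the gram-scale streams), each trial
runs an initialization (substrate-mass estimate), a calibration phase on
the first day/night cycle (temperature coefficients, initial actuator
delta) and continuous operation with regular re-estimation of the actuator
delta. The evaluation phase compares the per-plant sensor mass against
ground truth or harvest references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import (
    PlantLedger,
    LedgerEvent,
    init_substrate_mass,
    mass_at,
    mass_per_plant,
)
from .calibrate import (
    TempCalibration,
    fit_temperature_model,
    reestimate_delta,
)
from .errors import CalibrationError
from .pipeline import (
    FilterSpec,
    actuator_correct_piecewise,
    correlation,
    hampel_clean,
    lowpass_segmented,
    run_pipeline,
)
from .series import N_CELLS, BiomassSeries, TraySeries
from .simulate import GroundTruth, SimConfig, simulate_tray

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialConfig:
    """Knobs of a full trial run (sampling comes from the input series)."""

    hampel_window: int = 11
    hampel_threshold: float = 3.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    calibration_window: pd.Timedelta = pd.Timedelta(hours=24)
    reestimate_cadence: pd.Timedelta = pd.Timedelta(hours=24)
    init_window: pd.Timedelta = pd.Timedelta(hours=1)
    pre_event_window: pd.Timedelta = pd.Timedelta(minutes=10)


@dataclass
class RunReport:
    """Stage summaries and evaluation metrics of one trial run."""

    stages: dict
    metrics: dict

    def to_dict(self) -> dict:
        return {"stages": self.stages, "metrics": self.metrics}


def calibrate_trial(
    series: TraySeries,
    config: TrialConfig = TrialConfig(),
    t0: float | None = None,
) -> dict[int, TempCalibration]:
    """Fit per-cell temperature models on the first day/night cycle.

    ``t0`` defaults to the temperature at the first sample (the zero
    calibration reference). The static offset c_T0 is unidentifiable while
    plants sit on the tray and is absorbed by the substrate initialization.
    """
    sel = np.asarray(series.index <= series.index[0] + config.calibration_window)
    if sel.sum() < 10:
        raise CalibrationError("calibration window too short")
    cleaned = np.column_stack(
        [
            hampel_clean(series.cells[sel, i], config.hampel_window,
                         config.hampel_threshold)[0]
            for i in range(N_CELLS)
        ]
    )
    window = TraySeries(
        index=series.index[sel],
        cells=cleaned,
        temperature=series.temperature[sel],
        actuators={k: v[sel] for k, v in series.actuators.items()},
        mask=series.mask[sel],
    )
    if t0 is None:
        t0 = float(series.temperature[0])
    return {
        i: fit_temperature_model(window, i, t0) for i in range(N_CELLS)
    }


def process_trial(
    series: TraySeries,
    temp_calibs: dict[int, TempCalibration],
    config: TrialConfig = TrialConfig(),
    event_times: list[pd.Timestamp] | None = None,
) -> tuple[BiomassSeries, dict]:
    """Condition a whole trial with regularly re-estimated actuator deltas.

    ``event_times`` lists known step disturbances (harvests); the low-pass
    filter runs independently on each inter-event segment so a step never
    bleeds into the mass read just before it.
    """
    biomass, stages = run_pipeline(
        series,
        temp_calibs,
        actuator_models=None,
        filter_spec=config.filter,
        hampel_window=config.hampel_window,
        hampel_threshold=config.hampel_threshold,
    )
    m_act = biomass.m_temp.copy()
    for name, u in series.actuators.items():
        models = reestimate_delta(
            pd.Series(biomass.m_temp, index=series.index),
            pd.Series(u, index=series.index),
            cadence=config.reestimate_cadence,
            actuator_id=name,
        )
        m_act = actuator_correct_piecewise(
            pd.Series(m_act, index=series.index), u, models
        )
        stages["actuators"][name] = {
            "deltas": [m.delta for m in models],
            "rho_before": [m.rho_before for m in models],
            "rho_after": [m.rho_after for m in models],
        }
    if not series.actuators:
        log.warning("no actuator channels recorded; actuator correction skipped")
    breaks = [
        int(np.searchsorted(series.index, t)) for t in (event_times or [])
    ]
    m_filt = lowpass_segmented(m_act, config.filter, series.interval_s, breaks)
    biomass = BiomassSeries(
        index=biomass.index,
        m_raw=biomass.m_raw,
        m_temp=biomass.m_temp,
        m_act=m_act,
        m_filt=m_filt,
        mask=biomass.mask,
    )
    # overall compensation quality across the full trial
    for name, u in series.actuators.items():
        try:
            stages["actuators"][name]["rho_overall_before"] = correlation(
                biomass.m_temp, u
            )
            stages["actuators"][name]["rho_overall_after"] = correlation(
                biomass.m_act, u
            )
        except CalibrationError:
            pass
    return biomass, stages


def evaluate_trial(
    biomass: BiomassSeries,
    ledger: PlantLedger,
    config: TrialConfig = TrialConfig(),
    truth: GroundTruth | None = None,
) -> dict:
    """Per-plant masses at every ledger event plus ground-truth errors."""
    if ledger.m_sub is None:
        sel = np.asarray(biomass.index <= biomass.index[0] + config.init_window)
        ledger.m_sub = init_substrate_mass(
            float(biomass.m_filt[sel].mean()), ledger.n0
        )
    metrics: dict = {"m_sub_g": ledger.m_sub, "events": []}
    epochs = [ev.timestamp for ev in ledger.events]
    epochs.append(biomass.index[-1])  # end-of-trial harvest epoch
    for t in epochs:
        just_before = t - pd.Timedelta(seconds=1)
        n_before = ledger.count(just_before)
        if n_before <= 0:
            continue
        m_f = mass_at(biomass, just_before, config.pre_event_window)
        m_lc = mass_per_plant(m_f, ledger, just_before)
        entry = {
            "timestamp": pd.Timestamp(t).isoformat(),
            "n_plants": n_before,
            "m_filt_g": m_f,
            "m_lc_g": m_lc,
        }
        if truth is not None:
            sel = np.asarray(truth.index <= just_before)
            if sel.any():
                true_m = float(truth.per_plant_mass[sel][-1])
                entry["true_per_plant_g"] = true_m
                entry["abs_error_g"] = abs(m_lc - true_m)
        metrics["events"].append(entry)
    return metrics


def run_trial(
    sim_config: SimConfig,
    config: TrialConfig = TrialConfig(),
) -> tuple[BiomassSeries, RunReport, TraySeries, GroundTruth]:
    """Simulate one trial and run the full calibrate/process/evaluate chain.

    Deterministic given ``sim_config.seed``.
    """
    series, truth = simulate_tray(sim_config)
    temp_calibs = calibrate_trial(series, config)
    event_times = [
        sim_config.start + pd.Timedelta(days=day)
        for day, _ in sim_config.harvest_events
    ]
    biomass, stages = process_trial(series, temp_calibs, config, event_times)
    ledger = PlantLedger(
        n0=sim_config.n_plants_initial,
        events=[
            LedgerEvent(
                timestamp=sim_config.start + pd.Timedelta(days=day),
                plants_removed=removed,
                kind="harvest",
            )
            for day, removed in sim_config.harvest_events
        ],
    )
    metrics = evaluate_trial(biomass, ledger, config, truth=truth)
    stages["temperature_true"] = {
        i: {"c_t": sim_config.temp_coeffs[i][0], "c_t0": sim_config.temp_coeffs[i][1]}
        for i in range(N_CELLS)
    }
    return biomass, RunReport(stages=stages, metrics=metrics), series, truth
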