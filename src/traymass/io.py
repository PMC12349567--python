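"""File interfaces: CSV time series, JSON calibration sidecars, YAML configs.

CSV dialect: comma-separated, ``.`` decimal, ISO-8601 UTC timestamps,
mandatory header row. Tray streams carry columns ``timestamp``,
``s1_g``..``s4_g``, ``temp_c`` and one ``act_<name>`` 0/1 column per
actuator. Short recording gaps (< 5 min) are filled by linear
interpolation and flagged invalid in the mask; longer gaps raise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import ActuatorModel, SpanCalibration, TempCalibration
from .errors import SeriesFormatError
from .biomass import HarvestRecord, LedgerEvent, PlantLedger
from .series import BiomassSeries, TraySeries
from .simulate import GroundTruth, SimConfig, config_from_dict, config_to_dict

MAX_INTERP_GAP = pd.Timedelta(minutes=5)


# ---------------------------------------------------------------- tray CSV

def write_tray_csv(series: TraySeries, path: str | Path) -> None:
    frame = series.to_frame()
    frame.index = frame.index.strftime("%Y-%m-%dT%H:%M:%S%z")
    frame.to_csv(path, float_format="%.10g")


def read_tray_csv(path: str | Path) -> TraySeries:
    """Read and validate a tray stream; interpolate sub-5-min gaps.

    Malformed rows are reported with their file line number (header =
    line 1). Duplicated or non-monotone timestamps are format errors; a
    grid gap longer than one sample but at most 5 min is filled by linear
    interpolation with the filled samples flagged False in the mask.
    """
    frame = pd.read_csv(path)
    if "timestamp" not in frame.columns:
        raise SeriesFormatError(f"{path}: missing mandatory column 'timestamp'")
    try:
        ts = pd.to_datetime(frame["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SeriesFormatError(f"{path}: unparseable timestamp ({exc})") from exc
    dup = ts.duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # +1 header, +1 one-based
        raise SeriesFormatError(f"{path}: duplicated timestamp at line {line}")
    if not ts.is_monotonic_increasing:
        line = int(np.flatnonzero(ts.diff().dt.total_seconds() < 0)[0]) + 2
        raise SeriesFormatError(f"{path}: non-monotone timestamp at line {line}")
    frame = frame.set_index(pd.DatetimeIndex(ts))
    frame = frame.drop(columns=["timestamp"])

    steps = frame.index.to_series().diff().dropna()
    interval = steps.min()
    mask = np.ones(len(frame), dtype=bool)
    if len(steps) and (steps != interval).any():
        if (steps > MAX_INTERP_GAP).any():
            bad = steps[steps > MAX_INTERP_GAP].index[0]
            raise SeriesFormatError(
                f"{path}: gap longer than {MAX_INTERP_GAP} before {bad}"
            )
        full = pd.date_range(frame.index[0], frame.index[-1], freq=interval)
        present = full.isin(frame.index)
        frame = frame.reindex(full)
        act_cols = [c for c in frame.columns if c.startswith("act_")]
        frame[act_cols] = frame[act_cols].ffill()
        frame = frame.interpolate(method="linear")
        mask = np.asarray(present)
    return TraySeries.from_frame(frame, mask=mask)


# ------------------------------------------------------- derived-series CSV

def write_biomass_csv(biomass: BiomassSeries, path: str | Path) -> None:
    frame = biomass.to_frame()
    frame.index = frame.index.strftime("%Y-%m-%dT%H:%M:%S%z")
    frame.to_csv(path, float_format="%.10g")


def read_biomass_csv(path: str | Path) -> BiomassSeries:
    frame = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    return BiomassSeries.from_frame(frame)


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    frame = truth.to_frame()
    frame.index = frame.index.strftime("%Y-%m-%dT%H:%M:%S%z")
    frame.to_csv(path, float_format="%.10g")


def read_ground_truth_csv(path: str | Path) -> GroundTruth:
    frame = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    return GroundTruth(
        index=pd.DatetimeIndex(frame.index),
        per_plant_mass=frame["per_plant_g"].to_numpy(),
        plant_count=frame["n_plants"].to_numpy().astype(int),
        tray_true_mass=frame["tray_true_g"].to_numpy(),
        per_plant_root_mass=frame["per_plant_root_g"].to_numpy(),
    )


# --------------------------------------------------------- ledger/harvests

def write_ledger_csv(ledger: PlantLedger, path: str | Path) -> None:
    rows = [
        {"timestamp": ev.timestamp.isoformat(), "plants_removed": ev.plants_removed,
         "kind": ev.kind}
        for ev in ledger.events
    ]
    pd.DataFrame(rows, columns=["timestamp", "plants_removed", "kind"]).to_csv(
        path, index=False
    )


def read_ledger_csv(
    path: str | Path, n0: int, m_sub: float | None = None, m_basket: float = 0.0
) -> PlantLedger:
    frame = pd.read_csv(path)
    events = [
        LedgerEvent(
            timestamp=pd.Timestamp(row["timestamp"]),
            plants_removed=int(row["plants_removed"]),
            kind=str(row["kind"]),
        )
        for _, row in frame.iterrows()
    ]
    return PlantLedger(n0=n0, m_sub=m_sub, m_basket=m_basket, events=events)


def write_harvests_csv(records: list[HarvestRecord], path: str | Path) -> None:
    rows = [
        {"plant_id": r.plant_id, "day": r.day, "m_man_g": r.m_man,
         "m_leaf_g": r.m_leaf, "m_root_g": r.m_root,
         "m_dry_g": "" if r.m_dry is None else r.m_dry}
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["plant_id", "day", "m_man_g", "m_leaf_g", "m_root_g", "m_dry_g"]
    ).to_csv(path, index=False)


def read_harvests_csv(path: str | Path) -> list[HarvestRecord]:
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        m_dry = row.get("m_dry_g")
        records.append(
            HarvestRecord(
                plant_id=str(row["plant_id"]),
                day=float(row["day"]),
                m_man=float(row["m_man_g"]),
                m_leaf=float(row["m_leaf_g"]),
                m_root=float(row["m_root_g"]),
                m_dry=None if pd.isna(m_dry) else float(m_dry),
            )
        )
    return records


# ------------------------------------------------------- calibration JSON

def write_calibration_json(
    path: str | Path,
    temp_calibs: dict[int, TempCalibration] | None = None,
    actuator_models: dict[str, list[ActuatorModel]] | None = None,
    span_calibs: dict[int, SpanCalibration] | None = None,
) -> None:
    doc: dict = {"cells": {}, "actuators": {}, "span": {}}
    for cell, c in (temp_calibs or {}).items():
        doc["cells"][str(cell)] = {
            "c_t": c.c_t, "c_t0": c.c_t0, "t0": c.t0,
            "r_squared": c.r_squared,
            "c_t_stderr": c.c_t_stderr, "c_t0_stderr": c.c_t0_stderr,
        }
    for name, models in (actuator_models or {}).items():
        doc["actuators"][name] = [
            {
                "delta": m.delta, "rho_before": m.rho_before,
                "rho_after": m.rho_after,
                "estimated_at": None if m.estimated_at is None
                else m.estimated_at.isoformat(),
                "window_s": None if m.window is None
                else m.window.total_seconds(),
            }
            for m in models
        ]
    for cell, s in (span_calibs or {}).items():
        doc["span"][str(cell)] = {
            "factor": s.factor, "tare_offset": s.tare_offset,
            "reference_mass": s.reference_mass,
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_calibration_json(path: str | Path):
    doc = json.loads(Path(path).read_text())
    temp_calibs = {
        int(cell): TempCalibration(
            cell_id=int(cell), c_t=d["c_t"], c_t0=d["c_t0"], t0=d["t0"],
            r_squared=d["r_squared"],
            c_t_stderr=d.get("c_t_stderr", float("nan")),
            c_t0_stderr=d.get("c_t0_stderr", float("nan")),
        )
        for cell, d in doc.get("cells", {}).items()
    }
    actuator_models = {
        name: [
            ActuatorModel(
                actuator_id=name, delta=d["delta"],
                rho_before=d["rho_before"], rho_after=d["rho_after"],
                estimated_at=None if d.get("estimated_at") is None
                else pd.Timestamp(d["estimated_at"]),
                window=None if d.get("window_s") is None
                else pd.Timedelta(seconds=d["window_s"]),
            )
            for d in models
        ]
        for name, models in doc.get("actuators", {}).items()
    }
    span_calibs = {
        int(cell): SpanCalibration(
            cell_id=int(cell), factor=d["factor"],
            tare_offset=d["tare_offset"], reference_mass=d["reference_mass"],
        )
        for cell, d in doc.get("span", {}).items()
    }
    return temp_calibs, actuator_models, span_calibs


# ------------------------------------------------------------ config YAML

def write_sim_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
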