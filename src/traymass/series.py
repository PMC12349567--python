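"""In-memory containers for tray sensor streams and derived biomass series.

A tray is weighed by four bending-beam load cells; the raw channels are the
four per-cell readings (grams, already span-calibrated), the chamber air
temperature (degC) and one binary state channel per recorded actuator.
All channels live on a single uniform time grid (default 15 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SeriesFormatError

N_CELLS = 4


@dataclass
class TraySeries:
    """Aligned multi-channel tray recording on a uniform time grid.

    Parameters
    ----------
    index : pd.DatetimeIndex
        Strictly increasing, uniformly spaced timestamps (UTC).
    cells : np.ndarray, shape (n, 4)
        Per-cell readings S1..S4 in grams.
    temperature : np.ndarray, shape (n,)
        Chamber air temperature in degC.
    actuators : dict[str, np.ndarray]
        Binary (0/1) state series per actuator channel.
    mask : np.ndarray of bool, shape (n,)
        Per-sample validity; False marks gap-filled or manually masked samples.
    """

    index: pd.DatetimeIndex
    cells: np.ndarray
    temperature: np.ndarray
    actuators: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = len(self.index)
        if self.cells.shape != (n, N_CELLS):
            raise SeriesFormatError(
                f"cells must have shape ({n}, {N_CELLS}), got {self.cells.shape}"
            )
        if self.temperature.shape != (n,):
            raise SeriesFormatError("temperature length does not match index")
        for name, u in self.actuators.items():
            u = np.asarray(u)
            if u.shape != (n,):
                raise SeriesFormatError(f"actuator '{name}' length mismatch")
            if not np.isin(u, (0, 1)).all():
                raise SeriesFormatError(f"actuator '{name}' must be binary 0/1")
            self.actuators[name] = u.astype(int)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n,):
                raise SeriesFormatError("mask length does not match index")
        if n >= 2:
            steps = np.diff(self.index.asi8)
            if (steps <= 0).any():
                raise SeriesFormatError("timestamps must be strictly increasing")
            if not (steps == steps[0]).all():
                raise SeriesFormatError("timestamps must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.index)

    @property
    def interval_s(self) -> float:
        """Grid spacing in seconds."""
        if len(self.index) < 2:
            raise SeriesFormatError("need at least two samples to infer interval")
        return float((self.index[1] - self.index[0]).total_seconds())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical column layout used by the CSV interface."""
        data = {f"s{i + 1}_g": self.cells[:, i] for i in range(N_CELLS)}
        data["temp_c"] = self.temperature
        for name, u in self.actuators.items():
            data[f"act_{name}"] = u
        frame = pd.DataFrame(data, index=self.index)
        frame.index.name = "timestamp"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mask: np.ndarray | None = None) -> "TraySeries":
        cell_cols = [f"s{i + 1}_g" for i in range(N_CELLS)]
        missing = [c for c in cell_cols + ["temp_c"] if c not in frame.columns]
        if missing:
            raise SeriesFormatError(f"missing mandatory columns: {missing}")
        actuators = {
            c[len("act_"):]: frame[c].to_numpy()
            for c in frame.columns
            if c.startswith("act_")
        }
        return cls(
            index=pd.DatetimeIndex(frame.index),
            cells=frame[cell_cols].to_numpy(),
            temperature=frame["temp_c"].to_numpy(),
            actuators=actuators,
            mask=mask,
        )


@dataclass
class BiomassSeries:
    """Derived tray-level mass series, one value per raw sample.

    ``m_raw`` is the outlier-cleaned sum of the four cells (M), ``m_temp``
    the temperature-corrected tray mass (M_T), ``m_act`` the additionally
    actuator-corrected mass (M_u) and ``m_filt`` the low-pass filtered
    result (M_f). All in grams on the TraySeries grid.
    """

    index: pd.DatetimeIndex
    m_raw: np.ndarray
    m_temp: np.ndarray
    m_act: np.ndarray
    m_filt: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.index)
        for name in ("m_raw", "m_temp", "m_act", "m_filt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise SeriesFormatError(f"{name} length does not match index")
            setattr(self, name, arr)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "m_raw_g": self.m_raw,
                "m_temp_g": self.m_temp,
                "m_act_g": self.m_act,
                "m_filt_g": self.m_filt,
                "mask": self.mask.astype(int),
            },
            index=self.index,
        )
        frame.index.name = "timestamp"
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BiomassSeries":
        return cls(
            index=pd.DatetimeIndex(frame.index),
            m_raw=frame["m_raw_g"].to_numpy(),
            m_temp=frame["m_temp_g"].to_numpy(),
            m_act=frame["m_act_g"].to_numpy(),
            m_filt=frame["m_filt_g"].to_numpy(),
            mask=frame["mask"].to_numpy().astype(bool) if "mask" in frame else None,
        )
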