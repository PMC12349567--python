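"""Digital twin of a load-cell-instrumented hydroponic tray.

Generates raw per-cell readings with the full disturbance structure the
processing pipeline has to remove — linear temperature drift per cell, a
constant additive offset while an actuator is active, Gaussian measurement
noise and sporadic one-sample spikes — together with the ground-truth
biomass trajectory, so that every correction step can be validated by
parameter recovery instead of against unavailable trial data.

The emulated trial follows a lettuce crop on a 20-pot tray: sigmoidal
per-plant growth, a diurnal chamber-temperature cycle driven by the
photoperiod, wet rockwool substrate per plant, and step drops in tray mass
at harvest events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .series import N_CELLS, TraySeries

EPOCH = pd.Timestamp("2025-01-01T00:00:00Z")

#: Per-cell linear temperature-drift coefficients (c_T g/degC, c_T0 g) used
#: as simulator defaults; magnitudes of order 1 g/degC, as observed for
#: uncompensated low-cost bending-beam cells.
DEFAULT_TEMP_COEFFS = ((1.61, -0.46), (-1.41, -0.27), (0.61, -0.06), (-1.88, -0.09))


@dataclass(frozen=True)
class GrowthModel:
    """Logistic per-plant fresh-mass curve m(d) = g / (1 + exp(-r (d - d0))).

    Defaults interpolate a lettuce trial with a 15.2 g plant at day 18 and
    an 83.8 g plant at day 32: asymptote 90 g, rate 0.30 /day, midpoint
    day 23.3.
    """

    asymptote_g: float = 90.0
    rate_per_day: float = 0.30
    midpoint_day: float = 23.3

    def __post_init__(self) -> None:
        if self.asymptote_g < 0 or self.rate_per_day < 0 or self.midpoint_day < 0:
            raise InvalidSpecError("growth parameters must be non-negative")


@dataclass(frozen=True)
class TempProfile:
    """Diurnal chamber-temperature cycle driven by the photoperiod.

    Temperature sits at ``base_c`` in the dark and rises by ``amplitude_c``
    while the lights are on (``photoperiod_h`` hours from local midnight),
    with raised-cosine transitions of ``transition_min`` minutes emulating
    thermal inertia.
    """

    base_c: float = 20.0
    amplitude_c: float = 5.0
    photoperiod_h: float = 17.0
    transition_min: float = 30.0


@dataclass(frozen=True)
class ActuatorSchedule:
    """Periodic on/off duty cycle of one disturbing actuator.

    While active the actuator shifts the summed tray reading by ``delta_g``
    (negative for the pressure drop a climate-control exhaust causes).
    """

    name: str = "climate"
    period_min: float = 30.0
    duty: float = 0.5
    delta_g: float = -4.0
    phase_min: float = 0.0

    def __post_init__(self) -> None:
        if self.period_min <= 0 or not (0.0 <= self.duty <= 1.0):
            raise InvalidSpecError("actuator schedule needs period > 0, duty in [0,1]")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated growth trial.

    The defaults emulate the validation-style trial: 20 plants, 50 g wet
    substrate plugs, 32 days at 15 s sampling, 1 g per-cell Gaussian noise,
    a -4 g climate-control shift, and a single mid-trial harvest of 10
    plants on day 18. ``seed`` is mandatory: the twin has no implicit
    randomness.
    """

    seed: int
    n_plants_initial: int = 20
    tare_mass_g: float = 0.0
    substrate_mass_per_plant_g: float = 50.0
    growth: GrowthModel = field(default_factory=GrowthModel)
    temp_profile: TempProfile = field(default_factory=TempProfile)
    temp_coeffs: tuple[tuple[float, float], ...] = DEFAULT_TEMP_COEFFS
    actuator: ActuatorSchedule | None = field(default_factory=ActuatorSchedule)
    noise_sigma_g: float = 1.0
    spike_rate_per_day: float = 2.0
    spike_magnitude_g: float = 50.0
    harvest_events: tuple[tuple[float, int], ...] = ((18.0, 10),)
    root_to_shoot_ratio: float = 0.30
    sample_interval_s: float = 15.0
    duration_days: float = 32.0
    start: pd.Timestamp = EPOCH

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidSpecError("seed is mandatory")
        if self.sample_interval_s <= 0:
            raise InvalidSpecError("sample_interval_s must be positive")
        if self.duration_days <= 0:
            raise InvalidSpecError("duration_days must be positive")
        if len(self.temp_coeffs) != N_CELLS:
            raise InvalidSpecError(f"temp_coeffs must list {N_CELLS} cells")
        count = self.n_plants_initial
        for day, removed in sorted(self.harvest_events):
            if removed < 0 or day < 0:
                raise InvalidSpecError("harvest events must be non-negative")
            count -= removed
            if count < 0:
                raise InvalidSpecError(
                    "harvest schedule removes more plants than present"
                )


@dataclass
class GroundTruth:
    """True trajectories of the simulated tray, for parameter-recovery tests.

    Invariant: ``tray_true_mass = tare + plant_count * substrate + plant_count
    * per_plant_mass`` at every sample. Root mass is tracked separately and is
    NOT part of tray mass (roots hang submerged in the nutrient solution).
    """

    index: pd.DatetimeIndex
    per_plant_mass: np.ndarray
    plant_count: np.ndarray
    tray_true_mass: np.ndarray
    per_plant_root_mass: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "per_plant_g": self.per_plant_mass,
                "n_plants": self.plant_count,
                "tray_true_g": self.tray_true_mass,
                "per_plant_root_g": self.per_plant_root_mass,
            },
            index=self.index,
        )
        frame.index.name = "timestamp"
        return frame


def growth_curve(day, params: GrowthModel):
    """Logistic per-plant fresh mass (g) at trial day ``day`` (scalar or array)."""
    day = np.asarray(day, dtype=float)
    if (day < 0).any():
        raise InvalidSpecError("day must be >= 0")
    z = -params.rate_per_day * (day - params.midpoint_day)
    out = params.asymptote_g / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def temperature_profile(t_seconds: np.ndarray, profile: TempProfile) -> np.ndarray:
    """Chamber temperature (degC) at seconds-since-trial-start ``t_seconds``."""
    tod_h = (t_seconds / 3600.0) % 24.0
    w = profile.transition_min / 60.0
    on, off = 0.0, profile.photoperiod_h

    def _ramp(x):  # raised-cosine 0 -> 1 over [0, w]
        x = np.clip(x / max(w, 1e-9), 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(math.pi * x))

    level = _ramp(tod_h - on) - _ramp(tod_h - off)
    return profile.base_c + profile.amplitude_c * level


def actuator_state(t_seconds: np.ndarray, sched: ActuatorSchedule) -> np.ndarray:
    """Binary actuator duty pattern at seconds-since-start ``t_seconds``."""
    phase = ((t_seconds / 60.0 - sched.phase_min) / sched.period_min) % 1.0
    return (phase < sched.duty).astype(int)


def _ground_truth(config: SimConfig, index: pd.DatetimeIndex,
                  day: np.ndarray) -> GroundTruth:
    count = np.full(len(day), config.n_plants_initial, dtype=int)
    for h_day, removed in sorted(config.harvest_events):
        count[day >= h_day] -= removed
    shoot = growth_curve(day, config.growth)
    tray = (
        config.tare_mass_g
        + count * config.substrate_mass_per_plant_g
        + count * shoot
    )
    return GroundTruth(
        index=index,
        per_plant_mass=shoot,
        plant_count=count,
        tray_true_mass=tray,
        per_plant_root_mass=config.root_to_shoot_ratio * shoot,
    )


def simulate_tray(config: SimConfig) -> tuple[TraySeries, GroundTruth]:
    """Generate one seeded trial: raw sensor streams plus ground truth.

    Each cell carries a quarter of the true tray mass plus its own linear
    temperature drift, a quarter of the actuator shift while active,
    Gaussian noise and Poisson-arrival one-sample spikes. Deterministic
    given ``config.seed``; every channel draws from its own spawned
    substream so adding an effect never perturbs the others.
    """
    n = int(round(config.duration_days * 86400.0 / config.sample_interval_s))
    t_seconds = np.arange(n) * config.sample_interval_s
    index = config.start + pd.to_timedelta(t_seconds, unit="s")
    day = t_seconds / 86400.0

    truth = _ground_truth(config, index, day)
    temp = temperature_profile(t_seconds, config.temp_profile)
    t0 = config.temp_profile.base_c  # zero calibration done lights-off

    actuators: dict[str, np.ndarray] = {}
    act_total = np.zeros(n)
    if config.actuator is not None:
        u = actuator_state(t_seconds, config.actuator)
        actuators[config.actuator.name] = u
        act_total = config.actuator.delta_g * u

    streams = np.random.SeedSequence(config.seed).spawn(2 * N_CELLS)
    cells = np.empty((n, N_CELLS))
    p_spike = config.spike_rate_per_day * config.sample_interval_s / 86400.0
    for i in range(N_CELLS):
        c_t, c_t0 = config.temp_coeffs[i]
        noise_rng = np.random.default_rng(streams[i])
        spike_rng = np.random.default_rng(streams[N_CELLS + i])
        reading = (
            truth.tray_true_mass / N_CELLS
            + c_t * (temp - t0)
            + c_t0
            + act_total / N_CELLS
        )
        if config.noise_sigma_g > 0:
            reading = reading + noise_rng.normal(0.0, config.noise_sigma_g, n)
        if p_spike > 0 and config.spike_magnitude_g != 0:
            hits = spike_rng.random(n) < p_spike
            signs = np.where(spike_rng.random(n) < 0.5, -1.0, 1.0)
            reading = reading + hits * signs * config.spike_magnitude_g
        cells[:, i] = reading

    series = TraySeries(index=index, cells=cells, temperature=temp,
                        actuators=actuators)
    return series, truth


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a SimConfig (round-trippable via YAML/JSON)."""
    d = asdict(config)
    d["start"] = config.start.isoformat()
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["growth"] = GrowthModel(**d["growth"])
    d["temp_profile"] = TempProfile(**d["temp_profile"])
    if d.get("actuator") is not None:
        d["actuator"] = ActuatorSchedule(**d["actuator"])
    d["temp_coeffs"] = tuple(tuple(pair) for pair in d["temp_coeffs"])
    d["harvest_events"] = tuple(
        (float(day), int(k)) for day, k in d.get("harvest_events", ())
    )
    d["start"] = pd.Timestamp(d["start"])
    return SimConfig(**d)
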