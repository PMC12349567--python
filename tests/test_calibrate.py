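import numpy as np
import pandas as pd
import pytest

from traymass import (
    CalibrationError,
    SimConfig,
    estimate_actuator_delta,
    fit_span,
    fit_temperature_model,
    reestimate_delta,
    simulate_tray,
    tare,
)

from conftest import make_series


class TestSpan:
    def test_factor_from_reference_mass(self):
        cal = fit_span(2500.0, 500_000.0, 0.0)
        assert cal.factor == pytest.approx(0.005)

    def test_round_trip_reproduces_reference(self):
        cal = fit_span(2500.0, 731_200.0, 12_345.0)
        assert cal.convert(731_200.0) == pytest.approx(2500.0)
        assert cal.convert(12_345.0) == 0.0

    @pytest.mark.parametrize("known,loaded,empty", [(0.0, 10.0, 0.0), (5.0, 7.0, 7.0)])
    def test_degenerate_calibration_rejected(self, known, loaded, empty):
        with pytest.raises(CalibrationError):
            fit_span(known, loaded, empty)


class TestTare:
    def test_constant_offsets(self):
        series = make_series(np.full((40, 4), 250.0))
        assert np.allclose(tare(series), 250.0)
        assert np.allclose(series.cells - tare(series), 0.0)

    def test_noisy_offset_within_standard_error(self):
        rng = np.random.default_rng(1234)
        n = 240
        series = make_series(100.0 + rng.normal(0, 1.0, (n, 4)))
        offsets = tare(series)
        assert np.all(np.abs(offsets - 100.0) <= 3.0 / np.sqrt(n))

    def test_empty_window_rejected(self):
        series = make_series(np.full((40, 4), 250.0))
        with pytest.raises(CalibrationError):
            tare(series, window=pd.Timedelta(seconds=-1))


class TestTemperatureModel:
    def test_noiseless_exact_recovery(self):
        temp = 20.0 + 5.0 * np.sin(np.linspace(0, 2 * np.pi, 200))
        load = 500.0
        cells = np.tile(load + 2.0 * (temp - 20.0) + 1.0, (4, 1)).T
        calib = fit_temperature_model(
            make_series(cells, temperature=temp), 0, t0=20.0, reference_mass=load
        )
        assert calib.c_t == pytest.approx(2.0)
        assert calib.c_t0 == pytest.approx(1.0)
        assert calib.r_squared == pytest.approx(1.0)

    def test_constant_temperature_unidentifiable(self):
        series = make_series(np.full((50, 4), 250.0))
        with pytest.raises(CalibrationError):
            fit_temperature_model(series, 0, t0=20.0)

    def test_noisy_recovery_within_ols_confidence_interval(self):
        """24 h at 15 s, sigma = 1 g: the fitted slope must match both the
        closed-form OLS estimate and fall inside its 95% CI around truth."""
        rng = np.random.default_rng(1234)
        n = 5760
        t_h = np.arange(n) * 15.0 / 3600.0
        temp = 20.0 + 2.5 * (1 - np.cos(2 * np.pi * t_h / 24.0))
        c_t_true = 1.61
        cells = np.tile(400.0 + c_t_true * (temp - 20.0), (4, 1)).T
        cells += rng.normal(0, 1.0, cells.shape)
        calib = fit_temperature_model(
            make_series(cells, temperature=temp), 0, t0=20.0, reference_mass=400.0
        )
        # independent closed-form OLS oracle
        x = temp - 20.0
        y = cells[:, 0]
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert calib.c_t == pytest.approx(slope, rel=1e-12)
        assert abs(calib.c_t - c_t_true) <= 1.96 * calib.c_t_stderr

    def test_low_noise_fit_quality(self):
        """sigma = 0.1 g over a 5 degC swing gives an almost perfect fit."""
        rng = np.random.default_rng(7)
        temp = 20.0 + 2.5 * (1 - np.cos(np.linspace(0, 4 * np.pi, 2000)))
        cells = np.tile(400.0 + 1.61 * (temp - 20.0), (4, 1)).T
        cells += rng.normal(0, 0.1, cells.shape)
        calib = fit_temperature_model(
            make_series(cells, temperature=temp), 0, t0=20.0
        )
        assert calib.r_squared >= 0.99


class TestActuatorDelta:
    def test_mean_contrast(self):
        mass = np.array([12.0, 14.0, 8.0, 10.0])
        u = np.array([0, 0, 1, 1])
        assert estimate_actuator_delta(mass, u, edge_guard=0) == pytest.approx(-4.0)

    def test_identical_distributions_give_zero(self):
        mass = np.array([10.0, 10.0, 10.0, 10.0])
        u = np.array([0, 1, 0, 1])
        assert estimate_actuator_delta(mass, u, edge_guard=0) == 0.0

    def test_single_state_rejected(self):
        with pytest.raises(CalibrationError):
            estimate_actuator_delta(np.ones(10), np.zeros(10, dtype=int))

    def test_edge_guard_excludes_transients(self):
        # transient spike right after switch-on must not bias the contrast
        u = np.array([0] * 10 + [1] * 10)
        mass = np.full(20, 100.0)
        mass[10:] -= 4.0
        mass[10] += 50.0  # switching transient
        biased = estimate_actuator_delta(mass, u, edge_guard=0)
        guarded = estimate_actuator_delta(mass, u, edge_guard=2)
        assert abs(guarded - (-4.0)) < abs(biased - (-4.0))
        assert guarded == pytest.approx(-4.0)


class TestReestimateDelta:
    @staticmethod
    def _mass_u(n_days, delta_fn, seed=1234):
        n = n_days * 5760
        index = pd.date_range("2025-01-01", periods=n, freq="15s", tz="UTC")
        u = (np.arange(n) // 60) % 2  # 15 min on / 15 min off
        rng = np.random.default_rng(seed)
        day = np.arange(n) / 5760.0
        mass = 1000.0 + delta_fn(day) * u + rng.normal(0, 1.0, n)
        return pd.Series(mass, index=index), pd.Series(u, index=index)

    def test_stationary_shift_tracked_daily(self):
        mass, u = self._mass_u(5, lambda day: -4.0)
        models = reestimate_delta(mass, u, pd.Timedelta(hours=24))
        assert len(models) == 5
        assert all(m.delta == pytest.approx(-4.0, abs=0.2) for m in models)

    def test_shift_change_tracked_within_one_cadence(self):
        mass, u = self._mass_u(6, lambda day: np.where(day < 3.0, -4.0, -2.0))
        models = reestimate_delta(mass, u, pd.Timedelta(hours=24))
        assert models[1].delta == pytest.approx(-4.0, abs=0.3)
        assert models[-1].delta == pytest.approx(-2.0, abs=0.3)

    def test_single_state_window_retains_previous(self, caplog):
        n = 2 * 5760
        index = pd.date_range("2025-01-01", periods=n, freq="15s", tz="UTC")
        u = np.zeros(n, dtype=int)
        u[: n // 2] = (np.arange(n // 2) // 60) % 2  # day 2: actuator never on
        mass = pd.Series(1000.0 - 4.0 * u, index=index)
        models = reestimate_delta(mass, pd.Series(u, index=index),
                                  pd.Timedelta(hours=24))
        assert len(models) == 2
        assert models[1].delta == models[0].delta

    def test_series_shorter_than_cadence_rejected(self):
        mass, u = self._mass_u(1, lambda day: -4.0)
        with pytest.raises(CalibrationError):
            reestimate_delta(mass, u, pd.Timedelta(hours=48))


def test_parameter_recovery_on_simulated_calibration_run(calibration_config):
    """Simulator round trip: the temperature slopes injected per cell are
    recovered within 5% from one noisy day-night cycle."""
    from traymass.trial import calibrate_trial

    series, _ = simulate_tray(calibration_config)
    calibs = calibrate_trial(series)
    for i, calib in calibs.items():
        c_t_true = calibration_config.temp_coeffs[i][0]
        assert calib.c_t == pytest.approx(c_t_true, rel=0.05)
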