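"""Calibration: recover temperature coefficients and the actuator delta.

A constant-mass day-night cycle identifies each cell's linear drift model
S = load + c_T (T - T0) + c_T0; a state-contrast of the tray mass between
actuator-on and actuator-off samples identifies the disturbance delta.
"""

from traymass import (
    ActuatorSchedule,
    GrowthModel,
    SimConfig,
    estimate_actuator_delta,
    fit_temperature_model,
    simulate_tray,
)

# temperature-calibration run: constant load over one diurnal cycle
cal = SimConfig(seed=2, duration_days=1.0, growth=GrowthModel(asymptote_g=0.0),
                actuator=None, harvest_events=())
series, truth = simulate_tray(cal)
load_per_cell = truth.tray_true_mass[0] / 4.0
print("cell   c_T fit    c_T true   R^2")
for i in range(4):
    calib = fit_temperature_model(series, i, t0=cal.temp_profile.base_c,
                                  reference_mass=load_per_cell)
    print(f"  S{i + 1}   {calib.c_t:+7.3f}    {cal.temp_coeffs[i][0]:+5.2f}"
          f"     {calib.r_squared:.4f}")

# actuator-calibration run: steady tray, -4 g shift while the climate
# control is active
act = SimConfig(seed=3, duration_days=1.0, growth=GrowthModel(asymptote_g=0.0),
                temp_coeffs=((0.0, 0.0),) * 4,
                actuator=ActuatorSchedule(delta_g=-4.0),
                spike_rate_per_day=0.0, harvest_events=())
series2, _ = simulate_tray(act)
delta = estimate_actuator_delta(series2.cells.sum(axis=1),
                                series2.actuators["climate"])
print(f"\nactuator delta estimate: {delta:+.3f} g  (injected -4 g)")
print("A negative delta means the tray reads light while the actuator runs;")
print("the correction therefore raises the mass during active intervals.")
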