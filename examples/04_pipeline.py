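"""Conditioning pipeline: Hampel -> temperature -> sum -> actuator -> low-pass.

Runs the full chain on one simulated day with every disturbance enabled and
shows how each stage narrows the spread of the tray-mass estimate around
the 1000 g truth.
"""

import numpy as np

from traymass import (
    GrowthModel,
    SimConfig,
    TempCalibration,
    ActuatorModel,
    run_pipeline,
    simulate_tray,
)

config = SimConfig(seed=4, duration_days=1.0, growth=GrowthModel(asymptote_g=0.0),
                   harvest_events=())
series, truth = simulate_tray(config)

# correct with the true injected parameters to isolate the pipeline itself
calibs = {
    i: TempCalibration(i, c_t=config.temp_coeffs[i][0],
                       c_t0=config.temp_coeffs[i][1],
                       t0=config.temp_profile.base_c, r_squared=1.0)
    for i in range(4)
}
models = {"climate": ActuatorModel("climate", delta=-4.0,
                                   rho_before=-0.7, rho_after=0.0)}
biomass, report = run_pipeline(series, calibs, actuator_models=models)

truth_mass = truth.tray_true_mass
for name, stage in [("raw sum (Hampel only)", biomass.m_raw),
                    ("temperature-corrected", biomass.m_temp),
                    ("actuator-corrected", biomass.m_act),
                    ("low-pass filtered", biomass.m_filt)]:
    rms = np.sqrt(np.mean((stage - truth_mass) ** 2))
    print(f"{name:24s} RMS error {rms:6.2f} g")
print(f"outliers flagged: {report['outliers_flagged']} "
      f"of {4 * report['samples']} cell samples")
print("The filtered tray mass settles well inside the +-4 g accuracy of the")
print("four 5 kg cells, so sub-gram per-plant growth becomes resolvable.")
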