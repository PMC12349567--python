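"""Digital twin: generate a 32-day lettuce trial and inspect the raw streams.

The default configuration emulates a validation-style trial: 20 plants on
a four-cell tray sampled every 15 s, diurnal temperature drift, a -4 g
climate-control disturbance, 1 g Gaussian noise, spikes, and a mid-trial
harvest of 10 plants on day 18.
"""

import numpy as np

from traymass import SimConfig, simulate_tray

config = SimConfig(seed=1)
series, truth = simulate_tray(config)

print(f"samples:            {len(series)} at {series.interval_s:.0f} s cadence")
print(f"temperature range:  {series.temperature.min():.1f} .. "
      f"{series.temperature.max():.1f} degC")
total = series.cells.sum(axis=1)
print(f"raw tray sum:       {total[0]:.1f} g (day 0) -> {total[-1]:.1f} g (day 32)")
print(f"true tray mass:     {truth.tray_true_mass[0]:.1f} g -> "
      f"{truth.tray_true_mass[-1]:.1f} g")
print(f"plant count:        {truth.plant_count[0]} -> {truth.plant_count[-1]}")
print(f"true per-plant:     {truth.per_plant_mass[0]:.2f} g -> "
      f"{truth.per_plant_mass[-1]:.2f} g")
drop = np.max(-np.diff(truth.tray_true_mass))
print(f"largest true step:  {drop:.1f} g  (the day-18 harvest: 10 plants "
      "leave with their wet plugs)")
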