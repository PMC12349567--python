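"""End-to-end trial: per-plant biomass and harvest-point accuracy.

Simulates the full validation-style trial, runs calibration + processing +
evaluation, and compares the sensor's per-plant mass with ground truth at
the mid-trial and final harvests — the same comparison a grower would make
against destructive reference measurements.
"""

from traymass import (
    HarvestRecord,
    PlantLedger,
    SimConfig,
    compute_adjustment_factors,
    harvest_error,
    run_trial,
)

sim = SimConfig(seed=5)
biomass, report, series, truth = run_trial(sim)

print(f"substrate estimate: {report.metrics['m_sub_g']:.2f} g/plant "
      f"(true {sim.substrate_mass_per_plant_g:.0f} g)")
for entry in report.metrics["events"]:
    abs_err, rel_err = harvest_error(entry["m_lc_g"], entry["true_per_plant_g"])
    print(f"harvest @ {entry['timestamp'][:10]}  n={entry['n_plants']:2d}  "
          f"sensor {entry['m_lc_g']:6.2f} g  true {entry['true_per_plant_g']:6.2f} g"
          f"  error {abs_err:.2f} g ({rel_err:.2f}%)")

# adjustment of whole-pot manual measurements to leaf mass, using harvest
# records derived from the simulated ground truth (root mass hangs in the
# nutrient solution and is invisible to the tray)
final = truth.per_plant_mass[-1]
root = truth.per_plant_root_mass[-1]
ledger = PlantLedger(n0=20, m_sub=report.metrics["m_sub_g"], m_basket=10.0)
records = [HarvestRecord(f"p{k}", 32.0, final + root + ledger.m_sub + 10.0,
                         final, root) for k in range(10)]
factors = compute_adjustment_factors(records, records[0].m_man, ledger)
print(f"leaf fraction c_man = {factors.c_man:.2f}, "
      f"sample factor c_sample = {factors.c_sample:.2f}")
print("c_man converts a whole-plant mass to leaf mass; c_sample corrects a")
print("small manual sample toward the tray-average plant.")
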