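# Methods

This note documents the models, defaults and numerical choices behind
`traymass`, and what the simulation-based validation does and does not
demonstrate.

## Sensor model

A strain-gauge load cell is modelled as a full Wheatstone bridge: four
gauges of nominal resistance R, excitation V_in, output

V_out = [(R+ΔR₂)/((R+ΔR₁)+(R+ΔR₂)) − (R+ΔR₄)/((R+ΔR₃)+(R+ΔR₄))]·V_in.

In the symmetric small-deformation regime (ΔR₂=ΔR₃=ΔR, ΔR₁=ΔR₄=−ΔR) both
arm denominators equal 2R and the quotient collapses *algebraically* to
(ΔR/R)·V_in — the linearization is exact for symmetric states, which the
property tests exploit (agreement to rounding error on random specs). A
spec flags |ΔR|/R > 0.05 as outside the small-deformation regime.

Span calibration maps raw digitizer units to grams from a single known
reference mass (factor = mass / (loaded − empty)); tare subtracts the
per-cell mean over an empty-tray window. Four 5 kg cells at ±0.02 % of
full scale give ±1 g per cell and a worst-case ±4 g per tray; divided by
the plant count this sets the per-plant resolution floor (±0.4 g at 10
plants, ±0.67 g at 6 — conventionally printed truncated as 0.66).

## Disturbance models and their estimation

**Temperature drift** is additive and linear per cell:
drift_i = c_T,i·(T − T₀) + c_T0,i, with T the chamber air temperature and
T₀ its value at zero calibration. Coefficients are fitted by OLS of the
cell reading on (T − T₀) over one day/night cycle under constant load.
The slope is always identifiable; the intercept equals load + c_T0, so
c_T0 is only recovered when the true constant load is known
(`reference_mass`). In-trial calibration leaves c_T0 at zero and lets the
static offset be absorbed by the substrate-mass initialisation, which is
exactly where a constant tray offset ends up anyway. Air temperature is a
proxy for the cell body temperature; fast light-on transients therefore
leave small residuals, which is one reason the fitted R² on realistic
noise sits below 1 even with a perfect linear drift.

**Actuator disturbance** is a constant additive offset δ while the
actuator runs, estimated as the mean contrast
mean(M_T|u=1) − mean(M_T|u=0). Samples within ±2 samples of a state
transition are excluded from both means so switching transients do not
bias the contrast. During operation the delta is re-estimated on
consecutive 24 h windows; a window containing only one state retains the
previous estimate (logged). Each estimate governs the correction of data
after its window; compensation quality is reported as ρ(M,u) before and
after.

**Outliers** (manual handling, voltage glitches) are removed by a Hampel
filter: centred window of 11 samples (150 s at 15 s cadence), threshold 3
scaled MADs (MAD × 1.4826), replacement by the window median, truncated
windows at the series edges. With Gaussian noise this flags roughly 1–3 %
of samples (more near actuator edges, where the window mixes two levels);
replacements stay within the noise band and are harmless downstream.

**Noise** is removed by a Butterworth low-pass, order 4, cutoff
0.025 min⁻¹ (40 min), designed with scipy and applied either forward-
backward (zero-phase; default for offline reprocessing — no lag on slow
trends, magnitude response squared, so a sinusoid at the cutoff passes at
1/2 instead of 1/√2) or causally for streaming. DC gain is exactly 1.

Because a zero-phase filter smears a step symmetrically into the past,
the trial pipeline filters independently on segments delimited by known
ledger events (harvests). This keeps the mass read just before a harvest
untouched by the drop itself; without segmentation the pre-harvest
per-plant mass is biased low by hundreds of grams of backward smear.
Sub-5-minute recording gaps are linearly interpolated (flagged in the
mask) at read time; longer gaps are rejected rather than bridged.

## Biomass accounting

m_sub is initialised as M_f averaged over the first hour divided by n₀
(seedling mass at transplant is negligible against a ~50 g wet plug; the
residual seedling mass, ~0.1 g/plant under the default growth curve,
becomes a small constant negative bias of m_lc). Harvested plants leave
with their plugs, so both M_f and n drop and
m_lc = (M_f − n·m_sub)/n stays consistent. The mass at a harvest epoch is
read as the filtered value averaged over the 10 min before the event
(configurable). Root mass hangs submerged in the nutrient solution and is
invisible to the tray; it is handled only through the leaf fraction
c_man = m̄_leaf/(m̄_leaf+m̄_root) when adjusting manual whole-pot
measurements, together with the sample-representativeness factor
c_sample. Baskets are part of the tray tare but present in manual pot
measurements, hence m_basket appears only in the manual adjustment.

## The digital twin

`simulate_tray` emulates: per-cell quarter share of the true tray mass;
per-cell linear temperature drift (defaults: the four test-trial
coefficient pairs, order ±1.9 g/°C); a diurnal temperature square-wave
(20 °C base, +5 °C during a 17 h photoperiod, 30 min raised-cosine
transitions); a −4 g tray shift split equally over the cells while a
30 min/50 % duty actuator runs; Gaussian noise (σ = 1 g per cell);
Poisson one-sample spikes (2/day, ±50 g); logistic per-plant growth; and
harvest step drops. All randomness flows from one mandatory seed through
per-channel spawned substreams, so runs are bit-reproducible and adding
one disturbance never perturbs another.

Growth defaults (asymptote 90 g, rate 0.30 /day, midpoint day 23.3) were
chosen to pass through a 15.2 g plant at day 18 and an 83.8 g plant at
day 32 — the two harvest masses of the emulated validation-style trial —
with near-zero seedling mass at transplant. The equal split of the
actuator shift across cells is an assumption; only the tray-level sum is
identifiable anyway. Root mass is tracked in the ground truth at a 0.30
root:shoot ratio (leaf fraction ≈ 0.77) for the manual-adjustment tests.

**What passing recovery tests show — and don't.** They show the
estimators are consistent and the pipeline unbiased *under the modelled
disturbance structure*: additive linear drift, a constant actuator
offset, white noise, isolated spikes. Real trays add effects the twin
omits: sensor-body vs air temperature lag, drift nonlinearity and aging,
correlated mechanical vibration spectra, plant water-content dynamics,
neighbouring-tray contact late in growth, and non-uniform plant sizes
(the twin grows identical plants, so per-plant mass is exact rather than
an average). Field accuracy therefore has to be established against
manual harvests, as the evaluation module supports.

## Problem sizes and numerical choices

The default simulated trial is 32 days at 15 s (184 320 samples × 4
cells), which the full pipeline processes in about a second; tests use
1–2 day runs except the end-to-end recovery study, which uses the full
trial. Calibration uses the first 24 h cycle (one full day/night is the
minimum that exercises the whole temperature swing); re-estimation
cadence is 24 h. OLS is delegated to scipy.stats.linregress (closed-form
standard errors feed the confidence-interval tests); filtering to
scipy.signal (filtfilt pad length 3× filter order). The Hampel
implementation uses a vectorized sliding window for the interior and
explicit truncated windows at the edges, and is cross-checked against a
brute-force reference. Recovery tolerances in tests follow the sampling
distribution of the estimator in question (5 % relative for slopes of
order 1 g/°C at σ = 1 g over a day; 95 % OLS confidence intervals where a
parameter's magnitude makes a fixed relative bound meaningless, e.g. a
0.06 g intercept against a 0.014 g standard error). A 0.1 g settling
allowance on per-plant recovery covers the seedling-mass bias in m_sub
plus residual filter noise.

## Known limitations

- The causal filter mode carries the design's group delay (~40 min scale);
  harvest-epoch reads in streaming mode should use the pre-event window
  accordingly.
- Segmented filtering requires harvest events to be in the ledger; an
  unlogged step disturbance is smeared just as in any offline low-pass.
- c_T0 is not separable from the load without a known reference mass;
  absolute (as opposed to differential) tray mass therefore depends on
  the tare and substrate initialisation.
- The adaptive, growth-phase-dependent cutoff and automatic anomaly
  detection for manual interventions are out of scope.
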