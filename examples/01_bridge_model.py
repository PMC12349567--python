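"""Strain-gauge bridge: exact quotient output vs small-signal approximation.

A 350-ohm full bridge excited at 5 V with a symmetric 0.35-ohm deformation
produces 5 mV; for symmetric states the linear form (dR/R) V_in is exact.
"""

from traymass import BridgeSpec, bridge_output_exact, bridge_output_linear

balanced = BridgeSpec(350.0, (0.0, 0.0, 0.0, 0.0), 5.0)
print(f"balanced bridge:        {bridge_output_exact(balanced) * 1e3:.4f} mV")

symmetric = BridgeSpec.symmetric(350.0, 0.35, 5.0)
print(f"symmetric, exact:       {bridge_output_exact(symmetric) * 1e3:.4f} mV")
print(f"symmetric, linearized:  {bridge_output_linear(symmetric) * 1e3:.4f} mV")

quarter = BridgeSpec(350.0, (0.0, 0.35, 0.0, 0.0), 5.0)
print(f"single active gauge:    {bridge_output_exact(quarter) * 1e3:.4f} mV")
print("A single active gauge yields ~1/4 of the full-bridge sensitivity,")
print("which is why load cells bond four gauges, two in tension, two in")
print("compression.")
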