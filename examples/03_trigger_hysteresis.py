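"""Measure the Schmitt-trigger hysteresis of the OPN/burst-neuron circuit.

The motor command is ramped up quasi-statically until the omnipause
neuron silences (fixation -> saccade switch) and back down until it
recovers.  The positive feedback loop formed by the mutual OPN <-> IBN
inhibition makes the two thresholds differ; cutting the LLIBN -> OPN
projection collapses the loop and the hysteresis with it.
"""

from sacsim import default_parameters, trigger_hysteresis_curve

params = default_parameters()
up, down = trigger_hysteresis_curve(params)
print(f"intact loop : switch up at {up:.3f}, back down at {down:.3f} "
      f"(width {up - down:.3f} command units)")

broken = params.replace(w_LLIBN_OPN=0.0)
up0, down0 = trigger_hysteresis_curve(broken)
print(f"broken loop : up {up0:.3f}, down {down0:.3f} (width {up0 - down0:.4f})")

print("\nWide hysteresis means a fluctuation that triggers a saccade will "
      "not flicker the system back mid-movement; without the feedback "
      "projection the two thresholds coincide.")
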