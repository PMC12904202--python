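"""Posttetanic potentiation and miniature-event rates.

Builds a normalized eEPSC amplitude time series that doubles after a
tetanus and decays on ~92 s, quantifies the potentiation fold and its
half-decay time, measures the accompanying mEPSC rate increase from a
simulated Poisson event stream, and closes with the power-law
cooperativity arithmetic connecting both to residual calcium.
"""

import numpy as np

from synprime import (binned_event_rate, cooperativity_prediction,
                      gen_mepsc_stream, ptp_quantify, ptp_rate_profile)

t_pre = np.arange(-60.0, 0.0, 15.0)
t_post = np.arange(0.0, 300.0, 15.0)
amps = np.concatenate([np.ones(t_pre.size), 1 + np.exp(-t_post / 92.0)])
res = ptp_quantify(np.concatenate([t_pre, t_post]), amps)
print(f"eEPSC potentiation: {res.fold:.2f}-fold, "
      f"t_half = {res.t_half:.1f} s")

stream, _ = gen_mepsc_stream(ptp_rate_profile(2.0, 6.98, 100.0),
                             duration=300.0, seed=1)
rates = binned_event_rate(stream, 2.0)
print(f"mEPSC rate just after tetanus: {rates[:3].mean():.1f} Hz "
      f"(baseline 2.0 Hz -> {rates[:3].mean() / 2.0:.1f}-fold)")

print(f"predicted mEPSC fold for 50 -> 130 nM residual Ca, slope 1.73: "
      f"{cooperativity_prediction(50, 130, 1.73):.2f}")
print(f"predicted eEPSC fold for 56.00 -> 56.08 uM local Ca, slope 4.2: "
      f"{cooperativity_prediction(56, 56.08, 4.2):.3f}")

print()
print("Spontaneous release tracks the ~2.6-fold residual-calcium rise with")
print("high apparent cooperativity, while the same rise barely moves the")
print("local calcium peak seen by evoked release - so the twofold eEPSC")
print("potentiation cannot be a calcium-occupancy effect.")
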