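"""Correct, bleach-detect and screen traces, then compute apparent FRET.

Mirrors the single-molecule screen applied to real recordings: every trace
must show exactly one photobleach event, anti-correlated donor/acceptor
channels, and a long-enough pre-bleach segment. Accepted traces become
apparent-FRET trajectories E_app = I_A / (I_A + I_D), truncated at the
bleach.
"""

from collections import Counter

import numpy as np

from fretscape import pipeline
from fretscape.simulate import simulate_experiment

results = simulate_experiment("apo-ACKR3", n_traces=100, n_frames=300, seed=3)
screened = pipeline.screen_condition([t for t, _ in results], "apo-ACKR3")

print(f"screened {screened.n_input} traces; accepted {screened.n_accepted} "
      f"({screened.acceptance_rate:.0%})")
reasons = Counter(r for rep in screened.reports if not rep.accepted for r in rep.reasons)
print(f"rejection reasons: {dict(reasons)}")

corr = [r.anticorrelation for r in screened.reports if r.accepted]
print(f"median pre-bleach donor/acceptor correlation: {np.median(corr):.2f}")

pooled = np.concatenate([t.e_app for t in screened.trajectories])
print(f"{len(pooled)} pre-bleach frames of E_app; mean {pooled.mean():.3f}, "
      f"sd {pooled.std():.3f}")
# Acceptance should sit above 90%; the strongly negative channel correlation
# is the single-molecule FRET signature the screen demands.
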