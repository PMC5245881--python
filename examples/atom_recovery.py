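"""Measure how many ground-truth atoms a learner recovers as noise grows.

For each SNR level, draws fresh 20x40 instances, learns a dictionary, and
counts atoms matched at cosine distance < 0.01 via optimal assignment.
Recovery should degrade gracefully from the noiseless case toward heavy
noise."""

import math

from procdl import recovery_experiment

df = recovery_experiment(
    sizes=[(20, 40)], snr_levels=[math.inf, 30.0, 10.0, 0.0],
    L=2000, k=3, s=5, T=60, trials=3, seed=1, algorithms=("rsvd",),
)

table = df.groupby("snr").value.mean().sort_index(ascending=False)
print("mean recovered atoms out of 40 (3 trials each):")
for snr, val in table.items():
    label = "no noise" if math.isinf(snr) else f"SNR {snr:g} dB"
    print(f"  {label:12s} {val:5.1f}")
print("\nCounts near 40 mean the generating dictionary was essentially "
      "identified up to column permutation and sign.")
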