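"""A scaled-down discount-rate sweep: the EMA trade-off and how EBI bends it.

Sweeps a subset of the discount grid for the EMA and the EBI (m=0, K=10).
For the EMA, raising the rate improves followability and worsens accuracy —
a strict trade-off.  The sweep then reports how much of the EMA curve the
best single EBI setting dominates in both coordinates at once.
"""

import numpy as np

from ebinfer import TaskConfig, sweep_discount

task = TaskConfig()
rates = np.round(0.009 + 0.018 * np.arange(8), 9)  # every 6th grid point
ema = sweep_discount(["ema"], task, rates=rates, n_trials=3, seed_base=0).table
ebi = sweep_discount(["ebi"], task, rates=rates, K_list=[10], n_trials=3,
                     seed_base=0).table

print("EMA trade-off (rate, followability, accuracy):")
for _, row in ema.iterrows():
    print(f"  beta={row['rate']:.3f}  follow={row['followability']:.4f}  "
          f"acc={row['accuracy']:.4f}")

best_dom, best_alpha = 0, None
for _, row in ebi.iterrows():
    dom = int(((row["followability"] < ema["followability"])
               & (row["accuracy"] < ema["accuracy"])).sum())
    if dom > best_dom:
        best_dom, best_alpha = dom, row["rate"]

print()
print(f"best EBI alpha: {best_alpha:.3f} — its (followability, accuracy) pair")
print(f"lies below the EMA pair at {best_dom} of {len(ema)} grid rates.")
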