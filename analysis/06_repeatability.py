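"""Individual- and population-level repeatability of trip metrics.

Variance-components R per trait with bootstrap CIs, plus the adjusted
variant (sex and season residualized out).  Since the generator gives each
bird its own foraging range and bearing, distance-related traits should be
highly repeatable and mode proportions should not.
"""
import pandas as pd

from _common import RESULTS, SCRATCH, SEED
from sulakit.repeatability import adjusted_values, repeatability_table

metrics = pd.read_csv(SCRATCH / "trip_metrics.csv")
traits = [
    "duration_h",
    "max_dist_colony_km",
    "prop_travel",
    "prop_forage",
    "prop_rest",
    "distal_lat",
    "distal_lon",
]

plain = repeatability_table(metrics, traits, n_boot=500, seed=SEED)
plain.insert(1, "variant", "unadjusted")

adj = metrics.copy()
for t in traits:
    adj[t] = adjusted_values(metrics[t], metrics[["sex", "season"]])
adjusted = repeatability_table(adj, traits, n_boot=500, seed=SEED)
adjusted.insert(1, "variant", "adjusted")

table = pd.concat([plain, adjusted], ignore_index=True)
table.to_csv(RESULTS / "repeatability.csv", index=False)
print(table[["trait", "variant", "R_ind", "R_pop", "band"]].round(3).to_string(index=False))
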