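"""Annotate at-sea behaviour by EM clustering of (log-speed, turn) steps.

Fits the four-mode mixture pooled across all birds, labels every step, and
scores the labels against the generator's hidden states.  Writes the step
table to scratch/, the fitted model and a truth-vs-label confusion table to
results/.
"""
import json

import pandas as pd

from _common import CONFIG, RESULTS, SCRATCH, SEED
from sulakit.behaviour import fit_embc, label_states
from sulakit.trajectories import split_trips, step_features

fixes = pd.read_csv(SCRATCH / "fixes.csv", parse_dates=["timestamp"])
truth = pd.read_csv(SCRATCH / "truth_fix_states.csv")

trips = split_trips(fixes, CONFIG.colony_lonlat, CONFIG.colony_radius_km)
steps = pd.concat([step_features(t) for t in trips], ignore_index=True)
model = fit_embc(steps, seed=SEED)
steps["state"] = label_states(steps, model)
steps.to_csv(SCRATCH / "steps_labelled.csv", index=False)
(RESULTS / "behaviour_model.json").write_text(json.dumps(model.to_dict(), indent=1))

fx = fixes.assign(tstate=truth["state"], at_sea=truth["at_sea"])
joined = steps.merge(fx[["bird_id", "timestamp", "tstate", "at_sea"]], on=["bird_id", "timestamp"])
joined = joined[joined["at_sea"]].dropna(subset=["state"])
confusion = pd.crosstab(joined["tstate"], joined["state"], normalize="index").round(3)
confusion.to_csv(RESULTS / "label_confusion.csv")

acc = (joined["state"] == joined["tstate"]).mean()
print(f"{len(trips)} trips, {len(steps)} steps; EM converged in "
      f"{len(model.log_likelihoods)} iterations")
print(f"speed delimiter {model.speed_delimiter_kmh:.1f} km/h, "
      f"turn delimiter {model.delimiters[1]:.2f} rad")
print(f"label-vs-truth agreement (at-sea steps): {acc:.3f}")
print(confusion)
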