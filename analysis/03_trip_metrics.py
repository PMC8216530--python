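"""Trip-level foraging metrics: duration, range, distal bearing, mode shares.

Produces the per-trip table (scratch/) and a per-group mean +- SD summary
(results/trip_metrics_summary.csv) — the synthetic analogue of a tracking
study's trip-characteristics table.
"""
import pandas as pd

from _common import CONFIG, RESULTS, SCRATCH
from sulakit.behaviour import labels_per_fix
from sulakit.trajectories import split_trips, trips_to_metrics_table

fixes = pd.read_csv(SCRATCH / "fixes.csv", parse_dates=["timestamp"])
steps = pd.read_csv(SCRATCH / "steps_labelled.csv")
birds = pd.read_csv(SCRATCH / "truth_bird_traits.csv")

trips = split_trips(fixes, CONFIG.colony_lonlat, CONFIG.colony_radius_km)
labels_by_trip = {}
for t in trips:
    lab = steps.loc[steps["trip_id"] == t.trip_id, "state"].ffill().bfill()
    labels_by_trip[t.trip_id] = labels_per_fix(len(t.fixes), lab)

metrics = trips_to_metrics_table(trips, labels_by_trip, CONFIG.colony_lonlat)
metrics = metrics.merge(birds[["bird_id", "group", "species", "sex", "season"]], on="bird_id")
metrics.to_csv(SCRATCH / "trip_metrics.csv", index=False)

traits = ["duration_h", "max_dist_colony_km", "prop_travel", "prop_forage", "prop_rest"]
summary = metrics.groupby("group")[traits].agg(["mean", "std"]).round(3)
summary.columns = ["_".join(c) for c in summary.columns]
summary.to_csv(RESULTS / "trip_metrics_summary.csv")

print(f"{len(metrics)} trips summarised")
print(summary[["duration_h_mean", "max_dist_colony_km_mean", "prop_forage_mean"]])
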