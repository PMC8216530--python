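# sulakit

Movement and trophic ecology of sympatric central-place foraging seabirds,
as a tested, reusable Python pipeline. The package covers the full
analytical chain of a GPS-tracking + stable-isotope study of two booby
species (*Sula* spp.) sharing a tropical colony:

1. **Trip segmentation** of 5-minute GPS fix streams into central-place
   foraging trips, with trip metrics (duration, maximum colony distance,
   distal bearing, behavioural time budgets).
2. **Behavioural annotation** by expectation–maximization clustering of
   per-step (log-speed, turning angle) into the four speed/turn quadrants:
   LL rest, LH intensive foraging, HL travel, HH relocate.
3. **Space use**: kernel utilization distributions (UDs) of
   intensive-foraging locations on a 0.08° grid with an LSCV bandwidth,
   50% (core foraging region) and 95% (home range) isopleths,
   Bhattacharyya's affinity overlap BA = Σ√(p₁p₂), and a randomization
   test that reassigns whole individuals between groups (p = proportion of
   permuted overlaps smaller than observed).
4. **Environmental predictors**: regridding, moving-window proportional
   change PC = (max − min)·100/max over 3×3 cells (ocean-front and slope
   proxies), nearest-cell extraction at fixes, and iterative VIF screening
   (threshold 3).
5. **Repeatability** of trip metrics from one-way variance components:
   R_ind = S²_A/(S²_ind + S²_A) and R_pop = S²_A/(S² + S²_A), with
   bootstrap CIs over individuals.
6. **Isotopic niche**: Layman metrics (CR, NR, TA, CD, NND, SDNND),
   standard ellipse areas SEA/SEAc (≈40% coverage) with a Bayesian
   posterior variant SEA_B, pairwise ellipse overlap, and a body condition
   index (mass-on-wing-length residuals).
7. **Diet mixing**: a Bayesian stable-isotope mixing model
   xᵢⱼ ~ N(Σₖ pₖ(μₖⱼ+cⱼ), Σₖ pₖ²(σₖⱼ²+σ²_c,j) + εⱼ²) over three prey
   groups (epipelagic fish, juvenile fish, squid) with a plasma
   diet–tissue discrimination factor (−0.18‰ δ¹³C, +1.72‰ δ¹⁵N, SD 1.0‰)
   and a flat Dirichlet prior.

Because the original field data are not public, a first-class
**synthetic-data module** generates GPS tracks (state-switching correlated
random walks from the colony), monthly environmental rasters, and
consumer/prey isotope tables with known ground truth, so every stage can
be validated by parameter recovery.

## Worked example

```python
import pandas as pd
from sulakit.config import default_config
from sulakit.synthetic import generate_tracks
from sulakit.trajectories import split_trips, step_features
from sulakit.behaviour import fit_embc, label_states

cfg = default_config(seed=42, scale=0.35)
fixes, truth = generate_tracks(cfg)
trips = split_trips(fixes, cfg.colony_lonlat, cfg.colony_radius_km)
steps = pd.concat([step_features(t) for t in trips], ignore_index=True)
model = fit_embc(steps, seed=42)
steps["state"] = label_states(steps, model)
print(len(trips), "trips,", len(steps), "steps")
print("speed delimiter %.1f km/h" % model.speed_delimiter_kmh)
print(steps["state"].value_counts(normalize=True).round(3))
```

prints

```
262 trips, 20112 steps
speed delimiter 15.9 km/h
state
travel      0.341
forage      0.308
rest        0.237
relocate    0.113
```

i.e. the fitted mixture splits speed at ~16 km/h, and the labelled time
budget recovers the simulator's stationary behavioural mix (34% travel,
33% forage, 22% rest, 11% relocate). Against the generator's hidden
states, 89% of at-sea steps are labelled correctly (99% for intensive
foraging, the class that feeds the UD analysis).

The full chain — simulation through diet mixing — lives in the numbered
scripts under `analysis/`; run them in order from the repository root.
Summary tables land in `results/` (overlap tests, repeatability,
niche metrics, diet posteriors), bulky intermediates in `scratch/`.
`sulakit.pipeline.run_pipeline` performs the same chain in one call and
writes a manifest with the seed and config hash.

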