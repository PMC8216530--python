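# Methods

This note records the models, estimators and design choices behind each
module, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Synthetic data

**What it emulates.** Central-place foraging trips from a tropical island
colony (16.6113°N, 24.5877°W) recorded at a constant 5-minute GPS
interval; six consumer groups (two species × sex × season, red-footed
boobies present only June–October); monthly oceanographic rasters on a
0.08° grid; and plasma/prey isotope tables generated from three prey
source groups through the mixing-model forward equations.

**Movement model.** Each trip is a state-switching correlated random
walk. A four-state Markov chain (rest, forage, travel, relocate) with a
sticky row-stochastic transition matrix drives per-state kinematics:
speeds are normal (travel 35±5, relocate 30±5, forage 8±3, rest 1±0.5
km/h, truncated at a 0.3 km/h drift floor so log-speed has no atom) and
headings update by von Mises turning angles (travel/rest concentrated
near 0; forage/relocate diffuse around ±108°). The published study gives
quadrant semantics, not kinematic values; these defaults were chosen once
as field-plausible sulid values that make the four modes separable in
(log-speed, |turn|), and are configurable. Trips close via a
colony-attraction term blended into the heading, whose weight ramps up
with time in trip; it acts strongly on the directed states and only
weakly (w ≈ 0.05–0.08) on rest/forage, so the per-state turning signature
survives the central-place constraint. Per-bird foraging range and
bearing preferences are drawn around group means (log-normal ×1.2,
±12°), which is what makes trip metrics genuinely repeatable. Ground
truth records the state *departing* each fix — the state that generated
the step measured by the per-step features.

**Not emulated**: GPS positional error, device failure, irregular
sampling, tides/wind, prey fields, or behavioural responses to the
environment (foraging locations are not coupled to the rasters). Passing
tests therefore demonstrate correct statistical machinery and parameter
recovery under the stated generating model, not ecological validity of
any field inference.

**Environment.** One static depth layer plus monthly SST/CHLA/SSH/OMLT on
the 0.08° cell-centered grid; fields are low-order spatial harmonics with
seasonal amplitude modulation plus white noise, so moving-window
gradients are non-trivial. A constant-field switch produces flat layers
(gradients must vanish downstream). Rasters persist as plain-text ESRI
ASCII grids; in memory they are xarray DataArrays.

**Isotopes.** Prey samples are drawn from each source group's printed
moments (epipelagic fish −16.98±0.50‰ δ¹³C, 10.05±0.78‰ δ¹⁵N, n=35;
juvenile fish −18.47±0.24, 8.38±0.43, n=10; squid −17.02±1.56,
11.66±2.18, n=10). Consumers follow the mixing forward model with the
group's true diet; the residual ε defaults to 0.2‰ per isotope, the order
of mass-spectrometric precision. All randomness flows from one seed
through spawned `SeedSequence` children, so tracks, environment and
isotopes are independently reproducible.

## Trip segmentation and metrics

A trip is a maximal run of fixes beyond 1 km of the colony (configurable),
padded with the adjacent at-colony fix on each side; excursions shorter
than 30 min are discarded as logger jitter. Speeds are great-circle step
lengths (sphere radius 6371 km) over time gaps; turns are absolute
smallest signed heading differences in [0, π] — the quadrant semantics
are sign-agnostic. The distal bearing is the initial great-circle bearing
from the colony to the farthest fix. Time budgets are computed over fix
counts, which equals time share under uniform sampling. Reported mode
proportions cover all four states and sum to 1.

## Behavioural clustering

A four-component bivariate Gaussian mixture on (log-speed, |turn|),
fitted by EM (convergence when the log-likelihood gain < 1e-6, cap 300
iterations; singular covariances trigger up to 5 jittered restarts).
Log-speed tames the right skew of speeds; a 0.1 km/h floor keeps it
bounded. After convergence, per-axis delimiters are the midpoints between
the two lower and two upper component means, and components map to
quadrants by a minimum-cost bijection (Hungarian algorithm) against the
quadrant archetype corners those delimiters define. Steps take the
quadrant of their maximum-responsibility component; ties break toward
the heavier component; non-finite features yield missing labels that are
excluded downstream. The fit is pooled across individuals by default
(stabilizes small samples; per-bird fitting is a caller choice). No
temporal smoothing is applied. This module guarantees the
quadrant-semantics contract, not bit-compatibility with any particular
published implementation of binary-delimited clustering.

## Space use

UDs are bivariate Gaussian kernel densities of intensive-foraging
locations evaluated at 0.08° cell centers and normalized to unit mass.
One bandwidth is estimated by least-squares cross-validation on a
designated reference sample (closed-form pairwise-distance score;
bracketed log-scale search refined by Brent) and reused for all groups;
if the score is monotone on the bracket — a known LSCV failure mode —
the bivariate-normal reference bandwidth is used and flagged. Kernels are
geographic (unprojected); at 16.6°N the lon/lat metric anisotropy is
~4%, and an equirectangular `scale_lon` toggle is available.

Isopleths take highest-mass cells until the target mass is reached (ties
included together). BA overlap defaults to isopleth-restricted,
renormalized UDs — this makes the 50% and 95% rows differ — with full-UD
BA available (`level=None`). The randomization test's unit of
exchangeability is the individual (trips within a bird are
autocorrelated): each of the 1000 permutations reassigns whole birds to
groups of the original sizes, recomputing both UDs with the same h and
grid. Because a pooled-points KDE is exactly the count-weighted mixture
of per-bird KDEs, per-bird density grids are precomputed once and each
permutation is a cheap weighted sum. p is the proportion of permuted BA
*strictly below* the observed BA, so small p indicates segregation; under
the complementary relabelling p maps to its one-sided complement.

## Environmental predictors

Proportional change is computed per the printed formula on 3×3 windows,
truncated at raster edges so coastal cells keep gradients. Cells whose
window maximum is ≤ 0 (possible for sea-surface height) or all-missing
are set missing; an offset-to-positive shift can be applied upstream if a
gradient of negative fields is wanted. Depth uses absolute (positive)
meters. Regridding aggregates by block means when coarsening (missing
cells excluded) and interpolates bilinearly when refining; a source
already at target resolution passes through unchanged. Extraction is
nearest-cell, matching raster-resolution habitat analysis. VIF screening
iteratively drops the highest-VIF covariate while any exceeds 3;
VIF_j = 1/(1−R²_j) with perfect collinearity mapped to ∞ and ties broken
by name, making the result column-order independent.

## Repeatability

Moment estimators from the one-way random-effects ANOVA: the
between-individual component S²_A uses the unbalanced-design group size
n₀ = (N − Σnᵢ²/N)/(a−1), truncated at 0. R_ind divides by the unweighted
mean of per-individual variances, R_pop by the pooled within variance —
both as intraclass ratios S²_A/(S²_• + S²_A), the only reading of the
printed formulas that stays in [0, 1]. Uncertainty comes from
bootstrapping individuals with replacement; adjusted repeatability
residualizes fixed effects (sex, season) by OLS first. Moment estimators
were chosen over restricted-likelihood mixed models to keep the module
dependency-light and transparent; at the study's design sizes the two
agree closely (recovery tests at R ∈ {0, 0.5, 1} pass at ±0.05). Bands:
low < 0.25 ≤ moderate < 0.5 ≤ high.

## Isotopic niche and body condition

Layman metrics follow their standard definitions (convex hull area via
Qhull; nearest-neighbour distances exclude self). SEA = π√(λ₁λ₂) from
the sample covariance eigenvalues — the 1-σ ellipse, which contains
1 − e^(−1/2) ≈ 39.35% ("≈40%") of a bivariate-normal population — and
SEAc = SEA·(n−1)/(n−2). SEA_B uses a conjugate normal–inverse-Wishart
model (ν₀ = 3, κ₀ = 1, prior scale = sample covariance, prior mean at
the sample mean), sampling the covariance posterior directly; this is
weakly informative and slightly shrinks small-sample areas. Ellipse
overlap is computed on 720-vertex polygon approximations (error ≪ 0.5%);
the reported proportion is intersection over union of the two ellipse
areas, and the group tables also emit the raw intersection area and
Pr(A narrower than B) from paired SEA_B draws, since "overlap" is used
in all three senses in this literature. The body condition index is the
per-species OLS residual of body mass on wing length.

## Diet mixing

Process-error likelihood (source variances weighted by pₖ²), no
concentration dependence. The TEF is applied additively: corrected mean
= source mean + TEF mean, corrected variance = source SD² + TEF SD² —
the discrimination uncertainty supplements the source spread rather than
replacing it. Priors: Dirichlet(1,…,1) on p (the "no prior information"
choice) and half-Normal(0, 1‰) on each residual ε (configurable).
Sampling is random-walk Metropolis on an unconstrained log-ratio
parameterization of the simplex (softmax gauge fixing the last
coordinate; the Dirichlet prior carries its Jacobian Σlog pₖ) and log ε,
in alternating blocks with Robbins–Monro step adaptation toward ~35%
acceptance during burn-in (steps frozen before any kept draw). Defaults:
4 chains × 5000 iterations, half burn-in; split-R̂ and effective sample
size per parameter via ArviZ, failing loudly when any R̂ > 1.05 unless
convergence checking is disabled for batch runs. Simulation-based
calibration at the study's consumer sample size (n = 40, true diet
0.6/0.3/0.1) gives ≥ 90% coverage of 95% credible intervals over 50
replicates. With three sources whose δ¹³C values nearly coincide
(epipelagic fish vs squid), identifiability rests mostly on δ¹⁵N, and
posteriors are appropriately wide at small n.

## Problem sizes and numerical conventions

The analysis scripts run the design at ~35% of the field deployment
(54 birds, ~260 trips, ~20k steps), which preserves every qualitative
contrast while keeping a full run under a minute per stage on one core.
Distances use a spherical Earth of radius 6371 km; coordinates are
decimal degrees WGS84, lon before lat; timestamps ISO 8601 UTC. UD mass
normalization is exact to 1e-9; BA is computed in double precision and
matches brute-force summation to 1e-12. Isopleth level 1.0 is handled
specially (all positive-mass cells) to avoid cumulative-rounding edge
effects.

## Known limitations

- Foraging is not habitat-driven in the generator, so habitat-model
  exports (`model_ready_covariates.csv`) exercise plumbing, not
  inference; GLMM/GAMM fitting is deliberately out of scope.
- LSCV is known to undersmooth clustered tracking data; the degenerate
  flag and reference fallback mitigate but do not remove this.
- The EM annotator confuses travel with relocate where their speed
  distributions overlap (~20% of those states on default kinematics);
  intensive-foraging recovery, which feeds the UD chain, is ≥99%.
- Geographic (unprojected) kernels slightly anisotropize distances at the
  study latitude (~4%); enable `scale_lon` for metric-equalized kernels.
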