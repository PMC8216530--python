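"""Variance-components repeatability of trip-level foraging metrics.

Repeatability is the intraclass-correlation-type share of trait variance
attributable to differences between individuals.  Two variants are
reported: the individual-level form R_ind = S2_A / (S2_ind + S2_A), where
S2_ind is the unweighted mean of per-individual variances, and the
population-level form R_pop = S2_A / (S2 + S2_A) with the pooled
within-individual variance S2.  S2_A comes from the one-way
random-effects ANOVA moment estimator with the unbalanced-design group
size n0; negative estimates truncate to zero.  Uncertainty comes from a
bootstrap over individuals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RepeatabilityEstimate:
    r_ind: float
    r_pop: float
    s2_a: float  # inter-individual variance component
    s2_ind: float  # mean within-individual variance
    s2: float  # pooled within-individual variance
    se_r_ind: float
    ci_r_ind: tuple[float, float]
    se_r_pop: float
    ci_r_pop: tuple[float, float]
    n_individuals: int
    n_trips: int

    @property
    def band(self) -> str:
        return classify(self.r_ind)


def classify(r: float) -> str:
    """Repeatability band: low < 0.25 <= moderate < 0.5 <= high."""
    if not np.isfinite(r):
        return "undefined"
    if r < 0.25:
        return "low"
    if r < 0.5:
        return "moderate"
    return "high"


def _components(values: np.ndarray, ids: np.ndarray) -> tuple[float, float, float]:
    """(S2_A, S2_ind, S2) moment estimates from a one-way layout."""
    groups = pd.Series(values).groupby(pd.Series(ids))
    ni = groups.count().to_numpy(float)
    means = groups.mean().to_numpy(float)
    a = len(ni)
    n = ni.sum()
    grand = values.mean()
    ss_within = float(((values - groups.transform("mean").to_numpy()) ** 2).sum())
    ms_within = ss_within / (n - a)
    ss_between = float((ni * (means - grand) ** 2).sum())
    ms_between = ss_between / (a - 1)
    n0 = (n - (ni**2).sum() / n) / (a - 1)  # unbalanced-design group size
    s2_a = max((ms_between - ms_within) / n0, 0.0)
    per_ind_var = groups.var(ddof=1).to_numpy(float)
    s2_ind = float(np.nanmean(per_ind_var))
    return s2_a, s2_ind, ms_within


def estimate_repeatability(
    values,
    ids,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityEstimate:
    """Estimate R_ind and R_pop for one trait measured over repeated trips.

    ``values`` is the trait (one row per trip), ``ids`` the individual of
    each trip.  Requires >= 2 individuals with >= 2 trips each; traits with
    zero total variance are flagged undefined (NaN estimates).  Bootstrap
    resamples individuals with replacement.
    """
    values = np.asarray(values, float)
    ids = np.asarray(ids)
    ok = np.isfinite(values)
    values, ids = values[ok], ids[ok]
    counts = pd.Series(ids).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 individuals with at least 2 trips each")
    keep = np.isin(ids, counts[counts >= 2].index)
    values, ids = values[keep], ids[keep]
    if np.var(values) == 0:
        nan = float("nan")
        return RepeatabilityEstimate(
            nan, nan, 0.0, 0.0, 0.0, nan, (nan, nan), nan, (nan, nan),
            int(pd.Series(ids).nunique()), len(values),
        )
    s2_a, s2_ind, s2 = _components(values, ids)
    r_ind = s2_a / (s2_ind + s2_a) if s2_ind + s2_a > 0 else 1.0
    r_pop = s2_a / (s2 + s2_a) if s2 + s2_a > 0 else 1.0

    rng = np.random.default_rng(seed)
    uniq = np.unique(ids)
    by_id = {u: values[ids == u] for u in uniq}
    boots_ind, boots_pop = [], []
    for _ in range(n_boot):
        sample = rng.choice(uniq, size=len(uniq), replace=True)
        v = np.concatenate([by_id[u] for u in sample])
        g = np.concatenate([np.full(len(by_id[u]), j) for j, u in enumerate(sample)])
        if np.var(v) == 0 or len(np.unique(g)) < 2:
            continue
        ba, bi, bw = _components(v, g)
        boots_ind.append(ba / (bi + ba) if bi + ba > 0 else 1.0)
        boots_pop.append(ba / (bw + ba) if bw + ba > 0 else 1.0)
    bi_arr = np.asarray(boots_ind)
    bp_arr = np.asarray(boots_pop)

    def ci(arr):
        if len(arr) < 10:
            return float("nan"), (float("nan"), float("nan"))
        return float(arr.std(ddof=1)), tuple(np.quantile(arr, [0.025, 0.975]))

    se_i, ci_i = ci(bi_arr)
    se_p, ci_p = ci(bp_arr)
    return RepeatabilityEstimate(
        float(np.clip(r_ind, 0, 1)),
        float(np.clip(r_pop, 0, 1)),
        s2_a,
        s2_ind,
        s2,
        se_i,
        ci_i,
        se_p,
        ci_p,
        int(len(uniq)),
        int(len(values)),
    )


def adjusted_values(values, covariate_frame: pd.DataFrame):
    """Residualize a trait on fixed effects (e.g. sex, season) by OLS.

    Categorical columns are dummy-coded.  Feeding the residuals to
    ``estimate_repeatability`` gives adjusted repeatability — the paper's
    "with fixed effects" variant of the estimate.
    """
    y = np.asarray(values, float)
    xd = pd.get_dummies(covariate_frame, drop_first=True, dtype=float)
    a = np.column_stack([np.ones(len(y)), xd.to_numpy()])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return y - a @ coef


def repeatability_table(
    metrics: pd.DataFrame,
    traits: list[str],
    id_col: str = "bird_id",
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait repeatability summary table for a tidy trip-metrics frame."""
    rows = []
    for j, t in enumerate(traits):
        est = estimate_repeatability(metrics[t], metrics[id_col], n_boot=n_boot, seed=seed + j)
        rows.append(
            {
                "trait": t,
                "R_ind": est.r_ind,
                "R_pop": est.r_pop,
                "SE_R_ind": est.se_r_ind,
                "CI_low": est.ci_r_ind[0],
                "CI_high": est.ci_r_ind[1],
                "band": est.band,
                "n_individuals": est.n_individuals,
                "n_trips": est.n_trips,
            }
        )
    return pd.DataFrame(rows)
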