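"""Expectation–maximization behavioural annotation of (speed, turn) steps.

A four-component bivariate Gaussian mixture is fitted to (log-speed,
absolute turn) by EM, and components are mapped to the four speed/turn
quadrants — LL rest, LH intensive foraging, HL travel, HH relocate — by a
minimum-cost bijection against quadrant archetypes defined by per-axis
delimiters.  This delivers the quadrant-semantics contract of
binary-clustering behavioural annotation without temporal smoothing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

QUADRANTS = ("LL", "LH", "HL", "HH")
QUADRANT_MEANING = {
    "LL": "rest",
    "LH": "forage",
    "HL": "travel",
    "HH": "relocate",
}


@dataclass
class BehaviourModel:
    """Fitted mixture: component moments, per-axis delimiters and the
    component-to-quadrant bijection.  Feature space is (log speed, turn)."""

    means: np.ndarray  # (4, 2)
    covariances: np.ndarray  # (4, 2, 2)
    weights: np.ndarray  # (4,)
    delimiters: tuple[float, float]  # split on log-speed and turn axes
    assignment: dict[int, str]  # component index -> quadrant
    log_likelihoods: list[float] = field(default_factory=list)

    @property
    def speed_delimiter_kmh(self) -> float:
        """Speed split back on the natural km/h scale."""
        return float(np.exp(self.delimiters[0]))

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "weights": self.weights.tolist(),
            "delimiters": list(self.delimiters),
            "assignment": {str(k): v for k, v in self.assignment.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviourModel":
        return cls(
            means=np.asarray(d["means"], float),
            covariances=np.asarray(d["covariances"], float),
            weights=np.asarray(d["weights"], float),
            delimiters=tuple(d["delimiters"]),
            assignment={int(k): v for k, v in d["assignment"].items()},
        )


SPEED_FLOOR_KMH = 0.1  # below GPS jitter; keeps log-speed bounded


def _features(steps: pd.DataFrame) -> np.ndarray:
    x = np.column_stack(
        [
            np.log(np.maximum(steps["speed_kmh"].to_numpy(float), SPEED_FLOOR_KMH)),
            steps["turn_rad"].to_numpy(float),
        ]
    )
    return x


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x - mean
    ic = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    maha = np.einsum("ni,ij,nj->n", d, ic, d)
    return -0.5 * (maha + logdet + 2 * np.log(2 * np.pi))


def _init_means(x: np.ndarray) -> np.ndarray:
    """Quadrant-archetype initialisation: low/high quantiles per axis."""
    lo_s, hi_s = np.quantile(x[:, 0], [0.25, 0.75])
    lo_t, hi_t = np.quantile(x[:, 1], [0.25, 0.75])
    return np.array([[lo_s, lo_t], [lo_s, hi_t], [hi_s, lo_t], [hi_s, hi_t]])


def fit_embc(
    steps: pd.DataFrame,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    max_restarts: int = 5,
) -> BehaviourModel:
    """Fit the four-mode mixture to finite (speed, turn) steps.

    EM runs until the log-likelihood gain drops below ``tol`` or ``max_iter``
    iterations; singular covariances trigger a jittered restart (up to
    ``max_restarts``).  After convergence, per-axis delimiters are the
    midpoints between the two lower and two upper component means, and
    components are assigned to quadrants by a minimum-cost bijection.
    """
    x = _features(steps)
    x = x[np.isfinite(x).all(axis=1)]
    if len(x) < 50:
        raise ValueError("need at least 50 finite (speed, turn) steps")
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        try:
            means = _init_means(x)
            if attempt > 0:
                means = means + rng.normal(0.0, 0.25 * x.std(axis=0), means.shape)
            covs = np.stack([np.cov(x.T) / 4 + 1e-4 * np.eye(2)] * 4)
            weights = np.full(4, 0.25)
            lls: list[float] = []
            for _ in range(max_iter):
                logp = np.stack(
                    [np.log(weights[k]) + _log_gauss(x, means[k], covs[k]) for k in range(4)],
                    axis=1,
                )
                m = logp.max(axis=1, keepdims=True)
                lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
                ll = float(lse.sum())
                resp = np.exp(logp - lse[:, None])
                nk = resp.sum(axis=0)
                if np.any(nk < 1e-8):
                    raise np.linalg.LinAlgError("empty component")
                weights = nk / len(x)
                means = (resp.T @ x) / nk[:, None]
                for k in range(4):
                    d = x - means[k]
                    covs[k] = (resp[:, k, None] * d).T @ d / nk[k] + 1e-8 * np.eye(2)
                    if np.linalg.det(covs[k]) < 1e-12:
                        raise np.linalg.LinAlgError("singular covariance")
                if lls and ll - lls[-1] < tol:
                    lls.append(ll)
                    break
                lls.append(ll)
            break
        except np.linalg.LinAlgError as err:  # degenerate fit: restart
            last_err = err
    else:
        raise RuntimeError(f"EM failed after {max_restarts} restarts: {last_err}")

    delim = tuple(
        float((np.sort(means[:, j])[1] + np.sort(means[:, j])[2]) / 2) for j in range(2)
    )
    archetypes = {
        "LL": (0, 0),
        "LH": (0, 1),
        "HL": (1, 0),
        "HH": (1, 1),
    }
    # Cost of putting component k in quadrant q: distance from the component
    # mean to the quadrant's archetype corner (axis spans from the data).
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    corners = {
        q: np.array(
            [
                (lo[0] + delim[0]) / 2 if a == 0 else (delim[0] + hi[0]) / 2,
                (lo[1] + delim[1]) / 2 if b == 0 else (delim[1] + hi[1]) / 2,
            ]
        )
        for q, (a, b) in archetypes.items()
    }
    cost = np.array([[np.linalg.norm(means[k] - corners[q]) for q in QUADRANTS] for k in range(4)])
    rows, cols = linear_sum_assignment(cost)
    assignment = {int(r): QUADRANTS[c] for r, c in zip(rows, cols)}
    return BehaviourModel(means, covs, weights, delim, assignment, lls)


def label_steps(steps: pd.DataFrame, model: BehaviourModel) -> pd.Series:
    """Quadrant label per step from maximum component responsibility.

    Non-finite feature rows get a missing label; the output index matches
    the input row for row count preservation.  Ties go to the component
    with the larger mixture weight.
    """
    x = _features(steps)
    finite = np.isfinite(x).all(axis=1)
    labels = pd.Series(pd.NA, index=steps.index, dtype="object")
    if finite.any():
        xf = x[finite]
        logp = np.stack(
            [
                np.log(model.weights[k]) + _log_gauss(xf, model.means[k], model.covariances[k])
                for k in range(4)
            ],
            axis=1,
        )
        # Stable tie-break: add an epsilon preference for heavier components.
        order = np.argsort(-model.weights)
        pref = np.empty(4)
        pref[order] = -1e-12 * np.arange(4)
        best = np.argmax(logp + pref, axis=1)
        labels.loc[finite] = [model.assignment[int(k)] for k in best]
    return labels


def label_states(steps: pd.DataFrame, model: BehaviourModel) -> pd.Series:
    """Behavioural-state names (rest/forage/travel/relocate) per step."""
    quad = label_steps(steps, model)
    return quad.map(lambda q: QUADRANT_MEANING.get(q) if isinstance(q, str) else pd.NA)


def labels_per_fix(trip_fixes_len: int, step_labels: pd.Series) -> np.ndarray:
    """Expand per-step labels to per-fix labels for one trip.

    Fix i inherits step i's label (the step leaving it); the final fix
    inherits the last step's label, and the first fix its first step's.
    """
    lab = step_labels.to_numpy(object)
    if trip_fixes_len != len(lab) + 1:
        raise ValueError("expected one fewer step than fixes")
    return np.concatenate([lab, lab[-1:]])
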