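"""Bayesian stable-isotope mixing model for diet proportions.

Consumers' plasma (d13C, d15N) values are modelled as normal around the
diet-weighted mean of discrimination-corrected prey sources, with a
process-error variance that weights each source's variance by the squared
diet proportion:

    x_ij ~ Normal( sum_k p_k (mu_kj + c_j),
                   sum_k p_k^2 (sigma_kj^2 + sigma_c,j^2) + eps_j^2 )

where c is the diet–tissue discrimination factor (TEF) and eps_j a
residual SD per isotope.  The prior is Dirichlet(1,...,1) on p ("no prior
diet information") and half-Normal(0, 1 per mil) on eps.  Sampling is
random-walk Metropolis on log-ratio coordinates of p and log eps, with
multiple chains and split-R-hat convergence checks via ArviZ.
"""
from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .config import TEF, SourceGroup


def tef_correct(sources: list[SourceGroup] | tuple[SourceGroup, ...], tef: TEF) -> list[SourceGroup]:
    """Shift source means by the TEF and add its variance to theirs.

    Corrected mean = source mean + TEF mean; corrected SD =
    sqrt(source SD^2 + TEF SD^2) — the TEF uncertainty is additional to,
    not a replacement of, the source spread.
    """
    out = []
    for s in sources:
        out.append(
            SourceGroup(
                s.name,
                s.mean_d13c + tef.mean_d13c,
                float(np.hypot(s.sd_d13c, tef.sd_d13c)),
                s.mean_d15n + tef.mean_d15n,
                float(np.hypot(s.sd_d15n, tef.sd_d15n)),
                s.n,
            )
        )
    return out


@dataclass
class MixingPosterior:
    """Posterior draws (post burn-in, all chains) and diagnostics."""

    source_names: list[str]
    p: np.ndarray  # (n_chains, n_kept, K) simplex draws
    eps: np.ndarray  # (n_chains, n_kept, 2) residual SDs per isotope
    rhat: dict[str, float]
    ess: dict[str, float]
    accept_rate: float

    @property
    def p_flat(self) -> np.ndarray:
        return self.p.reshape(-1, self.p.shape[-1])


def log_likelihood(
    x: np.ndarray, p: np.ndarray, eps: np.ndarray, mu_c: np.ndarray, var_s: np.ndarray
) -> float:
    """Mixing-model log likelihood of consumers ``x`` (n, 2) at (p, eps).

    ``mu_c`` and ``var_s`` are the TEF-corrected source means and variances,
    shape (K, 2).
    """
    p = np.asarray(p, float)
    mean = p @ mu_c
    var = (p**2) @ var_s + np.asarray(eps, float) ** 2
    z2 = (x - mean) ** 2 / var
    return float((-0.5 * (np.log(2 * np.pi * var) + z2)).sum())


def _log_target_factory(x: np.ndarray, mu_c: np.ndarray, var_s: np.ndarray, eps_prior_sd: float):
    n = len(x)
    s1 = x.sum(axis=0)
    s2 = (x**2).sum(axis=0)

    def log_target(z: np.ndarray, log_eps: np.ndarray) -> float:
        zfull = np.concatenate([z, [0.0]])
        zfull = zfull - zfull.max()
        p = np.exp(zfull)
        p /= p.sum()
        eps = np.exp(log_eps)
        mean = p @ mu_c
        var = (p**2) @ var_s + eps**2
        ll = float(
            (-0.5 * n * np.log(2 * np.pi * var) - 0.5 * (s2 - 2 * mean * s1 + n * mean**2) / var).sum()
        )
        # Dirichlet(1) prior through the log-ratio transform: log|J| = sum log p
        lp = float(np.log(np.maximum(p, 1e-300)).sum())
        # half-Normal(0, sd) on eps, plus the log-eps Jacobian
        lp += float((-0.5 * (eps / eps_prior_sd) ** 2 + np.log(eps)).sum())
        return ll + lp

    return log_target


def fit_mixing(
    consumers: pd.DataFrame,
    sources: list[SourceGroup] | tuple[SourceGroup, ...],
    tef: TEF | None = None,
    n_chains: int = 4,
    n_iter: int = 5000,
    seed: int = 0,
    step: float = 0.25,
    eps_prior_sd: float = 1.0,
    rhat_limit: float = 1.05,
    check_convergence: bool = True,
) -> MixingPosterior:
    """Fit the mixing model to one consumer group's (d13C, d15N) table.

    Half of each chain is burn-in.  Raises if fewer than 3 consumers or 2
    sources, or (when ``check_convergence``) if any split-R-hat exceeds
    ``rhat_limit``.
    """
    x = consumers[["d13C", "d15N"]].to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite consumer values")
    if len(x) < 3:
        raise ValueError("need at least 3 consumers")
    if len(sources) < 2:
        raise ValueError("need at least 2 sources")
    if tef is not None:
        sources = tef_correct(sources, tef)
    mu_c = np.array([[s.mean_d13c, s.mean_d15n] for s in sources])
    var_s = np.array([[s.sd_d13c**2, s.sd_d15n**2] for s in sources])
    k = len(sources)
    log_target = _log_target_factory(x, mu_c, var_s, eps_prior_sd)

    keep = n_iter // 2
    p_draws = np.empty((n_chains, keep, k))
    e_draws = np.empty((n_chains, keep, 2))
    accepts = 0
    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(n_chains)):
        rng = np.random.default_rng(ss)
        z = rng.normal(0.0, 0.5, k - 1)
        le = np.log(np.full(2, 0.5)) + rng.normal(0.0, 0.3, 2)
        lt = log_target(z, le)
        # Alternating block updates (diet coordinates, then residual SDs),
        # each with Robbins–Monro step adaptation toward ~35% acceptance
        # during burn-in; steps are frozen before any kept draw.
        st_z, st_e = step, step
        win_z = win_e = 0
        for it in range(n_iter):
            zp = z + rng.normal(0.0, st_z, k - 1)
            ltp = log_target(zp, le)
            if np.log(rng.uniform()) < ltp - lt:
                z, lt = zp, ltp
                accepts += 1
                win_z += 1
            lep = le + rng.normal(0.0, st_e, 2)
            ltp = log_target(z, lep)
            if np.log(rng.uniform()) < ltp - lt:
                le, lt = lep, ltp
                accepts += 1
                win_e += 1
            if it < n_iter - keep and (it + 1) % 100 == 0:
                st_z *= float(np.exp(win_z / 100 - 0.35))
                st_e *= float(np.exp(win_e / 100 - 0.35))
                win_z = win_e = 0
            if it >= n_iter - keep:
                j = it - (n_iter - keep)
                zfull = np.concatenate([z, [0.0]])
                zfull -= zfull.max()
                p = np.exp(zfull)
                p_draws[c, j] = p / p.sum()
                e_draws[c, j] = np.exp(le)

    names = [s.name for s in sources]
    idata = az.from_dict(
        posterior={
            **{f"p_{nm}": p_draws[:, :, i] for i, nm in enumerate(names)},
            "eps_d13C": e_draws[:, :, 0],
            "eps_d15N": e_draws[:, :, 1],
        }
    )
    rhat = {v: float(az.rhat(idata)[v].values) for v in idata.posterior.data_vars}
    ess = {v: float(az.ess(idata)[v].values) for v in idata.posterior.data_vars}
    worst = max(rhat.values())
    if check_convergence and (not np.isfinite(worst) or worst > rhat_limit):
        raise RuntimeError(f"mixing model did not converge: max R-hat = {worst:.3f}")
    return MixingPosterior(
        names, p_draws, e_draws, rhat, ess, accepts / (2 * n_chains * n_iter)
    )


def summarize_posterior(posterior: MixingPosterior) -> pd.DataFrame:
    """Per-source posterior mean, median and 50%/95% credible intervals."""
    p = posterior.p_flat
    if p.size == 0:
        raise ValueError("empty posterior")
    rows = []
    for i, nm in enumerate(posterior.source_names):
        d = p[:, i]
        q = np.quantile(d, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows.append(
            {
                "source": nm,
                "mean": float(d.mean()),
                "median": float(q[2]),
                "ci50_low": float(q[1]),
                "ci50_high": float(q[3]),
                "ci95_low": float(q[0]),
                "ci95_high": float(q[4]),
            }
        )
    return pd.DataFrame(rows)
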