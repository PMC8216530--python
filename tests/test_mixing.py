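"""Bayesian mixing model: TEF correction, likelihood, posterior behaviour."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sulakit.config import DEFAULT_SOURCES, SourceGroup, TEF
from sulakit.mixing import (
    fit_mixing,
    log_likelihood,
    summarize_posterior,
    tef_correct,
)


def forward_sample(rng, p, sources, tef, n, eps=0.2):
    mu = np.array([[s.mean_d13c, s.mean_d15n] for s in sources])
    sd = np.array([[s.sd_d13c, s.sd_d15n] for s in sources])
    c = np.array([tef.mean_d13c, tef.mean_d15n])
    c_sd = np.array([tef.sd_d13c, tef.sd_d15n])
    p = np.asarray(p, float)
    mean = p @ (mu + c)
    var = (p**2) @ (sd**2 + c_sd**2) + eps**2
    draws = rng.normal(mean, np.sqrt(var), (n, 2))
    return pd.DataFrame({"d13C": draws[:, 0], "d15N": draws[:, 1]})


class TestTefCorrect:
    def test_d15n_means_shift_by_default_tef(self):
        out = tef_correct(DEFAULT_SOURCES, TEF())
        for before, after in zip(DEFAULT_SOURCES, out):
            assert after.mean_d15n == pytest.approx(before.mean_d15n + 1.72)
            assert after.mean_d13c == pytest.approx(before.mean_d13c - 0.18)

    def test_zero_tef_is_identity(self):
        zero = TEF(0.0, 0.0, 0.0, 0.0)
        out = tef_correct(DEFAULT_SOURCES, zero)
        for before, after in zip(DEFAULT_SOURCES, out):
            assert after.mean_d13c == before.mean_d13c
            assert after.sd_d15n == before.sd_d15n

    def test_squid_d15n_sd_closed_form(self):
        out = tef_correct(DEFAULT_SOURCES, TEF())
        squid = next(s for s in out if s.name == "squid")
        assert squid.sd_d15n == pytest.approx(np.sqrt(2.18**2 + 1.0**2), abs=1e-12)


class TestLikelihood:
    def test_matches_per_observation_normal_oracle(self, rng):
        """Vectorized likelihood equals a naive loop of normal logpdfs."""
        sources = tef_correct(DEFAULT_SOURCES, TEF())
        mu_c = np.array([[s.mean_d13c, s.mean_d15n] for s in sources])
        var_s = np.array([[s.sd_d13c**2, s.sd_d15n**2] for s in sources])
        x = rng.normal([-17.0, 11.0], 1.0, (15, 2))
        for _ in range(10):
            p = rng.dirichlet(np.ones(3))
            eps = rng.uniform(0.05, 1.5, 2)
            mean = p @ mu_c
            sd = np.sqrt((p**2) @ var_s + eps**2)
            naive = sum(
                norm.logpdf(x[i, j], mean[j], sd[j]) for i in range(15) for j in range(2)
            )
            ours = log_likelihood(x, p, eps, mu_c, var_s)
            assert ours == pytest.approx(naive, abs=1e-10)


@pytest.fixture(scope="module")
def symmetric_sources():
    return (
        SourceGroup("s1", -18.0, 0.5, 9.0, 0.5, 5),
        SourceGroup("s2", -16.0, 0.5, 9.0, 0.5, 5),
        SourceGroup("s3", -17.0, 0.5, 11.0, 0.5, 5),
    )


class TestFitMixing:
    def test_symmetric_sources_give_equal_thirds(self, symmetric_sources):
        """Consumers at the source centroid: posterior means near 1/3 each."""
        rng = np.random.default_rng(0)
        zero_tef = TEF(0.0, 0.0, 0.0, 0.0)
        center = np.array([-17.0, 29.0 / 3.0])
        cons = pd.DataFrame(
            {
                "d13C": rng.normal(center[0], 0.15, 30),
                "d15N": rng.normal(center[1], 0.15, 30),
            }
        )
        post = fit_mixing(cons, symmetric_sources, zero_tef, n_iter=4000, seed=1)
        means = post.p_flat.mean(axis=0)
        assert np.abs(means - 1 / 3).max() < 0.08

    def test_single_source_identified_when_sds_shrunk(self):
        sources = tuple(
            SourceGroup(s.name, s.mean_d13c, s.sd_d13c / 10, s.mean_d15n, s.sd_d15n / 10, s.n)
            for s in DEFAULT_SOURCES
        )
        tef = TEF(sd_d13c=0.1, sd_d15n=0.1)
        rng = np.random.default_rng(2)
        # consumers exactly at corrected epipelagic mean
        cons = pd.DataFrame(
            {
                "d13C": rng.normal(-16.98 - 0.18, 0.05, 25),
                "d15N": rng.normal(10.05 + 1.72, 0.05, 25),
            }
        )
        post = fit_mixing(cons, sources, tef, n_iter=4000, seed=3)
        p_epi = post.p_flat[:, 0].mean()
        assert p_epi > 0.9

    def test_posterior_draws_on_simplex(self, symmetric_sources):
        rng = np.random.default_rng(4)
        cons = forward_sample(rng, (0.5, 0.3, 0.2), symmetric_sources, TEF(), 20)
        post = fit_mixing(cons, symmetric_sources, TEF(), n_iter=2000, seed=5, check_convergence=False)
        p = post.p_flat
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_credible_interval_coverage(self):
        """Simulation-based calibration: 95% CIs cover each true proportion
        in >= 90% of 50 seeded replicates."""
        sources = DEFAULT_SOURCES
        tef = TEF()
        true_p = np.array([0.6, 0.3, 0.1])
        covered = np.zeros(3)
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            cons = forward_sample(rng, true_p, sources, tef, 40)
            post = fit_mixing(
                cons, sources, tef, n_chains=2, n_iter=3000, seed=rep, check_convergence=False
            )
            lo = np.quantile(post.p_flat, 0.025, axis=0)
            hi = np.quantile(post.p_flat, 0.975, axis=0)
            covered += (lo <= true_p) & (true_p <= hi)
        assert (covered / reps >= 0.90).all()

    def test_posterior_concentrates_with_sample_size(self, symmetric_sources):
        zero_tef = TEF(0.0, 0.0, 0.0, 0.0)
        devs = []
        for n in (10, 160):
            rng = np.random.default_rng(7)
            center = np.array([-17.0, 29.0 / 3.0])
            cons = pd.DataFrame(
                {
                    "d13C": rng.normal(center[0], 0.3, n),
                    "d15N": rng.normal(center[1], 0.3, n),
                }
            )
            post = fit_mixing(cons, symmetric_sources, zero_tef, n_iter=3000, seed=8, check_convergence=False)
            devs.append(np.abs(post.p_flat.mean(axis=0) - 1 / 3).max())
        assert devs[1] <= devs[0] + 0.02

    def test_nonfinite_consumers_rejected(self, symmetric_sources):
        cons = pd.DataFrame({"d13C": [np.nan, -17.0, -17.0], "d15N": [11.0, 11.0, 11.0]})
        with pytest.raises(ValueError):
            fit_mixing(cons, symmetric_sources)

    def test_rhat_reported_per_parameter(self, symmetric_sources):
        rng = np.random.default_rng(9)
        cons = forward_sample(rng, (0.4, 0.4, 0.2), symmetric_sources, TEF(), 25)
        post = fit_mixing(cons, symmetric_sources, TEF(), n_iter=3000, seed=10, check_convergence=False)
        assert set(post.rhat) == {"p_s1", "p_s2", "p_s3", "eps_d13C", "eps_d15N"}
        assert all(np.isfinite(v) for v in post.rhat.values())


class TestSummaries:
    def make_posterior(self, symmetric_sources):
        rng = np.random.default_rng(11)
        cons = forward_sample(rng, (0.5, 0.3, 0.2), symmetric_sources, TEF(), 25)
        return fit_mixing(cons, symmetric_sources, TEF(), n_iter=2000, seed=12, check_convergence=False)

    def test_mean_proportions_sum_to_one(self, symmetric_sources):
        summ = summarize_posterior(self.make_posterior(symmetric_sources))
        assert summ["mean"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_median_inside_50_interval(self, symmetric_sources):
        summ = summarize_posterior(self.make_posterior(symmetric_sources))
        assert (summ["ci50_low"] <= summ["median"]).all()
        assert (summ["median"] <= summ["ci50_high"]).all()

    def test_intervals_match_quantile_oracle(self, symmetric_sources):
        post = self.make_posterior(symmetric_sources)
        summ = summarize_posterior(post)
        for i, row in summ.iterrows():
            d = np.sort(post.p_flat[:, i])
            assert row["ci95_low"] == pytest.approx(np.quantile(d, 0.025), abs=1e-12)
            assert row["ci95_high"] == pytest.approx(np.quantile(d, 0.975), abs=1e-12)
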