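"""Body condition, Layman metrics, standard ellipses and overlaps."""
import numpy as np
import pandas as pd
import pytest

from sulakit.trophic import (
    Ellipse,
    body_condition_index,
    ellipse_overlap,
    layman_metrics,
    niche_table,
    overlap_table,
    prob_narrower,
    sea_bayes,
    standard_ellipse,
)


class TestBodyCondition:
    def test_perfect_linear_data_gives_zero_residuals(self):
        wing = np.array([380.0, 390.0, 400.0, 410.0, 420.0])
        mass = 100.0 + 3.0 * wing
        res = body_condition_index(mass, wing)
        assert np.allclose(res.bci, 0.0, atol=1e-9)
        assert res.slope == pytest.approx(3.0)

    def test_residuals_sum_to_zero(self, rng):
        wing = rng.normal(400, 10, 30)
        mass = 1200 + 4 * (wing - 400) + rng.normal(0, 50, 30)
        res = body_condition_index(mass, wing)
        assert res.bci.sum() == pytest.approx(0.0, abs=1e-9)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        wing = rng.normal(400, 10, 25)
        mass = 1200 + 4 * (wing - 400) + rng.normal(0, 50, 25)
        res = body_condition_index(mass, wing)
        sxx = ((wing - wing.mean()) ** 2).sum()
        sxy = ((wing - wing.mean()) * (mass - mass.mean())).sum()
        slope = sxy / sxx
        intercept = mass.mean() - slope * wing.mean()
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-8)

    def test_zero_wing_variance_rejected(self):
        with pytest.raises(ValueError):
            body_condition_index([1.0, 2.0, 3.0], [400.0, 400.0, 400.0])


class TestLaymanMetrics:
    def test_unit_square_geometry(self):
        m = layman_metrics([0, 0, 1, 1], [0, 1, 0, 1])
        assert m["TA"] == pytest.approx(1.0)
        assert m["CR"] == m["NR"] == pytest.approx(1.0)
        assert m["NND"] == pytest.approx(1.0)

    def test_centroid_distance_for_symmetric_ring(self):
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        m = layman_metrics(2.0 * np.cos(t), 2.0 * np.sin(t))
        assert m["CD"] == pytest.approx(2.0)

    def test_random_cloud_matches_bruteforce_oracles(self, rng):
        x = rng.normal(-17, 1.0, 12)
        y = rng.normal(11, 1.2, 12)
        m = layman_metrics(x, y)
        assert m["CR"] == pytest.approx(x.max() - x.min())
        assert m["NR"] == pytest.approx(y.max() - y.min())
        pts = np.column_stack([x, y])
        # Hull-area oracle: shapely convex hull (independent implementation)
        from shapely.geometry import MultiPoint

        assert m["TA"] == pytest.approx(MultiPoint(pts.tolist()).convex_hull.area, rel=1e-9)
        cd = np.mean([np.hypot(*(p - pts.mean(0))) for p in pts])
        assert m["CD"] == pytest.approx(cd, rel=1e-9)
        nnd = []
        for i in range(12):
            nnd.append(min(np.hypot(*(pts[i] - pts[j])) for j in range(12) if j != i))
        assert m["NND"] == pytest.approx(np.mean(nnd), rel=1e-9)
        assert m["SDNND"] == pytest.approx(np.std(nnd, ddof=1), rel=1e-9)

    def test_translation_invariance(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        m1 = layman_metrics(x, y)
        m2 = layman_metrics(x + 100.0, y - 42.0)
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], abs=1e-9)

    def test_duplicate_only_data_gives_zero_nnd(self):
        m = layman_metrics([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert m["NND"] == 0.0
        assert m["TA"] == 0.0


class TestStandardEllipse:
    def test_seac_ratio_definitional(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        sea, seac, _ = standard_ellipse(x, y)
        assert seac / sea == pytest.approx(19 / 18)

    def test_large_isotropic_sample_area_approaches_pi(self, rng):
        x, y = rng.normal(size=40000), rng.normal(size=40000)
        sea, _, _ = standard_ellipse(x, y)
        assert sea == pytest.approx(np.pi, rel=0.02)

    def test_rotation_invariance_of_area(self, rng):
        pts = np.column_stack([rng.normal(0, 2, 50), rng.normal(0, 0.5, 50)])
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        r = pts @ rot.T
        sea1, _, _ = standard_ellipse(pts[:, 0], pts[:, 1])
        sea2, _, _ = standard_ellipse(r[:, 0], r[:, 1])
        assert sea1 == pytest.approx(sea2, rel=1e-9)

    def test_coverage_about_40_percent(self, rng):
        """The 1-sigma ellipse contains ~39.35% of fresh bivariate draws."""
        train = rng.multivariate_normal([0, 0], [[2.0, 0.6], [0.6, 1.0]], 1000)
        _, _, ell = standard_ellipse(train[:, 0], train[:, 1])
        test = rng.multivariate_normal([0, 0], [[2.0, 0.6], [0.6, 1.0]], 100_000)
        c, s = np.cos(-ell.theta), np.sin(-ell.theta)
        d = test - ell.center
        u = d[:, 0] * c - d[:, 1] * s
        v = d[:, 0] * s + d[:, 1] * c
        inside = (u / ell.a) ** 2 + (v / ell.b) ** 2 <= 1.0
        assert inside.mean() * 100 == pytest.approx(39.35, abs=2.0)

    def test_singular_data_rejected(self):
        with pytest.raises(ValueError):
            standard_ellipse([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])


class TestSeaBayes:
    def test_posterior_median_tracks_seac_at_large_n(self, rng):
        x = rng.normal(0, 1.5, 400)
        y = 0.3 * x + rng.normal(0, 0.8, 400)
        _, seac, _ = standard_ellipse(x, y)
        draws = sea_bayes(x, y, n_draws=4000, seed=1)
        assert np.median(draws) == pytest.approx(seac, rel=0.05)
        assert (draws > 0).all()

    def test_identical_groups_equal_odds(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        a = sea_bayes(x, y, n_draws=4000, seed=2)
        b = sea_bayes(x, y, n_draws=4000, seed=3)
        assert prob_narrower(a, b) == pytest.approx(0.5, abs=0.05)

    def test_smaller_niche_detected(self, rng):
        """True 2:1 area ratio at n=50: Pr(small narrower) > 0.9."""
        small_x, small_y = rng.normal(0, 1.0, 50), rng.normal(0, 1.0, 50)
        big_x, big_y = rng.normal(0, np.sqrt(2), 50), rng.normal(0, np.sqrt(2), 50)
        a = sea_bayes(small_x, small_y, n_draws=4000, seed=4)
        b = sea_bayes(big_x, big_y, n_draws=4000, seed=5)
        assert prob_narrower(a, b) > 0.9

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            sea_bayes(rng.normal(size=3), rng.normal(size=3))


class TestEllipseOverlap:
    def test_self_overlap_is_one(self):
        e = Ellipse(np.array([0.0, 0.0]), 2.0, 1.0, 0.3)
        area, prop = ellipse_overlap(e, e)
        assert prop == pytest.approx(1.0, rel=1e-6)
        assert area == pytest.approx(e.area, rel=1e-3)

    def test_disjoint_ellipses_zero(self):
        e1 = Ellipse(np.array([0.0, 0.0]), 1.0, 0.5, 0.0)
        e2 = Ellipse(np.array([100.0, 0.0]), 1.0, 0.5, 0.0)
        area, prop = ellipse_overlap(e1, e2)
        assert area == 0.0 and prop == 0.0

    def test_matches_monte_carlo_oracle(self, rng):
        """720-vertex polygon area within 0.5% of a point-in-ellipse MC."""
        e1 = Ellipse(np.array([0.0, 0.0]), 2.0, 1.0, 0.4)
        e2 = Ellipse(np.array([0.8, 0.3]), 1.5, 0.9, -0.6)
        area, _ = ellipse_overlap(e1, e2)
        n = 1_000_000
        lo = np.array([-2.5, -2.2])
        hi = np.array([2.7, 2.3])
        pts = rng.uniform(lo, hi, (n, 2))

        def inside(e, p):
            c, s = np.cos(-e.theta), np.sin(-e.theta)
            d = p - e.center
            u = d[:, 0] * c - d[:, 1] * s
            v = d[:, 0] * s + d[:, 1] * c
            return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0

        mc = inside(e1, pts) & inside(e2, pts)
        mc_area = mc.mean() * np.prod(hi - lo)
        assert area == pytest.approx(mc_area, rel=0.005)

    def test_degenerate_ellipse_rejected(self):
        e1 = Ellipse(np.array([0.0, 0.0]), 1.0, 0.0, 0.0)
        e2 = Ellipse(np.array([0.0, 0.0]), 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ellipse_overlap(e1, e2)


class TestGroupTables:
    def make_samples(self, rng):
        rows = []
        for g, (cx, cy) in {"A": (-17.5, 11.5), "B": (-16.4, 11.0)}.items():
            for i in range(12):
                rows.append(
                    {
                        "individual": f"{g}{i}",
                        "group": g,
                        "d13C": rng.normal(cx, 0.4),
                        "d15N": rng.normal(cy, 0.5),
                    }
                )
        return pd.DataFrame(rows)

    def test_niche_table_columns_and_rows(self, rng):
        tab = niche_table(self.make_samples(rng), seed=0)
        assert set(tab["group"]) == {"A", "B"}
        assert {"CR", "NR", "TA", "CD", "NND", "SDNND", "SEA", "SEAc"} <= set(tab.columns)
        assert (tab["SEAc"] >= tab["SEA"]).all()

    def test_overlap_table_bounds(self, rng):
        tab = overlap_table(self.make_samples(rng), seed=0)
        assert len(tab) == 1
        assert 0 <= tab["overlap_proportion"].iloc[0] <= 1
        assert 0 <= tab["pr_a_narrower"].iloc[0] <= 1
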