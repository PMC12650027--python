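"""Homing tests, trajectory metrics, statistics and weight dynamics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_rel

from learnwalks.agent import TrajectoryRecord
from learnwalks.experiments import (BioBounds, NoveltyField,
                                    build_feature_grid, coverage_area,
                                    holm_adjust, homing_test, max_distance,
                                    paired_cohens_d, paired_stats,
                                    release_grid, success_curves,
                                    turning_stats, weight_dynamics,
                                    within_bounds_fraction)
from learnwalks.mbvision import MBNetwork, kc_activation, mb_learn


class TestReleaseGrid:
    def test_sixty_four_points(self):
        grid = release_grid()
        assert grid.points.shape == (64, 2)

    def test_geometry(self):
        grid = release_grid()
        assert np.allclose(np.hypot(*grid.points.T), grid.distances)
        assert set(np.round(grid.distances, 6)) == set(map(float, range(1, 9)))
        assert np.allclose(sorted(set(np.round(np.degrees(grid.angles), 6))),
                           np.arange(0, 360, 45))


class TestMetrics:
    def test_unit_square_area(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        assert coverage_area(pts) == pytest.approx(1.0)

    def test_collinear_path_has_zero_area(self):
        pts = np.stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)], axis=1)
        assert coverage_area(pts) == 0.0

    def test_hull_matches_shoelace_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, size=(60, 2))
        # independent oracle: shoelace on the hull polygon found by angle sort
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        x, y = poly[:, 0], poly[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert coverage_area(pts) == pytest.approx(shoelace, rel=1e-12)

    def test_max_distance_on_circle(self):
        theta = np.linspace(0, 2 * math.pi, 100)
        pts = 0.3 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        assert max_distance(pts) == pytest.approx(0.3)

    def test_straight_path_zero_turning(self):
        assert turning_stats(np.full(50, 0.7)) == 0.0

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_regular_polygon_turning(self, n):
        headings = np.cumsum(np.full(3 * n, 2 * math.pi / n))
        assert turning_stats(headings) == pytest.approx(2 * math.pi / n)

    def test_turning_wraps_heading_jumps(self):
        headings = np.array([math.pi - 0.05, -math.pi + 0.05])  # 0.1 rad turn
        assert turning_stats(headings) == pytest.approx(0.1)


class TestBioBounds:
    def test_band_construction(self):
        b = BioBounds.default()
        assert b.area[0] == (0.07, 0.035)
        assert b.dist[0] == (0.184, 0.0636)
        assert b.area[1][0] == pytest.approx(0.56)  # x8
        assert b.dist[1][0] == pytest.approx(0.6992)  # x3.8
        assert b.dist[3][0] == pytest.approx(2.7968)
        # sds scale proportionally with the means
        assert b.dist[1][1] / b.dist[0][1] == pytest.approx(3.8)

    def test_within_bounds_matches_hand_count(self):
        metrics = pd.DataFrame([
            {"walk": 1, "area": 0.07, "max_dist": 0.184},   # both inside
            {"walk": 1, "area": 0.7, "max_dist": 1.84},     # both outside
            {"walk": 2, "area": 0.56, "max_dist": 0.1},     # area in, dist out
            {"walk": 4, "area": 100.0, "max_dist": 2.8},    # area out, dist in
        ])
        frac = within_bounds_fraction(metrics)
        assert frac["area"] == pytest.approx(2 / 4)
        assert frac["max_dist"] == pytest.approx(2 / 4)

    def test_all_at_mean_fully_inside(self):
        b = BioBounds.default()
        rows = [{"walk": w, "area": b.area[w - 1][0], "max_dist": b.dist[w - 1][0]}
                for w in range(1, 5) for _ in range(10)]
        frac = within_bounds_fraction(pd.DataFrame(rows))
        assert frac == {"area": 1.0, "max_dist": 1.0}


class TestSuccessCurves:
    def _outcomes(self, success_by_dist):
        grid = release_grid()
        return pd.DataFrame({
            "dist_m": grid.distances,
            "success": [success_by_dist(d) for d in grid.distances]})

    def test_all_success(self):
        rates = success_curves(self._outcomes(lambda d: 1))
        assert rates == {"near": 1.0, "far": 1.0, "overall": 1.0}

    def test_near_only(self):
        rates = success_curves(self._outcomes(lambda d: int(d <= 4)))
        assert rates == {"near": 1.0, "far": 0.0, "overall": 0.5}

    def test_synthetic_pattern_matches_manual_count(self):
        rates = success_curves(self._outcomes(lambda d: int(d in (1, 5, 6))))
        assert rates["near"] == pytest.approx(8 / 32)
        assert rates["far"] == pytest.approx(16 / 32)
        assert rates["overall"] == pytest.approx(24 / 64)


class TestHolm:
    def test_matches_hand_worked_example(self):
        # classic worked example: sorted p (0.01, 0.02, 0.03, 0.04) with m=4
        p = [0.04, 0.01, 0.03, 0.02]
        adj = holm_adjust(p)
        assert np.allclose(adj, [0.06, 0.04, 0.06, 0.06])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, 6)
            assert (holm_adjust(p) >= p - 1e-15).all()

    def test_monotone_in_rank(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.5, 0.9])
        adj = holm_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()


class TestPairedStats:
    def _rates(self, cols):
        return pd.DataFrame({w: np.asarray(v, dtype=float)
                             for w, v in cols.items()})

    def test_identical_rates_give_null_result(self):
        rates = self._rates({w: [0.5] * 10 for w in (1, 2, 3, 4)})
        out = paired_stats(rates)
        assert (out["p_raw"] == 1.0).all()
        assert (out["effect"] == 0.0).all()

    def test_constant_shift_flags_degenerate_effect(self):
        base = np.linspace(0.1, 0.9, 10)
        rates = self._rates({1: base, 2: base + 0.1, 3: base, 4: base})
        out = paired_stats(rates, comparisons=[(2, 1)])
        assert np.isinf(out["effect"].iloc[0])

    def test_requires_three_agents(self):
        with pytest.raises(ValueError):
            paired_stats(self._rates({1: [0.1, 0.2], 4: [0.3, 0.4]}),
                         comparisons=[(4, 1)])

    def test_t_branch_matches_scipy_directly(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 0.1, 10)
        b = a + rng.normal(0.15, 0.05, 10)
        out = paired_stats(self._rates({1: a, 4: b}), comparisons=[(4, 1)])
        row = out.iloc[0]
        if row["method"] == "t-test":
            res = ttest_rel(b, a)
            assert row["statistic"] == pytest.approx(res.statistic)
            assert row["p_raw"] == pytest.approx(res.pvalue)

    def test_p_value_matches_permutation_oracle(self):
        """The parametric paired test agrees with a sign-flip permutation
        oracle on small Gaussian data."""
        rng = np.random.default_rng(11)
        a = rng.normal(0.4, 0.05, 10)
        b = a + rng.normal(0.06, 0.04, 10)
        out = paired_stats(self._rates({1: a, 4: b}), comparisons=[(4, 1)])
        diff = b - a
        t_obs = abs(diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff))))
        # exact enumeration of all 2^10 sign flips
        count = 0
        total = 2 ** len(diff)
        for mask in range(total):
            signs = np.array([1 if mask >> k & 1 else -1
                              for k in range(len(diff))])
            d = diff * signs
            t = abs(d.mean() / (d.std(ddof=1) / math.sqrt(len(d))))
            count += t >= t_obs - 1e-12
        p_perm = count / total
        assert out["p_raw"].iloc[0] == pytest.approx(p_perm, abs=0.03)

    def test_known_effect_recovered(self):
        """dz estimates concentrate near the true standardised shift."""
        rng = np.random.default_rng(5)
        true_dz = 1.0
        estimates = []
        for _ in range(300):
            diff = rng.normal(1.0, 1.0, 10)  # dz = 1
            estimates.append(diff.mean() / diff.std(ddof=1))
        # dz is biased upward at n=10 by roughly 1/(1 - 3/(4n - 5)) ~ 1.09
        assert np.mean(estimates) == pytest.approx(true_dz, abs=0.2)
        a = rng.normal(0.5, 0.08, 10)
        d = rng.normal(0.08, 0.08, 10)
        assert paired_cohens_d(a + d, a) == pytest.approx(
            d.mean() / d.std(ddof=1))

    def test_holm_family_is_six_comparisons(self):
        rng = np.random.default_rng(2)
        rates = self._rates({w: rng.uniform(0, 1, 10) for w in (1, 2, 3, 4)})
        out = paired_stats(rates)
        assert len(out) == 6
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()


class TestWeightDynamics:
    def _record(self, weights, walk=1):
        n = len(weights)
        rows = pd.DataFrame({
            "step": np.arange(n), "x": np.zeros(n), "y": np.zeros(n),
            "heading": np.zeros(n),
            "w_v": [w[0] for w in weights], "w_olf": [w[1] for w in weights],
            "w_pi": [w[2] for w in weights],
            "phi": np.zeros(n), "scan": 0, "random": 0, "ac": 1})
        return TrajectoryRecord(rows=rows, meta={"walk_index": walk,
                                                 "np_j": n, "iscan": 1,
                                                 "n_scans": 0,
                                                 "completed": True,
                                                 "seed": 0,
                                                 "n_reflections": 0})

    def test_constant_weights_give_flat_quartiles(self):
        rec = self._record([(0.2, 0.3, 0.5)] * 40)
        out = weight_dynamics([[rec]])
        q = out["quartiles"][1]
        assert np.allclose(q[25], q[75])
        assert np.allclose(q[50][:, 0], 20.0)
        assert out["walk_means"][1]["w_pi"] == pytest.approx(50.0)

    def test_two_phase_boundary_recovered(self):
        weights = [(0.0, 1.0, 0.0)] * 50 + [(0.0, 0.0, 1.0)] * 50
        rec = self._record(weights)
        out = weight_dynamics([[rec]])
        med_olf = out["quartiles"][1][50][:, 1]
        crossing = int(np.argmax(med_olf < 50.0))
        assert abs(crossing - 50) <= 2

    def test_shares_sum_to_hundred(self):
        rng = np.random.default_rng(1)
        weights = [tuple(rng.uniform(0.05, 1, 3)) for _ in range(30)]
        out = weight_dynamics([[self._record(weights)]])
        q50 = out["quartiles"][1][50]
        assert np.allclose(q50.sum(axis=1), 100.0)


class TestHomingTest:
    def test_outcome_grid_has_64_entries(self, small_env, small_series):
        _, snapshots, _ = small_series
        fgrid = build_feature_grid(small_env, radius=3.7, spacing=0.25)
        field = NoveltyField(fgrid, snapshots[0])
        out = homing_test(snapshots[0], small_env, field, release_grid(),
                          np.random.default_rng(0))
        assert len(out) == 64
        assert set(out.columns) >= {"agent", "walks", "dist_m", "angle_deg",
                                    "success", "steps"}

    def test_saturated_memory_guides_close_release_home(self, small_env):
        """A memory fully saturated over the central disc leaves a flat
        (uninformative) visual field inside it, so the recall agent falls
        back on the olfactory gradient and reaches the nest."""
        cfg = small_env.cfg
        net = MBNetwork.create(n_vpn=cfg.mb.n_vpn, n_kc=cfg.mb.n_kc,
                               fan_in=cfg.mb.fan_in, theta_kc=cfg.mb.theta_kc,
                               lambda_vis=1.0, seed=2)  # one-shot saturation
        for x in np.arange(-1.2, 1.21, 0.2):
            for y in np.arange(-1.2, 1.21, 0.2):
                if math.hypot(x, y) > 1.25:
                    continue
                active = kc_activation(net, small_env.features((x, y)),
                                       cfg.mb.feature_norm)
                mb_learn(net, active)
        fgrid = build_feature_grid(small_env, radius=2.0, spacing=0.2)
        field = NoveltyField(fgrid, net)
        from learnwalks.experiments import ReleaseGrid
        grid = ReleaseGrid(points=np.array([[0.5, 0.0], [0.0, -0.5]]),
                           distances=np.array([0.5, 0.5]),
                           angles=np.array([0.0, -math.pi / 2]))
        out = homing_test(net, small_env, field, grid,
                          np.random.default_rng(3))
        assert out["success"].sum() >= 1

    def test_untrained_far_release_fails(self, small_env):
        cfg = small_env.cfg
        net = MBNetwork.create(n_vpn=cfg.mb.n_vpn, n_kc=cfg.mb.n_kc,
                               fan_in=cfg.mb.fan_in, theta_kc=cfg.mb.theta_kc,
                               lambda_vis=cfg.mb.lambda_vis, seed=2)
        fgrid = build_feature_grid(small_env, radius=3.7, spacing=0.3)
        field = NoveltyField(fgrid, net)
        from learnwalks.experiments import ReleaseGrid
        grid = ReleaseGrid(points=np.array([[3.5, 0.0]]),
                           distances=np.array([3.5]), angles=np.array([0.0]))
        out = homing_test(net, small_env, field, grid,
                          np.random.default_rng(0))
        assert out["success"].iloc[0] == 0
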