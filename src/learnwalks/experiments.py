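"""Experimental harness: homing tests, trajectory metrics and statistics.

Reproduces the study protocol around the simulator: frozen-memory homing
tests from a 64-point release grid (8 distances x 8 bearings), trajectory
metrics (convex-hull coverage area, maximum distance, turning angle) with
their comparison against empirical per-walk bands, paired statistics with
a normality gate and Holm correction, the reduced-vision species contrast,
and the per-step cue-weight dynamics.

For recall tests the MB memory is frozen, so the MBON novelty over space
is a fixed scalar field; it is precomputed once on a grid and interpolated
during navigation, which makes the 64 x n_agents test runs cheap while the
learned memory itself stays untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import shapiro, ttest_rel, wilcoxon

from .agent import Environment, TrajectoryRecord, run_walk_series
from .config import SimConfig
from .cues import olf_familiarity, olf_homing_direction
from .lvector import WeightTriple, homing_vector
from .mbvision import MBNetwork, kc_activation, _normalize_features
from .world import wrap_angle

__all__ = [
    "ReleaseGrid",
    "release_grid",
    "BioBounds",
    "FeatureGrid",
    "NoveltyField",
    "build_feature_grid",
    "homing_test",
    "coverage_area",
    "max_distance",
    "turning_stats",
    "walk_metrics",
    "within_bounds_fraction",
    "success_curves",
    "paired_stats",
    "holm_adjust",
    "species_compare",
    "weight_dynamics",
    "run_cohort",
]

TABLE_COMPARISONS = [(2, 1), (3, 2), (4, 3), (3, 1), (4, 2), (4, 1)]


# ---------------------------------------------------------------------------
# Release grid
# ---------------------------------------------------------------------------

@dataclass
class ReleaseGrid:
    """8 distances x 8 bearings = 64 release points around the nest."""

    points: np.ndarray  # (64, 2)
    distances: np.ndarray  # per-point release distance [m]
    angles: np.ndarray  # per-point bearing [rad]


def release_grid(distances: Sequence[float] = tuple(range(1, 9)),
                 n_angles: int = 8) -> ReleaseGrid:
    ds, angs, pts = [], [], []
    for d in distances:
        for k in range(n_angles):
            a = 2 * math.pi * k / n_angles
            pts.append((d * math.cos(a), d * math.sin(a)))
            ds.append(d)
            angs.append(a)
    return ReleaseGrid(points=np.array(pts), distances=np.array(ds),
                       angles=np.array(angs))


# ---------------------------------------------------------------------------
# Frozen-memory novelty field
# ---------------------------------------------------------------------------

@dataclass
class FeatureGrid:
    """Zernike features pre-rendered on a square position grid (memory-
    independent, so shared by all agents living in one world)."""

    xs: np.ndarray
    ys: np.ndarray
    features: np.ndarray  # (ny, nx, n_vpn), min-max normalised per cell


def build_feature_grid(env: Environment, radius: Optional[float] = None,
                       spacing: float = 0.15) -> FeatureGrid:
    if radius is None:  # cover the release grid, but stay inside the world
        radius = min(8.8, env.mesh.extent - spacing)
    xs = np.arange(-radius, radius + spacing / 2, spacing)
    ys = xs.copy()
    n_vpn = env.cfg.mb.n_vpn
    feats = np.empty((ys.size, xs.size, n_vpn))
    mode = env.cfg.mb.feature_norm
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            feats[iy, ix] = _normalize_features(env.features((x, y)), mode)
    return FeatureGrid(xs=xs, ys=ys, features=feats)


class NoveltyField:
    """Bilinear-interpolated MBON novelty of one frozen network.

    Gives the normalised novelty (for omega_v) and the steepest-descent
    visual direction anywhere in the gridded arena.
    """

    def __init__(self, grid: FeatureGrid, net: MBNetwork,
                 chunk: int = 2048):
        ny, nx, n_vpn = grid.features.shape
        flat = grid.features.reshape(-1, n_vpn)
        cmbon = np.empty(flat.shape[0])
        n_active = np.empty(flat.shape[0])
        # KC drive = mean of connected (already-normalised) VPN values;
        # chunked over positions to bound memory
        for lo in range(0, flat.shape[0], chunk):
            block = flat[lo:lo + chunk]
            sums = np.zeros((block.shape[0], net.n_kc))
            for k in range(net.fan_in):
                sums += block[:, net.connectivity[:, k]]
            active = (sums / net.fan_in) > net.theta_kc
            cmbon[lo:lo + chunk] = active @ net.kc_weights
            n_active[lo:lo + chunk] = active.sum(axis=1)
        self.cmbon = cmbon.reshape(ny, nx)
        self.n_active = n_active.reshape(ny, nx)
        # cells activating no KC carry no familiarity evidence: fully novel
        novelty = np.where(self.n_active > 0,
                           self.cmbon / np.maximum(1, self.n_active), 1.0)
        # light smoothing removes spurious cell-scale minima that would
        # otherwise trap the recall-phase gradient descent
        self.novelty = gaussian_filter(novelty, sigma=1.0)
        self.n_kc = net.n_kc
        self.grid = grid
        self._x0 = grid.xs[0]
        self._y0 = grid.ys[0]
        self._h = grid.xs[1] - grid.xs[0]

    def _interp(self, field: np.ndarray, position) -> float:
        gx = (position[0] - self._x0) / self._h
        gy = (position[1] - self._y0) / self._h
        gx = min(max(gx, 0.0), self.grid.xs.size - 1 - 1e-9)
        gy = min(max(gy, 0.0), self.grid.ys.size - 1 - 1e-9)
        ix, iy = int(gx), int(gy)
        fx, fy = gx - ix, gy - iy
        return float((1 - fx) * (1 - fy) * field[iy, ix]
                     + fx * (1 - fy) * field[iy, ix + 1]
                     + (1 - fx) * fy * field[iy + 1, ix]
                     + fx * fy * field[iy + 1, ix + 1])

    def __call__(self, position) -> float:
        """Normalised novelty at ``position`` (bilinear; clamped to grid)."""
        return self._interp(self.novelty, position)

    def omega_v(self, position, normalizer_mode: str = "nkc") -> float:
        """Visual familiarity weight at ``position``."""
        if normalizer_mode == "active":
            return float(np.clip(1.0 - self(position), 0.0, 1.0))
        raw = self._interp(self.cmbon, position)
        return float(np.clip(1.0 - raw / self.n_kc, 0.0, 1.0))

    def direction(self, position, U: float, n_headings: int,
                  rng: np.random.Generator,
                  probe: float = 0.5) -> Tuple[Optional[float], bool]:
        """Steepest novelty-descent heading.

        Probes at ``probe`` meters (several grid cells) rather than the
        step size: the recall-phase field is only resolved at the grid
        scale, and a longer probe follows the large-scale familiarity
        trend instead of cell-scale corrugations.
        """
        probe = max(U, self._h, probe)
        here = self(position)
        headings = 2 * math.pi * np.arange(n_headings) / n_headings
        dec = np.array([here - self((position[0] + probe * math.cos(h),
                                     position[1] + probe * math.sin(h)))
                        for h in headings])
        # only follow the estimate while it is an actual descent; at a
        # plateau or local minimum the cue is uninformative
        if dec.max() <= 0 or dec.max() - dec.min() <= 1e-15:
            return None, False
        tied = np.flatnonzero(dec >= dec.max() - 1e-15)
        pick = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
        return float(wrap_angle(headings[pick])), True


# ---------------------------------------------------------------------------
# Homing test
# ---------------------------------------------------------------------------

def homing_test(net: MBNetwork, env: Environment, field: NoveltyField,
                grid: ReleaseGrid, rng: np.random.Generator,
                agent_id: int = 0, experience: int = 0) -> pd.DataFrame:
    """Frozen-memory recall test from every release point.

    The displaced agent has no valid PI home vector, so omega_PI is forced
    to 0 and the visual/olfactory weights are renormalised; Ac = 0 (pure
    homing, phi = 0), learning is disabled, and a small stochastic-step
    probability is kept to escape novelty plateaus.  Success means entering
    ``success_radius`` within the step budget.
    """
    cfg = env.cfg
    U = cfg.agent.step_size
    rows = []
    for p, dist, ang in zip(grid.points, grid.distances, grid.angles):
        pos = np.array(p, dtype=float)
        heading = float(rng.uniform(-math.pi, math.pi))
        success = False
        steps = 0
        for steps in range(1, cfg.agent.max_homing_steps + 1):
            w_v = field.omega_v(pos, cfg.mb.normalizer_mode)
            w_olf = olf_familiarity(env.odour, pos)
            total = w_v + w_olf
            if total > 1e-9:
                w_v, w_olf = w_v / total, w_olf / total
            theta_v, _ = field.direction(pos, U, cfg.mb.n_headings, rng)
            theta_olf = olf_homing_direction(pos)
            weights = WeightTriple(w_v=w_v, w_olf=w_olf)
            weights.w_pi = 0.0  # displaced agent: no home vector
            hv, ok = homing_vector(weights, theta_v, theta_olf, None)
            if rng.random() < cfg.agent.p_rand_test:
                heading = float(wrap_angle(rng.vonmises(heading,
                                                        cfg.agent.kappa)))
            elif ok:
                heading = math.atan2(hv[1], hv[0])
            pos = pos + U * np.array([math.cos(heading), math.sin(heading)])
            if float(np.hypot(*pos)) <= cfg.agent.success_radius:
                success = True
                break
        rows.append({"agent": agent_id, "walks": experience,
                     "dist_m": float(dist), "angle_deg": math.degrees(ang),
                     "success": int(success), "steps": steps,
                     "final_dist": float(np.hypot(*pos))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------

def coverage_area(traj: np.ndarray) -> float:
    """Convex-hull area (m^2) of a trajectory's points; 0 if degenerate."""
    pts = np.asarray(traj, dtype=float)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0


def max_distance(traj: np.ndarray) -> float:
    """Maximum Euclidean distance from the nest (origin)."""
    pts = np.asarray(traj, dtype=float)
    if pts.size == 0:
        return 0.0
    return float(np.hypot(pts[:, 0], pts[:, 1]).max())


def turning_stats(headings: np.ndarray) -> float:
    """Mean absolute per-step heading change (circular difference)."""
    h = np.asarray(headings, dtype=float)
    if h.size < 2:
        return 0.0
    return float(np.abs(wrap_angle(np.diff(h))).mean())


def walk_metrics(record: TrajectoryRecord, agent_id: int = 0) -> dict:
    """Per-walk summary consumed by the bounds and species analyses."""
    pts = record.positions
    shares = record.rows[["w_v", "w_olf", "w_pi"]].to_numpy()
    shares = shares / shares.sum(axis=1, keepdims=True)
    return {"agent": agent_id, "walk": record.meta["walk_index"],
            "area": coverage_area(pts), "max_dist": max_distance(pts),
            "turning": turning_stats(record.rows["heading"].to_numpy()),
            "n_scans": record.meta["n_scans"],
            "mean_w_v": float(shares[:, 0].mean()),
            "mean_w_olf": float(shares[:, 1].mean()),
            "mean_w_pi": float(shares[:, 2].mean())}


@dataclass
class BioBounds:
    """Empirical per-walk mean +- sd bands for area and maximum distance,
    derived from the printed first-walk values and growth multipliers
    (sds scaled proportionally with the means)."""

    area: List[Tuple[float, float]]
    dist: List[Tuple[float, float]]

    @classmethod
    def default(cls) -> "BioBounds":
        return cls.from_first_walk()

    @classmethod
    def from_first_walk(cls, area_mean: float = 0.07, area_sd: float = 0.035,
                        area_mult: Sequence[float] = (8.0, 2.5, 2.5),
                        dist_mean: float = 0.184, dist_sd: float = 0.0636,
                        dist_mult: Sequence[float] = (3.8, 2.0, 2.0)
                        ) -> "BioBounds":
        area = [(area_mean, area_sd)]
        for m in area_mult:
            area.append((area[-1][0] * m, area[-1][1] * m))
        dist = [(dist_mean, dist_sd)]
        for m in dist_mult:
            dist.append((dist[-1][0] * m, dist[-1][1] * m))
        return cls(area=area, dist=dist)


def within_bounds_fraction(metrics: pd.DataFrame,
                           bounds: Optional[BioBounds] = None) -> Dict[str, float]:
    """Pooled fraction of (agent, walk) metric values inside the per-walk
    ``mean +- sd`` band, for coverage area and maximum distance."""
    if bounds is None:
        bounds = BioBounds.default()
    out = {}
    for col, bands in (("area", bounds.area), ("max_dist", bounds.dist)):
        hits = total = 0
        for _, row in metrics.iterrows():
            mean, sd = bands[int(row["walk"]) - 1]
            hits += int(mean - sd <= row[col] <= mean + sd)
            total += 1
        out[col] = hits / total if total else float("nan")
    return out


# ---------------------------------------------------------------------------
# Success curves and statistics
# ---------------------------------------------------------------------------

def success_curves(outcomes: pd.DataFrame) -> Dict[str, float]:
    """Near (1-4 m, /32), far (5-8 m, /32) and overall (/64) success rates."""
    near = outcomes[outcomes["dist_m"] <= 4]
    far = outcomes[outcomes["dist_m"] >= 5]
    return {"near": float(near["success"].mean()),
            "far": float(far["success"].mean()),
            "overall": float(outcomes["success"].mean())}


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def paired_cohens_d(a: np.ndarray, b: np.ndarray, classic: bool = False) -> float:
    """Paired effect size: dz = mean(diff)/sd(diff) by default, or the
    classic d (mean diff over pooled sd)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    diff = a - b
    if classic:
        pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        return float(diff.mean() / pooled) if pooled > 0 else float("nan")
    if np.allclose(diff, diff[0]):  # zero-variance differences: degenerate
        return 0.0 if np.allclose(diff, 0.0) else math.copysign(
            float("inf"), float(diff[0]))
    return float(diff.mean() / diff.std(ddof=1))


def paired_stats(rates_by_walk: pd.DataFrame,
                 comparisons: Sequence[Tuple[int, int]] = tuple(TABLE_COMPARISONS),
                 alpha_normality: float = 0.05) -> pd.DataFrame:
    """Pairwise walk comparisons of per-agent success rates.

    Each comparison is gated by Shapiro-Wilk on the paired differences:
    normal -> paired t-test with Cohen's dz, otherwise Wilcoxon signed-rank
    with the rank-biserial-style ``r = |Z| / sqrt(n)``.  Raw p-values are
    Holm-corrected over the comparison family.
    """
    if rates_by_walk.shape[0] < 3:
        raise ValueError("paired statistics need at least 3 agents")
    rows = []
    for later, earlier in comparisons:
        a = rates_by_walk[later].to_numpy(dtype=float)
        b = rates_by_walk[earlier].to_numpy(dtype=float)
        diff = a - b
        if np.allclose(diff, diff[0]):
            normal = True  # Shapiro undefined for constant diffs
        else:
            normal = shapiro(diff).pvalue >= alpha_normality
        if normal:
            if np.allclose(diff, 0):
                stat, p = 0.0, 1.0
            else:
                res = ttest_rel(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
            effect = paired_cohens_d(a, b)
            method, etype = "t-test", "d"
        else:
            res = wilcoxon(a, b, method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
            z = float(getattr(res, "zstatistic", 0.0))
            effect = abs(z) / math.sqrt(len(a))
            method, etype = "wilcoxon", "r"
        rows.append({"comparison": f"LW{later} vs. LW{earlier}",
                     "method": method, "statistic": stat, "p_raw": p,
                     "effect": effect, "effect_type": etype,
                     "normal": normal})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Cohorts, species comparison and weight dynamics
# ---------------------------------------------------------------------------

def run_cohort(env: Environment, n_agents: int, master_seed: int,
               n_walks: int = 4):
    """Run ``n_agents`` independent agents (shared world, per-agent seeds).

    Returns ``(records, snapshots)`` keyed ``[agent][walk]``.
    """
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence((master_seed, 7)).spawn(n_agents)]
    all_records, all_snapshots = [], []
    for seed in seeds:
        records, snapshots, _ = run_walk_series(env, seed, n_walks)
        all_records.append(records)
        all_snapshots.append(snapshots)
    return all_records, all_snapshots


def cohort_metrics(all_records) -> pd.DataFrame:
    rows = [walk_metrics(rec, agent_id=i)
            for i, records in enumerate(all_records) for rec in records]
    return pd.DataFrame(rows)


def species_compare(cfg: SimConfig, reduced_cfg: SimConfig, n_agents: int,
                    master_seed: int, world_seed: Optional[int] = None,
                    n_walks: int = 4) -> Dict[str, object]:
    """Matched-seed cohorts under normal vs reduced-vision conditions.

    Both cohorts share the terrain and per-agent seeds, so the contrast
    isolates the visual-reliance manipulation.  Returns per-walk metrics
    for both cohorts and the relative change in mean turning angle.
    """
    if world_seed is None:
        world_seed = master_seed
    env = Environment.from_config(cfg, world_seed)
    env_red = Environment(env.mesh, env.odour, reduced_cfg)
    rec_norm, _ = run_cohort(env, n_agents, master_seed, n_walks)
    rec_red, _ = run_cohort(env_red, n_agents, master_seed, n_walks)
    m_norm = cohort_metrics(rec_norm)
    m_red = cohort_metrics(rec_red)
    turn_norm = float(m_norm["turning"].mean())
    turn_red = float(m_red["turning"].mean())
    return {"normal": m_norm, "reduced": m_red,
            "turning_normal": turn_norm, "turning_reduced": turn_red,
            "turning_reduction_pct": 100.0 * (turn_norm - turn_red) / turn_norm,
            "scan_ratio": float(m_red["n_scans"].sum() / m_norm["n_scans"].sum()),
            "records_normal": rec_norm, "records_reduced": rec_red}


def weight_dynamics(records_by_agent: Sequence[Sequence[TrajectoryRecord]],
                    n_norm_steps: int = 100) -> Dict[str, object]:
    """Cue-weight profiles over normalised walk time and per-walk means.

    Each walk is resampled to ``n_norm_steps`` normalised steps; weights
    are reported as shares of the triple (percent).  Returns per-step
    quartiles across agents per walk, and per-walk mean shares.
    """
    n_walks = len(records_by_agent[0])
    profiles = {w: [] for w in range(1, n_walks + 1)}
    for records in records_by_agent:
        for rec in records:
            w = rec.meta["walk_index"]
            shares = rec.rows[["w_v", "w_olf", "w_pi"]].to_numpy()
            shares = 100.0 * shares / shares.sum(axis=1, keepdims=True)
            t = np.linspace(0, 1, shares.shape[0])
            tq = np.linspace(0, 1, n_norm_steps)
            resampled = np.stack([np.interp(tq, t, shares[:, k])
                                  for k in range(3)], axis=1)
            profiles[w].append(resampled)
    quartiles = {}
    means = {}
    for w, profs in profiles.items():
        arr = np.stack(profs)  # (agents, steps, 3)
        quartiles[w] = {q: np.percentile(arr, q, axis=0) for q in (25, 50, 75)}
        means[w] = {"w_v": float(arr[..., 0].mean()),
                    "w_olf": float(arr[..., 1].mean()),
                    "w_pi": float(arr[..., 2].mean())}
    return {"quartiles": quartiles, "walk_means": means}
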