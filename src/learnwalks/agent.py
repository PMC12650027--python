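"""Agent orchestration: sensing, fusion, movement, scans, walk protocol.

Each simulation step senses the world (current-position MBON novelty,
odour concentration, PI home vector), fuses the cues into the Homing and
Learning Vectors, and moves one fixed-length step U — either along the
Learning Vector or, with probability ``p_rand``, along a stochastic von
Mises heading centred on the current direction.  Pirouette-like scans,
scheduled at a fixed interval per walk, are the only moments of visual
learning and of refreshing the visual direction estimate.  A walk runs a
predetermined exploration budget (doubling per walk), then flips the
exploration state Ac to 0 and homes until the nest is reached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .cues import (DistanceSchedule, PIState, dk_schedule, olf_familiarity,
                   olf_homing_direction, pi_home_direction, pi_offset,
                   pi_update)
from .lvector import (WeightTriple, folf_offset, fv_offset, homing_vector,
                      rotate, total_offset)
from .mbvision import (MBNetwork, NoveltyTrace, kc_activation, mb_learn,
                       mbon_novelty, panorama_features, visual_familiarity,
                       visual_homing_direction)
from .world import (OdourField, TerrainMesh, generate_terrain,
                    odour_concentration, render_panorama, wrap_angle)

__all__ = [
    "Environment",
    "AgentState",
    "TrajectoryRecord",
    "expected_steps",
    "scan_interval",
    "make_agent",
    "perform_scan",
    "step",
    "run_learning_walk",
    "run_walk_series",
    "reduced_vision_config",
]

ROW_COLUMNS = ["step", "x", "y", "heading", "w_v", "w_olf", "w_pi", "phi",
               "scan", "random", "ac"]


# ---------------------------------------------------------------------------
# Environment bundle
# ---------------------------------------------------------------------------

class Environment:
    """Terrain + odour field + the render/encode pipeline of one world."""

    def __init__(self, mesh: TerrainMesh, odour: OdourField, cfg: SimConfig):
        self.mesh = mesh
        self.odour = odour
        self.cfg = cfg

    @classmethod
    def from_config(cls, cfg: SimConfig, world_seed: int) -> "Environment":
        w = cfg.world
        mesh = generate_terrain(world_seed, n_objects=w.n_objects,
                                height_range=w.height_range, extent=w.extent,
                                width_range=w.width_range,
                                scatter_radius=w.scatter_radius,
                                clear_radius=w.clear_radius,
                                n_landmarks=w.n_landmarks,
                                landmark_height_range=w.landmark_height_range,
                                landmark_width_range=w.landmark_width_range)
        odour = OdourField(c0=cfg.odour.c0, sigma=cfg.odour.sigma,
                           wind=cfg.odour.wind, stretch=cfg.odour.stretch)
        return cls(mesh, odour, cfg)

    @property
    def n_max(self) -> int:
        # NVPN = (n_max + 2)^2 / 4  =>  n_max = 2 sqrt(NVPN) - 2
        return int(round(2 * math.sqrt(self.cfg.mb.n_vpn) - 2))

    def view(self, position):
        w = self.cfg.world
        # scan probes may poke a step beyond the wall; clamp them back in
        position = np.clip(np.asarray(position, dtype=float),
                           -self.mesh.extent, self.mesh.extent)
        return render_panorama(self.mesh, position, (w.n_az, w.n_el),
                               eye_height=w.eye_height,
                               el_range=(w.el_min, w.el_max),
                               ground_value=w.ground_value)

    def features(self, position) -> np.ndarray:
        return panorama_features(self.view(position),
                                 self.cfg.mb.disk_size, self.n_max)

    def concentration(self, position) -> float:
        return odour_concentration(self.odour, position)

    def novelty_fn(self, net: MBNetwork):
        """Normalised-novelty evaluator bound to one network."""

        def novelty(position) -> float:
            active = kc_activation(net, self.features(position),
                                   self.cfg.mb.feature_norm)
            return mbon_novelty(net, active)[1]

        return novelty


# ---------------------------------------------------------------------------
# Agent state and records
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    position: np.ndarray
    heading: float
    pi: PIState
    mb: MBNetwork
    trace: NoveltyTrace
    schedule: DistanceSchedule
    rng: np.random.Generator
    ac: int = 1
    walk_index: int = 1
    step_index: int = 0
    theta_v: float = 0.0
    theta_v_ok: bool = False
    segment_sign: int = 1
    scan_count: int = 0
    n_reflections: int = 0


@dataclass
class TrajectoryRecord:
    """Per-step log of one walk plus side-car metadata."""

    rows: pd.DataFrame
    meta: dict

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)
        Path(str(path) + ".meta.json").write_text(json.dumps(self.meta))

    @property
    def positions(self) -> np.ndarray:
        return self.rows[["x", "y"]].to_numpy()


def expected_steps(j: int, np1: int, growth: float) -> int:
    """Exploration-step budget of walk ``j``: ``round(np1 * growth^(j-1))``."""
    if j < 1:
        raise ValueError("walk index starts at 1")
    return int(round(np1 * growth ** (j - 1)))


def scan_interval(np_j: int, n_j: int) -> Optional[int]:
    """Average steps between scans, ``round(np_j / n_j)`` (minimum 1).
    ``n_j = 0`` disables scanning (returns None)."""
    if n_j == 0:
        return None
    if n_j < 0:
        raise ValueError("scan count must be non-negative")
    return max(1, int(round(np_j / n_j)))


def make_agent(cfg: SimConfig, seed: int) -> AgentState:
    """Fresh agent: new MB wiring (per-agent seed), zeroed PI, empty trace."""
    ss = np.random.SeedSequence(seed)
    mb_seed, rng_seed = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    mb = MBNetwork.create(n_vpn=cfg.mb.n_vpn, n_kc=cfg.mb.n_kc,
                          fan_in=cfg.mb.fan_in, theta_kc=cfg.mb.theta_kc,
                          lambda_vis=cfg.mb.lambda_vis, seed=mb_seed)
    return AgentState(position=np.zeros(2), heading=0.0,
                      pi=PIState(noise_sd=cfg.pi.noise_sd),
                      mb=mb, trace=NoveltyTrace(window=cfg.lv.fv_window),
                      schedule=dk_schedule(cfg.pi.d1, cfg.pi.multipliers),
                      rng=np.random.default_rng(rng_seed))


# ---------------------------------------------------------------------------
# Scanning and stepping
# ---------------------------------------------------------------------------

def perform_scan(state: AgentState, env: Environment) -> None:
    """Pirouette: learn the current view, refresh the visual direction.

    The only place visual learning happens; the scan also re-estimates
    theta_v by probing novelty around the current position, and (in the
    random sign mode) redraws the rotation sign for the next segment.
    """
    cfg = env.cfg
    active = kc_activation(state.mb, env.features(state.position),
                           cfg.mb.feature_norm)
    mb_learn(state.mb, active)
    theta_v, confident = visual_homing_direction(
        state.mb, state.position, novelty_fn=env.novelty_fn(state.mb),
        U=cfg.agent.step_size, n_headings=cfg.mb.n_headings, rng=state.rng)
    state.theta_v = theta_v
    state.theta_v_ok = confident
    if cfg.lv.sign_mode == "random":
        state.segment_sign = int(state.rng.choice([-1, 1]))
    state.scan_count += 1


def _reflect(position: np.ndarray, extent: float) -> Tuple[np.ndarray, bool]:
    p = position.copy()
    reflected = False
    for i in range(2):
        if p[i] > extent:
            p[i] = 2 * extent - p[i]
            reflected = True
        elif p[i] < -extent:
            p[i] = -2 * extent - p[i]
            reflected = True
    return p, reflected


def step(state: AgentState, env: Environment, *,
         p_rand: Optional[float] = None, scan_flag: bool = False) -> dict:
    """Advance the agent one step of length U; returns the trajectory row.

    Sensing (novelty, concentration, PI) happens every step; movement is
    stochastic with probability ``p_rand`` (von Mises around the current
    heading), otherwise along the Learning Vector.  PI accumulates the
    realised step afterwards.
    """
    cfg = env.cfg
    U = cfg.agent.step_size
    if p_rand is None:
        p_rand = cfg.agent.p_rand
    pos = state.position

    # --- sensing ---
    active = kc_activation(state.mb, env.features(pos), cfg.mb.feature_norm)
    cmbon, novelty = mbon_novelty(state.mb, active)
    state.trace.append(novelty)
    n_active = int(active.sum())
    if n_active == 0:
        w_v = 0.0  # no visual evidence at all
    elif cfg.mb.normalizer_mode == "active":
        w_v = visual_familiarity(cmbon, n_active)
    else:
        w_v = visual_familiarity(cmbon, state.mb.n_kc)
    conc = olf_familiarity(env.odour, pos)
    weights = WeightTriple(w_v=w_v, w_olf=conc)

    # --- fusion ---
    theta_olf = olf_homing_direction(pos)
    theta_pi = pi_home_direction(state.pi)
    theta_v = state.theta_v if state.theta_v_ok else None
    f_v = fv_offset(state.trace)
    f_olf = folf_offset(min(conc, 1.0))
    f_pi = pi_offset(state.pi.r, state.schedule,
                     min(state.walk_index, state.schedule.n_walks),
                     scaled=cfg.pi.fpi_scaled, clamp=cfg.pi.fpi_clamped,
                     scale=cfg.pi.fpi_scale)
    phi = total_offset(state.ac, weights, f_v, f_olf, f_pi,
                       clamp=cfg.lv.clamp_phi)
    hv, hv_ok = homing_vector(weights, theta_v, theta_olf, theta_pi)

    # --- movement ---
    random_step = bool(state.rng.random() < p_rand)
    if random_step:
        heading = float(wrap_angle(state.rng.vonmises(state.heading,
                                                      cfg.agent.kappa)))
    elif hv_ok:
        lv = rotate(hv, phi, state.segment_sign)
        if float(np.hypot(*lv)) > 1e-9:
            heading = math.atan2(lv[1], lv[0])
        else:
            heading = state.heading  # degenerate vector: keep going
    else:
        heading = state.heading  # no informative cue: keep going
    new_pos = pos + U * np.array([math.cos(heading), math.sin(heading)])
    new_pos, reflected = _reflect(new_pos, env.mesh.extent)
    if reflected:
        state.n_reflections += 1
        heading = math.atan2(*(new_pos - pos)[::-1])
    realised = new_pos - pos
    pi_update(state.pi, realised, state.rng)
    state.position = new_pos
    state.heading = heading
    state.step_index += 1
    return {"step": state.step_index, "x": new_pos[0], "y": new_pos[1],
            "heading": heading, "w_v": weights.w_v, "w_olf": weights.w_olf,
            "w_pi": weights.w_pi, "phi": phi, "scan": int(scan_flag),
            "random": int(random_step), "ac": state.ac}


# ---------------------------------------------------------------------------
# Walk protocol
# ---------------------------------------------------------------------------

def run_learning_walk(state: AgentState, env: Environment, j: int,
                      walk_seed: Optional[int] = None) -> TrajectoryRecord:
    """One learning walk: scans + exploration budget, then homing to nest.

    The agent starts at the nest with a fresh PI state and Ac = 1, performs
    a scan every ``Iscan`` steps while exploring, then switches to Ac = 0
    and keeps stepping until it re-enters ``nest_radius`` (or the homing
    budget runs out, in which case the walk is flagged incomplete).
    """
    cfg = env.cfg
    if walk_seed is not None:
        state.rng = np.random.default_rng(walk_seed)
    state.position = np.zeros(2)
    state.heading = float(state.rng.uniform(-math.pi, math.pi))
    state.pi.reset()
    state.ac = 1
    state.walk_index = j
    state.step_index = 0
    state.theta_v_ok = False
    scans_before = state.scan_count

    np_j = expected_steps(j, cfg.agent.np1, cfg.agent.growth)
    scans = cfg.agent.scans_per_walk
    n_j = scans[min(j, len(scans)) - 1]
    iscan = scan_interval(np_j, n_j)

    rows: List[dict] = []
    for n in range(np_j):
        scan_now = state.ac == 1 and iscan is not None and n % iscan == 0
        if scan_now:
            perform_scan(state, env)
        rows.append(step(state, env, scan_flag=scan_now))

    state.ac = 0
    completed = False
    for _ in range(cfg.agent.max_homing_steps):
        if float(np.hypot(*state.position)) <= cfg.agent.nest_radius:
            completed = True
            break
        rows.append(step(state, env))
    else:
        completed = float(np.hypot(*state.position)) <= cfg.agent.nest_radius

    meta = {"walk_index": j, "np_j": np_j, "iscan": iscan,
            "n_scans": state.scan_count - scans_before,
            "completed": completed, "seed": walk_seed,
            "n_reflections": state.n_reflections}
    return TrajectoryRecord(rows=pd.DataFrame(rows, columns=ROW_COLUMNS),
                            meta=meta)


def run_walk_series(env: Environment, agent_seed: int, n_walks: int = 4
                    ) -> Tuple[List[TrajectoryRecord], List[MBNetwork], AgentState]:
    """Run ``n_walks`` successive learning walks of one agent.

    The walks share the MB memory and the expected-range schedule; per-walk
    RNG seeds are derived from ``agent_seed``.  Returns the records, a
    snapshot of the MB network after each walk (for frozen-memory homing
    tests), and the final agent state.
    """
    state = make_agent(env.cfg, agent_seed)
    walk_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence((agent_seed, 1)).spawn(n_walks)]
    records, snapshots = [], []
    for j in range(1, n_walks + 1):
        records.append(run_learning_walk(state, env, j, walk_seeds[j - 1]))
        snapshots.append(state.mb.copy())
    return records, snapshots, state


def reduced_vision_config(cfg: SimConfig) -> SimConfig:
    """Reduced-visual-reliance variant: the MB learning rate is halved and
    the pirouette scan counts drop to one quarter of the defaults; every
    other parameter is unchanged."""
    mb = cfg.mb.__class__(**{**cfg.mb.__dict__,
                             "lambda_vis": cfg.mb.lambda_vis / 2.0})
    agent = cfg.agent.__class__(**{
        **cfg.agent.__dict__,
        "scans_per_walk": tuple(max(1, int(round(n / 4.0)))
                                for n in cfg.agent.scans_per_walk)})
    return cfg.replace(mb=mb, agent=agent)
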