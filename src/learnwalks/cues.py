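"""Innate olfactory homing and noisy path integration.

Both cues emit a familiarity score in [0, 1] and a nestward direction
estimate.  Olfaction reads the normalised Gaussian field directly
(concentration = familiarity; the gradient always points to the nest).
Path integration accumulates the realised per-step motion vectors plus a
small Gaussian error per component, the standard model of biological PI
drift; its "familiarity" is the ratio of the current home-vector length to
the walk's expected maximum range d_k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .world import OdourField, odour_concentration

__all__ = [
    "PIState",
    "DistanceSchedule",
    "olf_familiarity",
    "olf_homing_direction",
    "pi_update",
    "pi_home_direction",
    "pi_offset",
    "dk_schedule",
]


# ---------------------------------------------------------------------------
# Olfaction
# ---------------------------------------------------------------------------

def olf_familiarity(f: OdourField, position) -> float:
    """``omega_olf = C(x, y)`` for the normalised field (c0 = 1)."""
    return odour_concentration(f, position)


def olf_homing_direction(position) -> Optional[float]:
    """Nestward direction ``atan2(-y, -x)``; ``None`` exactly at the nest
    (the undefined branch — callers drop the cue)."""
    x, y = float(position[0]), float(position[1])
    if x == 0.0 and y == 0.0:
        return None
    return math.atan2(0.0 - y, 0.0 - x)  # 0.0-y avoids the -0.0 -> -pi branch


# ---------------------------------------------------------------------------
# Path integration
# ---------------------------------------------------------------------------

@dataclass
class PIState:
    """Accumulated outbound displacement estimate (nest -> agent)."""

    displacement: np.ndarray = field(default_factory=lambda: np.zeros(2))
    noise_sd: float = 1e-4  # per-component per-step error [m]

    @property
    def r(self) -> float:
        return float(np.hypot(*self.displacement))

    def reset(self) -> None:
        self.displacement[:] = 0.0


def pi_update(state: PIState, step_vector,
              rng: Optional[np.random.Generator] = None) -> PIState:
    """Accumulate one realised step plus i.i.d. N(0, noise_sd^2) error per
    component.  Mutates and returns ``state``."""
    step_vector = np.asarray(step_vector, dtype=float)
    delta = np.zeros(2)
    if rng is not None and state.noise_sd > 0:
        delta = rng.normal(0.0, state.noise_sd, size=2)
    state.displacement += step_vector + delta
    return state


def pi_home_direction(state: PIState, eps: float = 1e-6) -> Optional[float]:
    """Nestward PI direction: the phase of the *negated* accumulated
    displacement (the home vector points from the agent back to the nest).
    ``None`` when the displacement is shorter than ``eps``."""
    if state.r <= eps:
        return None
    dx, dy = state.displacement
    return math.atan2(0.0 - dy, 0.0 - dx)


# ---------------------------------------------------------------------------
# Per-walk expected-range schedule
# ---------------------------------------------------------------------------

@dataclass
class DistanceSchedule:
    """Expected maximum distances d_k per learning walk.

    ``d_k = d1 * prod(multipliers[:k-1])``; the defaults follow the
    empirical growth of maximum distance across the first four walks
    (x3.8, x2, x2 on a first-walk maximum of 0.184 m).
    """

    d1: float
    multipliers: Tuple[float, ...]
    dks: Tuple[float, ...] = ()

    def __post_init__(self):
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be positive")
        dks = [self.d1]
        for m in self.multipliers:
            dks.append(dks[-1] * m)
        self.dks = tuple(dks)

    def dk(self, k: int) -> float:
        """Expected maximum distance for 1-based walk index ``k``."""
        if not 1 <= k <= len(self.dks):
            raise ValueError(f"walk index {k} outside schedule")
        return self.dks[k - 1]

    @property
    def n_walks(self) -> int:
        return len(self.dks)


def dk_schedule(d1: float = 0.184,
                multipliers: Tuple[float, ...] = (3.8, 2.0, 2.0)) -> DistanceSchedule:
    return DistanceSchedule(d1=d1, multipliers=tuple(multipliers))


def pi_offset(r: float, schedule: DistanceSchedule, k: int,
              scaled: bool = True, clamp: bool = True,
              scale: Optional[float] = None) -> float:
    """PI familiarity offset from the ratio ``r / d_k``.

    The ratio admits two printed readings — the bare ratio (radians) or a
    mapping onto [0, pi] — so the angular gain is explicit here:
    ``scale`` multiplies the ratio (``1.0`` reproduces the literal ratio,
    ``pi`` the [0, pi] mapping; when None it falls back to the ``scaled``
    boolean).  ``clamp`` caps the ratio at 1 before scaling.  The gain
    sets where the PI-driven deviation crosses pi/2 — i.e. the radius,
    relative to d_k, at which outward drift turns back.
    """
    ratio = max(float(r), 0.0) / schedule.dk(k)
    if clamp:
        ratio = min(ratio, 1.0)
    if scale is None:
        scale = math.pi if scaled else 1.0
    return ratio * scale
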