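"""Cue fusion: Homing Vector, exploration offset phi, Learning Vector.

The three directional estimates (visual, olfactory, PI) are fused as a
weighted vector sum — the Homing Vector, the agent's integrated nest
estimate.  The Learning Vector rotates it by an angular offset phi in
[0, pi] that encodes the exploration/homing trade-off: each modality maps
its familiarity onto an offset contribution (familiar -> bold -> large
offset), the contributions are mixed with the same cue weights, and the
binary exploration state Ac gates the whole offset (Ac = 0 forces pure
homing, phi = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .mbvision import NoveltyTrace

__all__ = [
    "WeightTriple",
    "LearningVectorOutput",
    "pi_weight",
    "homing_vector",
    "fv_offset",
    "folf_offset",
    "total_offset",
    "rotate",
]


def pi_weight(w_v: float, w_olf: float) -> float:
    """``omega_PI = max(1 - omega_v - omega_olf, 0)`` — PI takes up the
    reliability left over by the other cues, floored at zero."""
    return max(1.0 - w_v - w_olf, 0.0)


@dataclass
class WeightTriple:
    """Per-step cue weights; ``w_pi`` is always recomputed from the other
    two so the construction invariant holds."""

    w_v: float
    w_olf: float
    w_pi: float = 0.0

    def __post_init__(self):
        self.w_pi = pi_weight(self.w_v, self.w_olf)

    @property
    def total(self) -> float:
        return self.w_v + self.w_olf + self.w_pi

    def shares(self) -> np.ndarray:
        """Weights normalised to fractions of the triple (sums to 1)."""
        t = self.total
        return np.array([self.w_v, self.w_olf, self.w_pi]) / t


@dataclass
class LearningVectorOutput:
    homing: np.ndarray
    phi: float
    learning: np.ndarray
    ac: int


def homing_vector(weights: WeightTriple,
                  theta_v: Optional[float],
                  theta_olf: Optional[float],
                  theta_pi: Optional[float],
                  eps: float = 1e-12):
    """Weighted vector sum of the available cue directions.

    ``None`` marks an unavailable direction (undefined cue signal): it
    contributes a zero vector and its weight is dropped from the sum.
    Returns ``(vector, ok)`` where ``ok`` is False when no cue was
    available or the sum cancelled to (numerically) zero.
    """
    v = np.zeros(2)
    any_cue = False
    for w, theta in ((weights.w_v, theta_v), (weights.w_olf, theta_olf),
                     (weights.w_pi, theta_pi)):
        if theta is None:
            continue
        any_cue = True
        v += w * np.array([math.cos(theta), math.sin(theta)])
    ok = any_cue and float(np.hypot(*v)) > eps
    return v, ok


def fv_offset(trace: NoveltyTrace) -> float:
    """Visual familiarity offset from the novelty trace (Kenyon-output
    sequence): a piecewise-linear ramp through (mean - sd, pi) and
    (mean + sd, 0) over the sliding window.  Low novelty relative to the
    recent window means a familiar scene and full boldness (pi); high
    novelty means caution (0).  A degenerate window (fewer than 3 entries
    or zero spread) yields the neutral pi/2.
    """
    if len(trace) == 0:
        raise ValueError("empty novelty trace")
    window = trace.window_values()
    vn = window[-1]
    if window.size < 3:
        return math.pi / 2
    mean = float(window.mean())
    sd = float(window.std())
    if sd <= 0.0:
        return math.pi / 2
    lo, hi = mean - sd, mean + sd
    if vn <= lo:
        return math.pi
    if vn >= hi:
        return 0.0
    return (hi - vn) / (hi - lo) * math.pi


def folf_offset(c: float) -> float:
    """Olfactory offset: the relative concentration mapped linearly onto
    [0, pi] (strong nest odour -> bold exploration)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("concentration must lie in [0, 1]")
    return c * math.pi


def total_offset(ac: int, weights: WeightTriple, f_v: float, f_olf: float,
                 f_pi: float, clamp: bool = True) -> float:
    """Overall offset ``phi = Ac * (w_v f_v + w_olf f_olf + w_pi f_pi)``.

    ``Ac`` gates the entire sum (exploration over -> pure homing).  The
    weighted sum can exceed pi when ``w_v + w_olf > 1``; clamping (default)
    keeps phi a deviation angle in [0, pi].
    """
    phi = float(ac) * (weights.w_v * f_v + weights.w_olf * f_olf
                       + weights.w_pi * f_pi)
    return float(np.clip(phi, 0.0, math.pi)) if clamp else phi


def rotate(vec, phi: float, sign: int = 1) -> np.ndarray:
    """Rotate a 2-vector by ``sign * phi`` (norm-preserving).

    The literal form always rotates counter-clockwise (``sign=1``); the
    per-segment random-sign mode passes ``sign=-1`` for clockwise loops.
    """
    a = sign * phi
    c, s = math.cos(a), math.sin(a)
    x, y = float(vec[0]), float(vec[1])
    return np.array([c * x - s * y, s * x + c * y])
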