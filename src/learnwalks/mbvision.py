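"""Mushroom-body visual familiarity: Zernike encoding and the MB network.

Panoramic snapshots are mapped onto a unit disk (azimuth -> polar angle,
elevation -> radius) and encoded as Zernike-moment amplitudes, which are
invariant to image rotation and hence to the viewer's heading.  The
amplitudes feed a three-layer VPN -> KC -> MBON network: each Kenyon cell
reads a fixed random subset of VPNs, and learning depresses the KC->MBON
synapses of active cells, so the MBON output is a scalar novelty score that
drops for familiar views.  Visual homing follows the direction of steepest
novelty decrease probed over a ring of candidate headings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Tuple

import numpy as np

from .world import PanoramicView, TerrainMesh, render_panorama

__all__ = [
    "neuron_rate",
    "preprocess_panorama",
    "zernike_pairs",
    "zernike_amplitudes",
    "MBNetwork",
    "NoveltyTrace",
    "kc_activation",
    "mbon_novelty",
    "mb_learn",
    "visual_familiarity",
    "visual_homing_direction",
    "make_novelty_fn",
    "panorama_features",
]

_TWO_PI = 2.0 * math.pi


def neuron_rate(x):
    """Sigmoid rate transfer ``1 / (1 + exp(-x))``."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Zernike encoding
# ---------------------------------------------------------------------------

def zernike_pairs(n_max: int) -> List[Tuple[int, int]]:
    """(n, m) index pairs with 0 <= m <= n <= n_max and n - m even,
    ordered n-major, m-minor.  For even n_max the count is (n_max+2)^2/4."""
    if n_max < 0 or n_max % 2 != 0:
        raise ValueError("n_max must be an even non-negative integer")
    return [(n, m) for n in range(n_max + 1)
            for m in range(n % 2, n + 1, 2)]


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


_BASIS_CACHE: dict = {}


def _zernike_basis(size: int, n_max: int):
    """Conjugated Zernike basis on a size x size raster, flattened."""
    key = (size, n_max)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    coords = 2.0 * (np.arange(size) + 0.5) / size - 1.0
    xx, yy = np.meshgrid(coords, coords)
    rho = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    mask = rho <= 1.0
    pairs = zernike_pairs(n_max)
    basis = np.zeros((len(pairs), size * size), dtype=complex)
    darea = (2.0 / size) ** 2
    for i, (n, m) in enumerate(pairs):
        v = _radial_poly(n, m, rho) * np.exp(-1j * m * theta) * mask
        basis[i] = ((n + 1) / math.pi * darea) * v.ravel()
    _BASIS_CACHE[key] = (pairs, basis)
    return pairs, basis


def zernike_amplitudes(disk: np.ndarray, n_max: int = 16) -> np.ndarray:
    """Zernike-moment amplitudes ``|Z_nm|`` of a square unit-disk raster."""
    disk = np.asarray(disk, dtype=float)
    if disk.ndim != 2 or disk.shape[0] != disk.shape[1]:
        raise ValueError("disk raster must be square")
    _, basis = _zernike_basis(disk.shape[0], n_max)
    return np.abs(basis @ disk.ravel())


_DISK_MAP_CACHE: dict = {}


def preprocess_panorama(view: PanoramicView, disk_size: int = 64) -> np.ndarray:
    """Map a panorama onto a unit-disk raster.

    Azimuth becomes the polar angle and elevation the radius (the highest
    elevation maps to the disk centre), so a rotation of the viewer becomes
    a rotation of the disk image.  Pixels outside the unit circle are 0.
    """
    key = (view.n_el, view.n_az, round(view.el_min, 9), round(view.el_max, 9),
           disk_size)
    cached = _DISK_MAP_CACHE.get(key)
    if cached is None:
        coords = 2.0 * (np.arange(disk_size) + 0.5) / disk_size - 1.0
        xx, yy = np.meshgrid(coords, coords)
        rho = np.hypot(xx, yy)
        theta = np.mod(np.arctan2(yy, xx), _TWO_PI)
        inside = rho <= 1.0
        el = view.el_max - rho * (view.el_max - view.el_min)
        # floor(x + 0.5) rounding keeps azimuth binning exactly equivariant
        # under whole-bin cyclic shifts (rint's half-to-even is not)
        i_idx = np.clip(np.floor((el - view.el_min)
                                 / (view.el_max - view.el_min)
                                 * (view.n_el - 1) + 0.5).astype(int),
                        0, view.n_el - 1)
        j_idx = np.mod(np.floor(theta / _TWO_PI * view.n_az + 0.5).astype(int),
                       view.n_az)
        cached = (inside, i_idx, j_idx)
        _DISK_MAP_CACHE[key] = cached
    inside, i_idx, j_idx = cached
    disk = np.zeros((disk_size, disk_size))
    disk[inside] = view.intensities[i_idx[inside], j_idx[inside]]
    return disk


_POLAR_BASIS_CACHE: dict = {}


def _polar_basis(n_el: int, n_az: int, n_max: int) -> np.ndarray:
    """Zernike quadrature basis directly on the (elevation, azimuth) grid.

    The panorama is already a polar sampling of the disk (elevation ->
    radius, azimuth -> angle), so the disk integral can be evaluated on it
    without rasterisation.  The azimuth part is a plain DFT, which makes
    the amplitudes of a cyclically shifted panorama *exactly* equal to the
    original's.
    """
    key = (n_el, n_az, n_max)
    if key in _POLAR_BASIS_CACHE:
        return _POLAR_BASIS_CACHE[key]
    rho = 1.0 - np.arange(n_el) / (n_el - 1)  # row 0 = lowest el = rim
    theta = _TWO_PI * np.arange(n_az) / n_az
    dr = 1.0 / (n_el - 1)
    w_r = np.full(n_el, dr)
    w_r[[0, -1]] = dr / 2  # trapezoid in radius
    dth = _TWO_PI / n_az
    pairs = zernike_pairs(n_max)
    basis = np.empty((len(pairs), n_el, n_az), dtype=complex)
    for i, (n, m) in enumerate(pairs):
        radial = _radial_poly(n, m, rho) * rho * w_r * ((n + 1) / math.pi * dth)
        basis[i] = radial[:, None] * np.exp(-1j * m * theta)[None, :]
    basis = basis.reshape(len(pairs), n_el * n_az)
    _POLAR_BASIS_CACHE[key] = basis
    return basis


def panorama_features(view: PanoramicView, disk_size: int = 64,
                      n_max: int = 16) -> np.ndarray:
    """Panorama -> rotation-invariant Zernike amplitude vector.

    Uses the polar quadrature (``_polar_basis``) rather than the raster
    route, so heading invariance is exact for whole-bin azimuth shifts;
    ``disk_size`` is kept for signature compatibility with the raster
    pipeline and ignored here.
    """
    basis = _polar_basis(view.n_el, view.n_az, n_max)
    return np.abs(basis @ view.intensities.ravel())


# ---------------------------------------------------------------------------
# MB network
# ---------------------------------------------------------------------------

@dataclass
class MBNetwork:
    """Sparse VPN -> KC -> MBON network with depressing KC->MBON synapses.

    ``connectivity[i]`` holds the ``fan_in`` VPN indices wired to Kenyon
    cell ``i`` (fixed at construction); ``kc_weights`` are the KC->MBON
    synaptic weights, all 1 at initialisation and bounded to ``[0, 1]``.
    """

    connectivity: np.ndarray
    kc_weights: np.ndarray
    n_vpn: int
    theta_kc: float
    lambda_vis: float
    seed: int

    @classmethod
    def create(cls, n_vpn: int = 81, n_kc: int = 4000, fan_in: int = 10,
               theta_kc: float = 0.04, lambda_vis: float = 0.01,
               seed: int = 0) -> "MBNetwork":
        rng = np.random.default_rng(seed)
        conn = np.empty((n_kc, fan_in), dtype=np.int64)
        for i in range(n_kc):
            conn[i] = rng.choice(n_vpn, size=fan_in, replace=False)
        return cls(connectivity=conn, kc_weights=np.ones(n_kc),
                   n_vpn=int(n_vpn), theta_kc=float(theta_kc),
                   lambda_vis=float(lambda_vis), seed=int(seed))

    @property
    def n_kc(self) -> int:
        return int(self.kc_weights.size)

    @property
    def fan_in(self) -> int:
        return int(self.connectivity.shape[1])

    def copy(self) -> "MBNetwork":
        return MBNetwork(connectivity=self.connectivity,
                         kc_weights=self.kc_weights.copy(), n_vpn=self.n_vpn,
                         theta_kc=self.theta_kc, lambda_vis=self.lambda_vis,
                         seed=self.seed)

    def save(self, path) -> None:
        state = {"version": 1, "seed": self.seed, "n_vpn": self.n_vpn,
                 "n_kc": self.n_kc, "fan_in": self.fan_in,
                 "theta_kc": self.theta_kc, "lambda_vis": self.lambda_vis,
                 "kc_weights": self.kc_weights.tolist()}
        Path(path).write_text(json.dumps(state))

    @classmethod
    def load(cls, path) -> "MBNetwork":
        state = json.loads(Path(path).read_text())
        if state.get("version") != 1:
            raise ValueError("unsupported MBNetwork state version")
        net = cls.create(n_vpn=int(state["n_vpn"]), n_kc=int(state["n_kc"]),
                         fan_in=int(state["fan_in"]),
                         theta_kc=state["theta_kc"],
                         lambda_vis=state["lambda_vis"], seed=int(state["seed"]))
        net.kc_weights[:] = np.asarray(state["kc_weights"], dtype=float)
        return net


def _normalize_features(features: np.ndarray, mode: str = "l1") -> np.ndarray:
    """Per-presentation feature normalisation.

    ``l1`` (default) scales amplitudes to unit sum, so the mean feature is
    ``1/n_vpn`` and the KC threshold acts as a sparse gate; ``minmax``
    rescales to [0, 1] instead (a much denser code under the same
    threshold).
    """
    features = np.asarray(features, dtype=float)
    if mode == "minmax":
        lo, hi = features.min(), features.max()
        if hi - lo < 1e-300:
            return np.zeros_like(features)
        return (features - lo) / (hi - lo)
    total = features.sum()
    if total < 1e-300:
        return np.zeros_like(features)
    return features / total


def kc_activation(net: MBNetwork, features: np.ndarray,
                  feature_norm: str = "l1") -> np.ndarray:
    """Binary KC activation for one feature presentation.

    Features are normalised per presentation (see ``_normalize_features``);
    a KC fires iff the mean of its connected VPN values exceeds
    ``theta_kc``.  With the default L1 normalisation the threshold sits
    well above the mean feature value, giving the sparse Kenyon-cell code
    that underpins pattern separation.
    """
    features = np.asarray(features, dtype=float)
    if features.shape != (net.n_vpn,):
        raise ValueError(
            f"feature length {features.size} != n_vpn {net.n_vpn}")
    normed = _normalize_features(features, feature_norm)
    drive = normed[net.connectivity].mean(axis=1)
    return drive > net.theta_kc


def mbon_novelty(net: MBNetwork, active: np.ndarray) -> Tuple[float, float]:
    """Raw MBON response (sum of weights over active KCs) and its
    normalised form in [0, 1] (divided by the active-KC count, so a
    never-seen pattern scores exactly 1).  A pattern that activates no KC
    at all carries no familiarity evidence and scores fully novel (1)."""
    active = np.asarray(active, dtype=bool)
    if active.size != net.n_kc:
        raise ValueError("active vector length must equal the KC count")
    n_active = int(active.sum())
    if n_active == 0:
        return 0.0, 1.0
    cmbon = float(net.kc_weights[active].sum())
    return cmbon, cmbon / n_active


def mb_learn(net: MBNetwork, active: np.ndarray) -> MBNetwork:
    """Depress the KC->MBON weights of active cells by ``lambda_vis``
    (subtractive, floored at 0).  Mutates and returns ``net``."""
    active = np.asarray(active, dtype=bool)
    net.kc_weights[active] = np.maximum(0.0, net.kc_weights[active] - net.lambda_vis)
    return net


def visual_familiarity(cmbon: float, normalizer: float) -> float:
    """``omega_v = 1 - CMBON / normalizer`` clipped to [0, 1].

    With the default active-count normaliser a completely novel view (all
    weights still 1) gives 0 and a fully depressed one gives 1; passing the
    literal KC count reproduces the raw-network normalisation instead.
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    return float(np.clip(1.0 - cmbon / normalizer, 0.0, 1.0))


@dataclass
class NoveltyTrace:
    """Append-only record of normalised MBON novelty with a sliding window."""

    window: int = 50
    values: List[float] = field(default_factory=list)

    def append(self, value: float) -> None:
        self.values.append(float(value))

    def __len__(self) -> int:
        return len(self.values)

    def window_values(self) -> np.ndarray:
        return np.asarray(self.values[-self.window:], dtype=float)


# ---------------------------------------------------------------------------
# Scan-based visual homing
# ---------------------------------------------------------------------------

def make_novelty_fn(net: MBNetwork, mesh: TerrainMesh, *,
                    resolution=(90, 25), eye_height=0.005,
                    el_range=(math.radians(-10), math.radians(60)),
                    ground_value=0.5, disk_size=64, n_max=16,
                    feature_norm="l1") -> Callable[[np.ndarray], float]:
    """Normalised-novelty evaluator over positions via the full
    render/encode path.  The normalised (per-active-cell) MBON response is
    used rather than the raw sum so that comparisons between nearby
    positions reflect familiarity, not how many cells the scene drives."""

    def novelty(position) -> float:
        view = render_panorama(mesh, position, resolution,
                               eye_height=eye_height, el_range=el_range,
                               ground_value=ground_value)
        active = kc_activation(net, panorama_features(view, disk_size, n_max),
                               feature_norm)
        return mbon_novelty(net, active)[1]

    return novelty


def visual_homing_direction(net: MBNetwork, position, *,
                            novelty_fn: Callable,
                            U: float = 0.01, n_headings: int = 8,
                            rng: Optional[np.random.Generator] = None,
                            offset: float = 0.0) -> Tuple[float, bool]:
    """Heading of steepest novelty decrease (the visual nest estimate).

    Probes ``n_headings`` equally spaced headings at distance ``U`` and
    returns the one maximising the drop in MBON novelty (``novelty_fn``
    should give the normalised response, see :func:`make_novelty_fn`).
    Ties are broken uniformly at random with ``rng``; the second return
    value is False when all probes are indistinguishable (low confidence).
    """
    if n_headings < 4:
        raise ValueError("n_headings must be >= 4")
    if rng is None:
        rng = np.random.default_rng()
    position = np.asarray(position, dtype=float)
    here = novelty_fn(position)
    headings = offset + _TWO_PI * np.arange(n_headings) / n_headings
    decreases = np.array([
        here - novelty_fn(position + U * np.array([math.cos(h), math.sin(h)]))
        for h in headings])
    best = decreases.max()
    tied = np.flatnonzero(decreases >= best - 1e-12)
    choice = int(tied[rng.integers(len(tied))]) if len(tied) > 1 else int(tied[0])
    confident = decreases.max() - decreases.min() > 1e-12
    theta = math.atan2(math.sin(headings[choice]), math.cos(headings[choice]))
    return theta, confident
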