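"""Synthetic 3D environment: terrain mesh, panoramic views and odour field.

Coordinate conventions (used everywhere in the package):

* the nest sits at the origin ``(0, 0)``, distances are in meters;
* angles are in radians, measured counter-clockwise from the +x axis and
  wrapped to ``(-pi, pi]``;
* agents move in the x-y plane; the z axis only matters for rendering.

The terrain is a triangle-list mesh: a flat ground plane plus cone-shaped,
tussock-like objects scattered around the nest.  Panoramas are rendered by
casting one ray per (azimuth, elevation) pixel and segmenting the scene
into object (1), sky (0) and below-horizon ground (a fixed mid-value), the
skyline-contrast representation that snapshot-based homing models rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from numba import njit

__all__ = [
    "TerrainMesh",
    "OdourField",
    "PanoramicView",
    "wrap_angle",
    "generate_terrain",
    "render_panorama",
    "odour_concentration",
    "odour_gradient",
    "plume_concentration",
]

_TWO_PI = 2.0 * math.pi


def wrap_angle(theta):
    """Wrap an angle (or array of angles) to ``(-pi, pi]``."""
    wrapped = np.mod(-np.asarray(theta) + math.pi, _TWO_PI)
    return -(wrapped - math.pi)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

@dataclass
class TerrainMesh:
    """Triangle-list world geometry.

    ``triangles`` has shape ``(Np, 3, 3)``: Np triangles, 3 vertices each,
    (x, y, z) coordinates in meters.  The first ``n_ground`` triangles are
    the flat ground plane; the rest belong to scattered objects.
    """

    triangles: np.ndarray
    extent: float
    seed: int
    n_ground: int = 2

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    @property
    def object_triangles(self) -> np.ndarray:
        return self.triangles[self.n_ground:]

    def save(self, path) -> None:
        """Write one triangle per line: ``x1 y1 z1 x2 y2 z2 x3 y3 z3``."""
        flat = self.triangles.reshape(self.n_triangles, 9)
        header = f"extent={self.extent} seed={self.seed} n_ground={self.n_ground}"
        np.savetxt(path, flat, header=header)

    @classmethod
    def load(cls, path) -> "TerrainMesh":
        path = Path(path)
        meta = {}
        with path.open() as fh:
            first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if "=" in tok:
                    k, v = tok.split("=")
                    meta[k] = float(v)
        flat = np.loadtxt(path, ndmin=2)
        tris = flat.reshape(-1, 3, 3)
        return cls(
            triangles=tris,
            extent=float(meta.get("extent", np.abs(tris[..., :2]).max())),
            seed=int(meta.get("seed", -1)),
            n_ground=int(meta.get("n_ground", 2)),
        )


def _cone_triangles(cx: float, cy: float, radius: float, height: float,
                    n_sides: int = 8, phase: float = 0.0) -> np.ndarray:
    """Triangle fan of an upright cone (n_sides side triangles)."""
    az = phase + _TWO_PI * np.arange(n_sides + 1) / n_sides
    base = np.stack([cx + radius * np.cos(az), cy + radius * np.sin(az),
                     np.zeros(n_sides + 1)], axis=1)
    apex = np.array([cx, cy, height])
    tris = np.empty((n_sides, 3, 3))
    tris[:, 0] = base[:-1]
    tris[:, 1] = base[1:]
    tris[:, 2] = apex
    return tris


def generate_terrain(seed: int,
                     n_objects: int = 100,
                     height_range: Tuple[float, float] = (0.05, 0.35),
                     extent: float = 10.0,
                     *,
                     width_range: Tuple[float, float] = (0.05, 0.25),
                     scatter_radius: Optional[float] = None,
                     clear_radius: float = 0.1,
                     n_landmarks: int = 12,
                     landmark_height_range: Tuple[float, float] = (0.5, 1.8),
                     landmark_width_range: Tuple[float, float] = (0.3, 0.8),
                     triangles_per_object: int = 8) -> TerrainMesh:
    """Generate a seeded tussock-field terrain with distant landmarks.

    Small cone-shaped tussocks with random base radius and height are
    scattered uniformly over a disc of ``scatter_radius`` (default
    ``extent / 2``), keeping a clear disc of ``clear_radius`` around the
    nest.  A sparse ring of larger bush/tree-like cones (``n_landmarks``,
    placed between ``scatter_radius/2`` and ``0.9 * extent``) provides the
    heterogeneous distant skyline that keeps panoramic views globally
    distinctive.  Generation is fully deterministic per
    ``(seed, parameters)``.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    if n_objects < 0 or n_landmarks < 0:
        raise ValueError("object counts must be non-negative")
    if height_range[0] <= 0 or height_range[1] <= 0:
        raise ValueError("heights must be positive")
    if scatter_radius is None:
        scatter_radius = extent / 2.0

    rng = np.random.default_rng(seed)
    ground = np.array([
        [[-extent, -extent, 0.0], [extent, -extent, 0.0], [extent, extent, 0.0]],
        [[-extent, -extent, 0.0], [extent, extent, 0.0], [-extent, extent, 0.0]],
    ])
    parts = [ground]
    placed = 0
    tries = 0
    while placed < n_objects and tries < 200 * (n_objects + 1):
        tries += 1
        r = scatter_radius * math.sqrt(rng.random())
        az = rng.uniform(0.0, _TWO_PI)
        cx, cy = r * math.cos(az), r * math.sin(az)
        radius = rng.uniform(*width_range)
        height = rng.uniform(*height_range)
        phase = rng.uniform(0.0, _TWO_PI)
        if math.hypot(cx, cy) - radius < clear_radius:
            continue  # keep the nest surroundings clear
        parts.append(_cone_triangles(cx, cy, radius, height,
                                     n_sides=triangles_per_object, phase=phase))
        placed += 1
    placed = 0
    tries = 0
    lm_hi = 0.9 * extent
    lm_lo = min(scatter_radius / 2.0, 0.5 * lm_hi)
    while placed < n_landmarks and tries < 200 * (n_landmarks + 1):
        tries += 1
        r = rng.uniform(lm_lo, lm_hi)
        az = rng.uniform(0.0, _TWO_PI)
        cx, cy = r * math.cos(az), r * math.sin(az)
        radius = rng.uniform(*landmark_width_range)
        height = rng.uniform(*landmark_height_range)
        phase = rng.uniform(0.0, _TWO_PI)
        if math.hypot(cx, cy) - radius < clear_radius:
            continue  # a landmark overhanging the nest would blind it
        parts.append(_cone_triangles(cx, cy, radius, height,
                                     n_sides=triangles_per_object, phase=phase))
        placed += 1
    return TerrainMesh(triangles=np.concatenate(parts, axis=0),
                       extent=float(extent), seed=int(seed), n_ground=2)


# ---------------------------------------------------------------------------
# Panorama rendering
# ---------------------------------------------------------------------------

@dataclass
class PanoramicView:
    """Binary-ish panoramic snapshot.

    ``intensities`` has shape ``(n_el, n_az)``; row 0 is the lowest
    elevation.  Column ``j`` looks along azimuth ``2*pi*j/n_az`` (0 = +x,
    counter-clockwise).  Values: 1 object, 0 sky, ``ground_value`` ground.
    The image depends only on the viewing position; heading invariance is
    provided downstream by the Zernike-amplitude encoding.
    """

    intensities: np.ndarray
    el_min: float
    el_max: float

    @property
    def n_el(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_az(self) -> int:
        return int(self.intensities.shape[1])


@njit(cache=True)
def _raycast_objects(tris, cos_az, sin_az, cos_el, sin_el,
                     az_step, el_min_g, el_step):  # pragma: no cover - numba
    """Nearest-hit distance per (el, az) pixel against object triangles.

    Triangles are given in viewer-relative coordinates.  Each triangle is
    culled to the azimuth/elevation pixel ranges it can subtend before the
    per-ray Moller-Trumbore test.
    """
    n_el = cos_el.size
    n_az = cos_az.size
    tmin = np.full((n_el, n_az), np.inf)
    for t in range(tris.shape[0]):
        v0x, v0y, v0z = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
        v1x, v1y, v1z = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
        v2x, v2y, v2z = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]

        # angular bounding box of the triangle as seen from the origin
        full_az = False
        az0 = math.atan2(v0y, v0x)
        dmin = 0.0
        dmax = 0.0
        el_lo = 1e30
        el_hi = -1e30
        for k in range(3):
            vx, vy, vz = tris[t, k, 0], tris[t, k, 1], tris[t, k, 2]
            h = math.hypot(vx, vy)
            if h < 1e-9:
                full_az = True
                el_hi = math.pi / 2
                el_lo = -math.pi / 2
                continue
            d = math.atan2(vy, vx) - az0
            while d > math.pi:
                d -= 2 * math.pi
            while d <= -math.pi:
                d += 2 * math.pi
            if d < dmin:
                dmin = d
            if d > dmax:
                dmax = d
            el = math.atan2(vz, h)
            if el < el_lo:
                el_lo = el
            if el > el_hi:
                el_hi = el
        if dmax - dmin > math.pi:
            full_az = True

        if full_az:
            j_lo, j_hi = 0, n_az - 1
        else:
            a_lo = az0 + dmin - az_step
            a_hi = az0 + dmax + az_step
            j_lo = int(math.floor(a_lo / az_step))
            j_hi = int(math.ceil(a_hi / az_step))
            if j_hi - j_lo >= n_az:
                j_lo, j_hi = 0, n_az - 1
        i_lo = int(math.floor((el_lo - el_step - el_min_g) / el_step))
        i_hi = int(math.ceil((el_hi + el_step - el_min_g) / el_step))
        if i_lo < 0:
            i_lo = 0
        if i_hi > n_el - 1:
            i_hi = n_el - 1
        if i_hi < i_lo:
            continue

        e1x, e1y, e1z = v1x - v0x, v1y - v0y, v1z - v0z
        e2x, e2y, e2z = v2x - v0x, v2y - v0y, v2z - v0z
        for j in range(j_lo, j_hi + 1):
            jj = j % n_az
            ca, sa = cos_az[jj], sin_az[jj]
            for i in range(i_lo, i_hi + 1):
                dx = cos_el[i] * ca
                dy = cos_el[i] * sa
                dz = sin_el[i]
                # Moller-Trumbore, ray origin at (0,0,0)
                px = dy * e2z - dz * e2y
                py = dz * e2x - dx * e2z
                pz = dx * e2y - dy * e2x
                det = e1x * px + e1y * py + e1z * pz
                if -1e-12 < det < 1e-12:
                    continue
                inv = 1.0 / det
                u = -(v0x * px + v0y * py + v0z * pz) * inv
                if u < 0.0 or u > 1.0:
                    continue
                qx = -(v0y * e1z - v0z * e1y)
                qy = -(v0z * e1x - v0x * e1z)
                qz = -(v0x * e1y - v0y * e1x)
                v = (dx * qx + dy * qy + dz * qz) * inv
                if v < 0.0 or u + v > 1.0:
                    continue
                ray_t = (e2x * qx + e2y * qy + e2z * qz) * inv
                if 1e-9 < ray_t < tmin[i, jj]:
                    tmin[i, jj] = ray_t
    return tmin


def render_panorama(mesh: TerrainMesh,
                    position,
                    resolution: Tuple[int, int] = (90, 25),
                    *,
                    eye_height: float = 0.005,
                    el_range: Tuple[float, float] = (math.radians(-10), math.radians(60)),
                    ground_value: float = 0.5) -> PanoramicView:
    """Render the binary skyline panorama seen from ``position``.

    A pixel is 1 when its ray hits an object triangle before anything else,
    ``ground_value`` when the (below-horizon) ray reaches the ground plane
    first, and 0 (sky) otherwise.
    """
    x, y = float(position[0]), float(position[1])
    if abs(x) > mesh.extent or abs(y) > mesh.extent:
        raise ValueError(f"position {position} outside world extent {mesh.extent}")
    n_az, n_el = resolution
    el_min, el_max = el_range
    az = _TWO_PI * np.arange(n_az) / n_az
    el = np.linspace(el_min, el_max, n_el)
    obj = mesh.object_triangles
    if obj.shape[0] > 0:
        rel = np.ascontiguousarray(obj - np.array([x, y, eye_height]))
        tmin = _raycast_objects(rel, np.cos(az), np.sin(az), np.cos(el),
                                np.sin(el), _TWO_PI / n_az, el_min,
                                (el_max - el_min) / max(n_el - 1, 1))
    else:
        tmin = np.full((n_el, n_az), np.inf)
    # ground plane handled analytically (z = 0, eye at +eye_height)
    t_ground = np.full(n_el, np.inf)
    below = el < 0
    t_ground[below] = eye_height / np.sin(-el[below])
    img = np.zeros((n_el, n_az))
    obj_hit = tmin < t_ground[:, None]
    img[obj_hit] = 1.0
    img[~obj_hit & below[:, None]] = ground_value
    return PanoramicView(intensities=img, el_min=el_min, el_max=el_max)


# ---------------------------------------------------------------------------
# Odour field
# ---------------------------------------------------------------------------

@dataclass
class OdourField:
    """Nest-centred Gaussian concentration field.

    ``C(x, y) = c0 * exp(-(x^2 + y^2) / (2 sigma^2))`` for the isotropic
    case.  When ``wind = (direction, strength)`` is set, the downwind lobe
    is stretched (see :func:`plume_concentration`).
    """

    c0: float = 1.0
    sigma: float = 0.2
    centre: Tuple[float, float] = (0.0, 0.0)
    wind: Optional[Tuple[float, float]] = None
    stretch: float = 3.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")


def odour_concentration(f: OdourField, position) -> float:
    """Isotropic Gaussian concentration at ``position``."""
    x = position[0] - f.centre[0]
    y = position[1] - f.centre[1]
    return f.c0 * math.exp(-(x * x + y * y) / (2.0 * f.sigma ** 2))


def odour_gradient(f: OdourField, position) -> np.ndarray:
    """Closed-form gradient of the isotropic field (per meter)."""
    x = position[0] - f.centre[0]
    y = position[1] - f.centre[1]
    c = odour_concentration(f, position)
    return (c / f.sigma ** 2) * np.array([-x, -y])


def plume_concentration(f: OdourField, position) -> float:
    """Anisotropic (wind-stretched) Gaussian plume concentration.

    The downwind axis is elongated by ``1 + (stretch - 1) * strength``;
    the upwind and crosswind widths stay at ``sigma``, so the plume forms a
    one-sided lobe.  Reduces exactly to the isotropic field at zero wind.
    """
    if f.wind is None:
        raise ValueError("plume_concentration requires a wind setting")
    direction, strength = f.wind
    x = position[0] - f.centre[0]
    y = position[1] - f.centre[1]
    u = x * math.cos(direction) + y * math.sin(direction)  # downwind coord
    v = -x * math.sin(direction) + y * math.cos(direction)
    s = 1.0 + (f.stretch - 1.0) * max(float(strength), 0.0)
    sigma_u = f.sigma * s if u > 0 else f.sigma
    return f.c0 * math.exp(-(u * u / (2.0 * sigma_u ** 2)
                             + v * v / (2.0 * f.sigma ** 2)))
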