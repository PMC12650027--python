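"""Configuration containers for the learning-walk simulator.

Every tunable of the model lives here, grouped by subsystem.  The defaults
are the nominal study conditions used throughout the package: a visually
rich tussock field, a nest-centred CO2-like odour field with sigma = 0.15 m,
the 81-VPN / 4000-KC mushroom-body network, and the four-walk protocol with
a doubling step budget.  ``SimConfig`` round-trips to YAML/JSON-style nested
dicts so runs can be reproduced from a config file plus a master seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = [
    "WorldConfig",
    "OdourConfig",
    "MBConfig",
    "PIConfig",
    "LVConfig",
    "AgentConfig",
    "SimConfig",
    "nominal_config",
]


@dataclass
class WorldConfig:
    """Synthetic terrain and panorama-rendering parameters."""

    n_objects: int = 100
    extent: float = 10.0  # bounding square half-width [m]
    height_range: Tuple[float, float] = (0.05, 0.35)  # tussock heights [m]
    width_range: Tuple[float, float] = (0.05, 0.25)  # tussock base radii [m]
    scatter_radius: float = 5.0  # objects placed within this disc [m]
    clear_radius: float = 0.1  # object-free disc around the nest [m]
    n_landmarks: int = 12  # large bush/tree cones on the far skyline
    landmark_height_range: Tuple[float, float] = (0.5, 1.8)
    landmark_width_range: Tuple[float, float] = (0.3, 0.8)
    n_az: int = 90  # panorama azimuth resolution
    n_el: int = 25  # panorama elevation resolution
    el_min: float = math.radians(-10.0)
    el_max: float = math.radians(60.0)
    eye_height: float = 0.005  # viewer eye height above ground [m]
    ground_value: float = 0.5  # intensity of below-horizon ground pixels


@dataclass
class OdourConfig:
    """Nest-centred Gaussian odour field (optionally wind-stretched)."""

    c0: float = 1.0  # normalised peak concentration at the nest
    sigma: float = 0.15  # diffusion spread [m]
    wind: Optional[Tuple[float, float]] = None  # (direction [rad], strength)
    stretch: float = 3.0  # downwind elongation factor at strength 1


@dataclass
class MBConfig:
    """Mushroom-body network and visual encoding parameters."""

    n_vpn: int = 81  # Zernike amplitudes fed to the VPN layer (n_max = 16)
    n_kc: int = 4000
    theta_kc: float = 0.04  # KC activation threshold
    lambda_vis: float = 0.018  # per-exposure synaptic depression
    fan_in: int = 2  # VPNs sampled by each KC (sparse drive)
    n_headings: int = 8  # headings probed during a scan
    normalizer_mode: str = "active"  # "active" or "nkc" familiarity normaliser
    feature_norm: str = "l1"  # per-presentation VPN scaling: "l1" or "minmax"
    disk_size: int = 64  # unit-disk raster resolution for Zernike moments


@dataclass
class PIConfig:
    """Path integration and the per-walk expected-range schedule."""

    noise_sd: float = 1e-4  # per-component per-step PI noise [m]
    d1: float = 0.184  # empirical first-walk maximum distance [m]
    multipliers: Tuple[float, ...] = (3.8, 2.0, 2.0)
    fpi_scaled: bool = False  # map the r/d_k ratio onto [0, pi]
    fpi_clamped: bool = False  # cap the r/d_k ratio at 1
    fpi_scale: Optional[float] = None  # explicit angular gain (overrides fpi_scaled)


@dataclass
class LVConfig:
    """Learning-Vector fusion parameters."""

    sign_mode: str = "random"  # "random" (per-segment sign) or "ccw" (literal)
    clamp_phi: bool = True
    fv_window: int = 300  # sliding-window length for the novelty trace


@dataclass
class AgentConfig:
    """Movement, scanning and walk-protocol parameters."""

    step_size: float = 0.01  # U [m]
    p_rand: float = 0.5  # probability of a stochastic step
    kappa: float = 5.0  # von Mises concentration of stochastic headings
    np1: int = 120  # expected exploration steps in walk 1
    growth: float = 2.0  # per-walk step-budget growth rate
    scans_per_walk: Tuple[int, ...] = (12, 18, 24, 32)
    nest_radius: float = 0.05  # walk-completion radius [m]
    success_radius: float = 0.1  # homing-test success radius [m]
    max_homing_steps: int = 3000
    p_rand_test: float = 0.1  # stochastic-step probability during recall tests


@dataclass
class SimConfig:
    """Aggregate configuration for a full simulation."""

    world: WorldConfig = field(default_factory=WorldConfig)
    odour: OdourConfig = field(default_factory=OdourConfig)
    mb: MBConfig = field(default_factory=MBConfig)
    pi: PIConfig = field(default_factory=PIConfig)
    lv: LVConfig = field(default_factory=LVConfig)
    agent: AgentConfig = field(default_factory=AgentConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        def build(klass, sub):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name in sub:
                    v = sub[f.name]
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[f.name] = v
            return klass(**kwargs)

        return cls(
            world=build(WorldConfig, d.get("world", {})),
            odour=build(OdourConfig, d.get("odour", {})),
            mb=build(MBConfig, d.get("mb", {})),
            pi=build(PIConfig, d.get("pi", {})),
            lv=build(LVConfig, d.get("lv", {})),
            agent=build(AgentConfig, d.get("agent", {})),
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def nominal_config() -> SimConfig:
    """The nominal study conditions (all defaults)."""
    return SimConfig()
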