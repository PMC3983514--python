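"""Simulation configuration: apparatus geometry, rod material, growth protocol.

All lengths are millimetres, all angles degrees unless noted otherwise.
The default configuration encodes the desk-scale apparatus: a rigid
hemispherical "pericardial" cavity of inner diameter 136 mm sitting on a
plane dorsal stage, a silicone-rubber rod stand-in for the heart tube
(480 mm long, 23 mm diameter), and quasi-static feeding of rod material
through the cranial port.

Coordinate frame (right-handed): +x runs cranial -> caudal, +y points to
the embryo's left, +z is ventral; the dome occupies z > 0 with the dorsal
floor plane at z = 0.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

SCHEMA_VERSION = 1


@dataclass
class CavityGeometry:
    """Rigid hemispherical cavity on a dorsal floor plane.

    The cranial and caudal ports are openings on the rim circle (z = 0),
    antipodal along the cranio-caudal (x) axis.  ``port_height`` is the
    height above the floor at which the rod centerline crosses the port
    (the rod rests on the floor, so this defaults to the rod radius).
    ``port_axis_tilt`` is the ventral tilt of the end-clamp axes, degrees.
    ``port_window_deg`` is the angular half-width of the contact exemption
    window around each port axis, so the rod can pass through the openings.
    """

    inner_radius: float = 68.0
    port_axis_tilt: float = 10.0
    port_height: float = 11.5
    port_window_deg: float = 14.0

    @property
    def cranial_port(self) -> np.ndarray:
        return np.array([-self.inner_radius, 0.0, self.port_height])

    @property
    def caudal_port(self) -> np.ndarray:
        return np.array([self.inner_radius, 0.0, self.port_height])

    @property
    def floor_normal(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    @property
    def length(self) -> float:
        """Cranio-caudal cavity length (port-to-port distance)."""
        return 2.0 * self.inner_radius


@dataclass
class RodModel:
    """Elastic rod: geometry and (nondimensionalized) stiffnesses.

    The bend stiffness is the unit of the energy scale; equilibrium shapes
    of a near-inextensible rod without gravity are independent of the
    modulus, so only the ratios matter.  The twist-to-bend ratio 2/3 is
    the isotropic-rod value ``1/(1 + nu)`` at ``nu = 0.5`` (incompressible
    rubber).  ``weight_per_length`` is expressed in the same nondimensional
    force unit; it is only used when gravity is enabled.
    """

    total_length: float = 480.0
    radius: float = 11.5
    stretch_stiffness: float = 10.0
    bend_stiffness: float = 1.0
    twist_stiffness: float = 2.0 / 3.0
    weight_per_length: float = 5.4e-7


@dataclass
class GrowthProtocol:
    """Quasi-static feeding of rod length through the cranial port."""

    initial_fed_length: float = 136.0
    final_fed_length: float = 350.0
    feed_increment: float = 1.0
    feed_end: str = "cranial"


@dataclass
class PerturbationSpec:
    """Symmetry breaking: seeded lateral micro-noise plus caudal offset.

    ``caudal_offset`` is the signed pre-buckling displacement of the caudal
    clamp along the left-right axis (+ = leftward, i.e. +y).  Noise of RMS
    ``noise_amplitude`` is added to the interior nodes' y coordinates while
    the configuration is still planar, emulating apparatus imperfection.
    """

    noise_amplitude: float = 0.065
    seed: int = 0
    caudal_offset: float = 0.0


@dataclass
class SimulationConfig:
    cavity: CavityGeometry = field(default_factory=CavityGeometry)
    rod: RodModel = field(default_factory=RodModel)
    growth: GrowthProtocol = field(default_factory=GrowthProtocol)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    node_spacing: float = 4.0
    contact_penalty_stiffness: float = 5.0
    friction_coefficient: float = 0.0
    gravity_enabled: bool = False
    confinement_enabled: bool = True
    floor_enabled: bool = True
    caudal_boundary: str = "fixed"  # "fixed" | "free_lateral"
    caudal_rail_limit: float = 50.0  # free_lateral: max lateral clamp travel, mm
    solver_tolerance: float = 1.0e-4
    max_iterations: int = 4000
    # morphometric thresholds (fractions of cavity radius unless stated)
    straight_deflection_frac: float = 0.05
    planarity_rms_frac: float = 0.05
    flop_rms_frac: float = 0.10
    writhe_dead_zone: float = 0.05
    torsion_run_min_frac: float = 0.15
    # self-contact handling; skip None = auto (edges within ~3 rod radii of
    # arclength are never contact candidates — the rod surface cannot meet
    # itself over so short a geodesic distance)
    self_contact_skip: int | None = None
    self_contact_onset_length: float = 170.0
    schema_version: int = SCHEMA_VERSION


def default_config() -> SimulationConfig:
    """The apparatus defaults: confined, gravity off, midline, fixed caudal end."""
    return SimulationConfig()


def ensemble_config(
    caudal_offset: float = 0.0,
    *,
    node_spacing: float = 9.0,
    feed_increment: float = 3.0,
    final_fed_length: float = 200.0,
    solver_tolerance: float = 3.0e-4,
) -> SimulationConfig:
    """Coarser configuration for chirality ensembles.

    Handedness is decided at the sinusoidal-to-helical bifurcation
    (~175 mm fed length) and is locked in well before 200 mm, so ensemble
    runs stop shortly after onset and use a coarser discretization and a
    looser equilibrium tolerance than the single full-growth run.
    """
    cfg = default_config()
    cfg.perturbation.caudal_offset = caudal_offset
    cfg.node_spacing = node_spacing
    cfg.growth.feed_increment = feed_increment
    cfg.growth.final_fed_length = final_fed_length
    cfg.solver_tolerance = solver_tolerance
    return cfg


def validate_config(config: SimulationConfig) -> list[str]:
    """Return a list of invariant violations (empty iff the config is valid)."""
    v: list[str] = []
    cav, rod, gro, per = config.cavity, config.rod, config.growth, config.perturbation
    if cav.inner_radius <= 0:
        v.append("cavity.inner_radius must be > 0")
    if not (0 <= cav.port_axis_tilt < 90):
        v.append("cavity.port_axis_tilt must be in [0, 90) degrees")
    if not (0 <= cav.port_height < cav.inner_radius):
        v.append("cavity.port_height must be in [0, inner_radius)")
    if rod.radius <= 0:
        v.append("rod.radius must be > 0")
    if rod.total_length <= 2 * cav.inner_radius:
        v.append("rod.total_length must exceed the cavity chord")
    for name in ("stretch_stiffness", "bend_stiffness", "twist_stiffness"):
        if getattr(rod, name) <= 0:
            v.append(f"rod.{name} must be > 0")
    if rod.weight_per_length < 0:
        v.append("rod.weight_per_length must be >= 0")
    if rod.stretch_stiffness * config.node_spacing ** 2 < 100 * rod.bend_stiffness:
        v.append("rod.stretch_stiffness too low for the near-inextensible regime")
    if gro.initial_fed_length > gro.final_fed_length:
        v.append("growth.initial_fed_length must be <= final_fed_length")
    if gro.final_fed_length > rod.total_length:
        v.append("growth.final_fed_length must not exceed rod.total_length")
    if gro.feed_increment <= 0:
        v.append("growth.feed_increment must be > 0")
    if gro.feed_end != "cranial":
        v.append("growth.feed_end must be 'cranial'")
    if gro.initial_fed_length < cav.length:
        v.append("growth.initial_fed_length must be >= the port-to-port chord")
    if per.noise_amplitude < 0:
        v.append("perturbation.noise_amplitude must be >= 0")
    if abs(per.caudal_offset) >= cav.inner_radius:
        v.append("perturbation.caudal_offset magnitude must be < inner_radius")
    if config.node_spacing >= 2 * rod.radius:
        v.append("node_spacing must be < rod diameter")
    if config.node_spacing <= 0:
        v.append("node_spacing must be > 0")
    if config.contact_penalty_stiffness <= 0:
        v.append("contact_penalty_stiffness must be > 0")
    if config.friction_coefficient < 0:
        v.append("friction_coefficient must be >= 0")
    if config.solver_tolerance <= 0:
        v.append("solver_tolerance must be > 0")
    if config.max_iterations < 1:
        v.append("max_iterations must be >= 1")
    if config.caudal_boundary not in ("fixed", "free_lateral"):
        v.append("caudal_boundary must be 'fixed' or 'free_lateral'")
    if config.self_contact_skip is not None and config.self_contact_skip < 2:
        v.append("self_contact_skip must be >= 2 (or None for automatic)")
    return v


def resolved_self_contact_skip(config: SimulationConfig) -> int:
    """Effective skip window: configured value, or ~3 rod radii of arclength."""
    if config.self_contact_skip is not None:
        return config.self_contact_skip
    return max(2, int(math.ceil(3.0 * config.rod.radius / config.node_spacing)))


# ---------------------------------------------------------------------------
# serialization

def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["schema_version"] = SCHEMA_VERSION
    return d


def config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = copy.deepcopy(d)
    version = d.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    sub = {
        "cavity": CavityGeometry,
        "rod": RodModel,
        "growth": GrowthProtocol,
        "perturbation": PerturbationSpec,
    }
    kwargs: dict[str, Any] = {}
    for key, val in d.items():
        if key in sub:
            kwargs[key] = sub[key](**val)
        else:
            kwargs[key] = val
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the config as YAML (canonical on-disk schema, units mm/degrees)."""
    with open(path, "w") as fh:
        fh.write("# cardiobuckle configuration; units: mm, degrees\n")
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def apply_overrides(config: SimulationConfig, overrides: dict[str, str]) -> SimulationConfig:
    """Apply dotted-key overrides like ``perturbation.caudal_offset=2.0``."""
    cfg = copy.deepcopy(config)
    for dotted, raw in overrides.items():
        obj: Any = cfg
        *parents, leaf = dotted.split(".")
        for p in parents:
            obj = getattr(obj, p)
        current = getattr(obj, leaf)
        if isinstance(current, bool):
            value: Any = raw if isinstance(raw, bool) else str(raw).lower() in ("1", "true", "yes")
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(raw)
        elif isinstance(current, float):
            value = float(raw)
        else:
            value = raw
        setattr(obj, leaf, value)
    return cfg


def clamp_tangents(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents imposed at the cranial and caudal clamps.

    Both clamp axes are tilted ventrally (toward +z) by ``port_axis_tilt``
    so planar bending is consistently directed toward the mid-ventral dome.
    The rod runs cranial -> caudal (+x); the caudal clamp tangent therefore
    dips back toward the floor so the bow rises between the ports.
    """
    t = math.radians(config.cavity.port_axis_tilt)
    cranial = np.array([math.cos(t), 0.0, math.sin(t)])
    caudal = np.array([math.cos(t), 0.0, -math.sin(t)])
    return cranial, caudal
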