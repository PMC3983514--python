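"""Analytic centerline fixtures: straight rods, planar arcs, helices, perversions.

These are the idealized geometries the morphometric classifiers must
recognize — a straight tube, a planar (sinusoidal-phase) arc, single-handed
helices of either chirality, and a two-handed helix joined by a perversion.
All curves are generated along the cranio-caudal (+x) axis in the package's
right-handed frame (+y = embryo-left, +z = ventral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rod import Centerline

KINDS = ("straight", "planar_arc", "helix", "perversion")


@dataclass
class FixtureSpec:
    kind: str
    length: float = 200.0           # straight / planar_arc arclength, mm
    radius: float = 20.0            # helix or arc radius, mm
    pitch: float = 40.0             # helix advance per turn, mm
    turns: float = 2.0              # turns per helical limb
    handedness: str = "right"       # helix chirality; for perversion: caudal limb
    n_nodes: int = 200
    arc_angle: float = 90.0         # planar_arc subtended angle, degrees
    jitter: float = 0.0             # RMS node jitter, mm
    seed: int = 0

    def validate(self) -> list[str]:
        v = []
        if self.kind not in KINDS:
            v.append(f"kind must be one of {KINDS}")
        if self.n_nodes < 4:
            v.append("n_nodes must be >= 4")
        for name in ("length", "radius", "pitch"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be > 0")
        if self.turns <= 0:
            v.append("turns must be > 0")
        if self.handedness not in ("left", "right"):
            v.append("handedness must be 'left' or 'right'")
        if self.jitter < 0:
            v.append("jitter must be >= 0")
        return v


def _helix_points(a: float, pitch: float, turns: float, n: int, right: bool) -> np.ndarray:
    """Helix about the +x axis; right-handed winds +y toward +z as x advances."""
    t = np.linspace(0.0, 2.0 * np.pi * turns, n)
    c = pitch / (2.0 * np.pi)
    sign = 1.0 if right else -1.0
    return np.column_stack([c * t, a * np.cos(t), sign * a * np.sin(t)])


def _perversion_points(a: float, pitch: float, turns: float, n: int,
                       caudal_right: bool) -> np.ndarray:
    """Two mirror-image helical limbs joined with tangent continuity at x = 0.

    The limb parametrization ``(c t, ±a (1 - cos t), a sin t)`` has a
    y-tangent that vanishes at the junction, so mirroring y across t = 0
    keeps the curve C1; the second derivative flips there (the perversion's
    inflection).  The caudal limb is the t > 0 (larger-x) half.
    """
    t = np.linspace(-2.0 * np.pi * turns, 2.0 * np.pi * turns, n)
    c = pitch / (2.0 * np.pi)
    ysign = np.where(t >= 0.0, 1.0, -1.0)
    pts = np.column_stack([c * t, ysign * a * (1.0 - np.cos(t)), a * np.sin(t)])
    # the +y limb of this parametrization is left-handed; mirror if the
    # caudal limb is requested right-handed
    if caudal_right:
        pts[:, 1] = -pts[:, 1]
    return pts


def generate_fixture(spec: FixtureSpec) -> Centerline:
    problems = spec.validate()
    if problems:
        raise ValueError("invalid fixture spec: " + "; ".join(problems))
    n = spec.n_nodes
    if spec.kind == "straight":
        x = np.linspace(0.0, spec.length, n)
        pts = np.column_stack([x, np.zeros(n), np.zeros(n)])
    elif spec.kind == "planar_arc":
        # sagittal (x-z) plane arc of arclength ``length`` subtending
        # ``arc_angle`` (cavity-scale, like the sinusoidal bow)
        full = np.radians(spec.arc_angle)
        radius = spec.length / full
        ang = np.linspace(-full / 2.0, full / 2.0, n)
        pts = np.column_stack([
            radius * np.sin(ang),
            np.zeros(n),
            radius * np.cos(ang),
        ])
    elif spec.kind == "helix":
        pts = _helix_points(spec.radius, spec.pitch, spec.turns, n,
                            right=spec.handedness == "right")
    else:  # perversion
        pts = _perversion_points(spec.radius, spec.pitch, spec.turns, n,
                                 caudal_right=spec.handedness == "right")
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.jitter, size=pts.shape)
    return Centerline.from_nodes(pts)
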