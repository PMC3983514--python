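"""Discrete Kirchhoff rod: state, elastic energies, and equilibrium solver.

The rod is a polyline of nodes with per-edge rest lengths.  Elastic energy
is the classical decoupled quadratic form

* stretch:  sum_i  1/2 k_s (|e_i| - l_i)^2 / l_i
* bend:     sum_i  B |kb_i|^2 / (2 lbar_i)   with the curvature binormal
  kb_i = 2 e_{i-1} x e_i / (|e_{i-1}||e_i| + e_{i-1}.e_i), |kb| = 2 tan(phi/2)
* twist:    quasistatic material frame between clamped end directors —
  the twist relaxes to uniform density, leaving C Theta^2 / (2 L) where
  Theta is the total material twist imposed by the clamps minus the
  parallel-transport holonomy of the centerline.

Clamps are hard constraints: end nodes are fixed and the first/last edge
direction is fixed, while the first/last edge *length* is a sliding degree
of freedom (the rod feeds through the ports).  Equilibria are found by
L-BFGS-B on the free coordinates with the analytic gradient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .config import SimulationConfig, clamp_tangents


class DegenerateGeometryError(ValueError):
    pass


class SolverFailure(RuntimeError):
    """Equilibrium solve did not meet the gradient tolerance."""

    def __init__(self, message: str, state: "RodState", diagnostics: "SolveDiagnostics"):
        super().__init__(message)
        self.state = state
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# geometry containers


@dataclass
class Centerline:
    """Ordered 3-D nodes (index 0 = cranial) with per-edge rest lengths, mm."""

    nodes: np.ndarray          # (M, 3)
    rest_lengths: np.ndarray   # (M-1,)

    @classmethod
    def from_nodes(cls, nodes: np.ndarray, total_rest_length: float | None = None) -> "Centerline":
        nodes = np.asarray(nodes, dtype=float)
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise DegenerateGeometryError("duplicate consecutive nodes")
        if total_rest_length is not None:
            seg = seg * (total_rest_length / seg.sum())
        return cls(nodes=nodes, rest_lengths=seg)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each node (rest parametrization)."""
        return np.concatenate([[0.0], np.cumsum(self.rest_lengths)])

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)


@dataclass
class SolveDiagnostics:
    converged: bool
    iterations: int
    grad_norm: float
    energy: float
    message: str = ""
    penalty_escalations: int = 0


@dataclass
class RodState:
    centerline: Centerline
    edge_twists: np.ndarray            # per-edge material angle vs reference frame, rad
    reference_frames: np.ndarray       # per-edge Bishop director, (M-1, 3)
    fed_length: float
    clamp_frames: Optional[np.ndarray] = None  # (2, 3) material directors at clamps
    twist_total: float = 0.0           # unwrapped total material twist, rad
    caudal_y: float = 0.0              # lateral caudal-clamp displacement (free_lateral)
    last_solve: Optional[SolveDiagnostics] = None

    @property
    def nodes(self) -> np.ndarray:
        return self.centerline.nodes

    def copy(self) -> "RodState":
        return RodState(
            centerline=Centerline(self.centerline.nodes.copy(),
                                  self.centerline.rest_lengths.copy()),
            edge_twists=self.edge_twists.copy(),
            reference_frames=self.reference_frames.copy(),
            fed_length=self.fed_length,
            clamp_frames=None if self.clamp_frames is None else self.clamp_frames.copy(),
            twist_total=self.twist_total,
            caudal_y=self.caudal_y,
            last_solve=self.last_solve,
        )


@dataclass
class EnergyBreakdown:
    stretch: float
    bend: float
    twist: float
    gravity: float
    contact: float

    @property
    def total(self) -> float:
        return self.stretch + self.bend + self.twist + self.gravity + self.contact


# ---------------------------------------------------------------------------
# frames and transport


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def parallel_transport_frames(nodes: np.ndarray, first_director: np.ndarray) -> np.ndarray:
    """Bishop frame directors per edge, transported from the first edge.

    Each step rotates the director by the minimal rotation taking tangent i
    to tangent i+1 (Rodrigues about t_i x t_{i+1}).
    """
    edges = np.diff(nodes, axis=0)
    lens = np.linalg.norm(edges, axis=1)
    if np.any(lens == 0.0):
        raise DegenerateGeometryError("duplicate consecutive nodes")
    t = edges / lens[:, None]
    n_edges = t.shape[0]
    a = np.empty((n_edges, 3))
    d = np.asarray(first_director, dtype=float)
    d = d - np.dot(d, t[0]) * t[0]
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise DegenerateGeometryError("first director parallel to first tangent")
    d = d / nd
    a[0] = d
    # scalar loop (hot path): Rodrigues with unnormalized axis t0 x t1,
    # |axis| = sin(phi), cos(phi) = t0.t1
    tl = t.tolist()
    dx, dy, dz = float(d[0]), float(d[1]), float(d[2])
    out = a
    for i in range(n_edges - 1):
        t0x, t0y, t0z = tl[i]
        t1x, t1y, t1z = tl[i + 1]
        kx = t0y * t1z - t0z * t1y
        ky = t0z * t1x - t0x * t1z
        kz = t0x * t1y - t0y * t1x
        c = t0x * t1x + t0y * t1y + t0z * t1z
        s2 = kx * kx + ky * ky + kz * kz
        if s2 < 1e-28:
            if c < 0.0:
                raise DegenerateGeometryError("tangent reversal during transport")
        else:
            kd = (kx * dx + ky * dy + kz * dz) / (1.0 + c)
            nx = c * dx + (ky * dz - kz * dy) + kd * kx
            ny = c * dy + (kz * dx - kx * dz) + kd * ky
            nz = c * dz + (kx * dy - ky * dx) + kd * kz
            # project out the tangent component and renormalize
            pt = nx * t1x + ny * t1y + nz * t1z
            nx -= pt * t1x
            ny -= pt * t1y
            nz -= pt * t1z
            inv = 1.0 / (nx * nx + ny * ny + nz * nz) ** 0.5
            dx, dy, dz = nx * inv, ny * inv, nz * inv
        out[i + 1, 0] = dx
        out[i + 1, 1] = dy
        out[i + 1, 2] = dz
    return out


def frame_deviation(state: RodState) -> float:
    """Max deviation between stored reference frames and fresh transport."""
    if state.clamp_frames is None:
        return 0.0
    fresh = parallel_transport_frames(state.nodes, state.clamp_frames[0])
    return float(np.max(np.linalg.norm(fresh - state.reference_frames, axis=1)))


def _signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle from a to b about axis (all ~unit, a,b ~perp to axis)."""
    return float(np.arctan2(np.dot(np.cross(a, b), axis), np.dot(a, b)))


def total_twist(nodes: np.ndarray, clamp_frames: np.ndarray, prev: float = 0.0) -> float:
    """Unwrapped total material twist between the clamp directors.

    Transports the cranial director to the last edge and measures the angle
    to the caudal clamp director about the last tangent; the 2*pi branch is
    chosen nearest ``prev`` (quasi-static continuation conserves the branch,
    as the physical clamps cannot spin).
    """
    a = parallel_transport_frames(nodes, clamp_frames[0])
    t_last = _unit(nodes[-1] - nodes[-2])
    m = clamp_frames[1] - np.dot(clamp_frames[1], t_last) * t_last
    nm = np.linalg.norm(m)
    if nm < 1e-12:
        raise DegenerateGeometryError("caudal director parallel to last tangent")
    m = m / nm
    raw = _signed_angle(a[-1], m, t_last)
    return raw + 2.0 * np.pi * np.round((prev - raw) / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# standalone energies (the clear, per-term reference path)


def stretch_energy(state: RodState, rod) -> float:
    """Quadratic penalty on edge strain: 1/2 k_s (|e| - l)^2 / l per edge."""
    rest = state.centerline.rest_lengths
    if np.any(rest <= 0.0):
        raise DegenerateGeometryError("non-positive rest length")
    lens = state.centerline.edge_lengths()
    return float(0.5 * rod.stretch_stiffness * np.sum((lens - rest) ** 2 / rest))


def _curvature_binormals(nodes: np.ndarray):
    e = np.diff(nodes, axis=0)
    l = np.linalg.norm(e, axis=1)
    if np.any(l == 0.0):
        raise DegenerateGeometryError("duplicate consecutive nodes")
    u, v = e[:-1], e[1:]
    lu, lv = l[:-1], l[1:]
    chi = lu * lv + np.einsum("ij,ij->i", u, v)
    if np.any(chi <= 0.0):
        raise DegenerateGeometryError("edge fold-back (180 degree turn)")
    kb = 2.0 * np.cross(u, v) / chi[:, None]
    return e, l, kb, chi


def bend_energy(state: RodState, rod) -> float:
    """Discrete bending energy B |kb|^2 / (2 lbar) summed over interior nodes."""
    _, _, kb, _ = _curvature_binormals(state.nodes)
    rest = state.centerline.rest_lengths
    lbar = 0.5 * (rest[:-1] + rest[1:])
    return float(rod.bend_stiffness * np.sum(np.einsum("ij,ij->i", kb, kb) / (2.0 * lbar)))


def twist_energy(state: RodState, rod) -> float:
    """Material twist energy against the parallel-transported reference frame.

    Uses the stored per-edge angles; the clamp directors close the two end
    half-edges so a uniform density Theta/L gives exactly C Theta^2 / (2 L).
    """
    if state.clamp_frames is None:
        return 0.0
    if frame_deviation(state) > 1e-8:
        raise ValueError("stale reference frames: re-derive by parallel transport")
    theta = state.edge_twists
    rest = state.centerline.rest_lengths
    end_angle = total_twist(state.nodes, state.clamp_frames, prev=state.twist_total)
    segs = np.concatenate([[theta[0] - 0.0], np.diff(theta), [end_angle - theta[-1]]])
    lens = np.concatenate([[0.5 * rest[0]],
                           0.5 * (rest[:-1] + rest[1:]),
                           [0.5 * rest[-1]]])
    return float(0.5 * rod.twist_stiffness * np.sum(segs ** 2 / lens))


def gravity_energy(state: RodState, config: SimulationConfig) -> float:
    if not config.gravity_enabled or config.rod.weight_per_length == 0.0:
        return 0.0
    rest = state.centerline.rest_lengths
    node_l = np.concatenate([[0.5 * rest[0]],
                             0.5 * (rest[:-1] + rest[1:]),
                             [0.5 * rest[-1]]])
    return float(config.rod.weight_per_length * np.sum(node_l * state.nodes[:, 2]))


def energy_breakdown(state: RodState, config: SimulationConfig) -> EnergyBreakdown:
    from .contact import total_contact_energy
    return EnergyBreakdown(
        stretch=stretch_energy(state, config.rod),
        bend=bend_energy(state, config.rod),
        twist=twist_energy(state, config.rod),
        gravity=gravity_energy(state, config),
        contact=total_contact_energy(state, config),
    )


# ---------------------------------------------------------------------------
# boundary handling / DOF packing


@dataclass
class BoundarySpec:
    """How the two rod ends are constrained.

    ``clamped`` fixes end node positions and first/last edge directions;
    the first/last edge lengths slide along the clamp rays (the rod feeds
    through the ports).  ``free_caudal_y`` lets the whole caudal clamp
    translate along y (Experiment-4 rail).  ``pinned`` fixes only the end
    node positions (used for classical elastica checks); twist is inactive
    then, since no material frame is imposed.
    """

    mode: str = "clamped"              # "clamped" | "pinned"
    cranial_base: np.ndarray = field(default_factory=lambda: np.zeros(3))
    caudal_base: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t_cranial: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    t_caudal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    free_caudal_y: bool = False

    @classmethod
    def from_config(cls, config: SimulationConfig, caudal_offset: float | None = None) -> "BoundarySpec":
        t_cran, t_caud = clamp_tangents(config)
        off = config.perturbation.caudal_offset if caudal_offset is None else caudal_offset
        caud = config.cavity.caudal_port + np.array([0.0, off, 0.0])
        return cls(
            mode="clamped",
            cranial_base=config.cavity.cranial_port.copy(),
            caudal_base=caud,
            t_cranial=t_cran,
            t_caudal=t_caud,
            free_caudal_y=config.caudal_boundary == "free_lateral",
        )


class _DofMap:
    """Pack/unpack free coordinates <-> node positions for a boundary spec."""

    def __init__(self, boundary: BoundarySpec, n_nodes: int):
        self.b = boundary
        self.m = n_nodes
        if boundary.mode == "clamped":
            self.n_interior = n_nodes - 4          # nodes 2 .. m-3
            self.size = 3 * self.n_interior + 2 + (1 if boundary.free_caudal_y else 0)
        else:  # pinned
            self.n_interior = n_nodes - 2
            self.size = 3 * self.n_interior

    def pack(self, state: RodState) -> np.ndarray:
        x = state.nodes
        if self.b.mode == "pinned":
            return x[1:-1].ravel().copy()
        dof = np.empty(self.size)
        dof[: 3 * self.n_interior] = x[2:-2].ravel()
        dof[3 * self.n_interior] = np.linalg.norm(x[1] - x[0])
        dof[3 * self.n_interior + 1] = np.linalg.norm(x[-1] - x[-2])
        if self.b.free_caudal_y:
            dof[-1] = state.caudal_y
        return dof

    def unpack(self, dof: np.ndarray) -> np.ndarray:
        b = self.b
        x = np.empty((self.m, 3))
        if b.mode == "pinned":
            x[0] = b.cranial_base
            x[-1] = b.caudal_base
            x[1:-1] = dof.reshape(-1, 3)
            return x
        ni = self.n_interior
        x[2:-2] = dof[: 3 * ni].reshape(-1, 3)
        s_c = dof[3 * ni]
        s_d = dof[3 * ni + 1]
        dy = dof[-1] if b.free_caudal_y else 0.0
        shift = np.array([0.0, dy, 0.0])
        x[0] = b.cranial_base
        x[1] = b.cranial_base + s_c * b.t_cranial
        x[-1] = b.caudal_base + shift
        x[-2] = x[-1] - s_d * b.t_caudal
        return x

    def chain(self, grad_nodes: np.ndarray) -> np.ndarray:
        """Map a (m,3) node-gradient to the free-DOF gradient."""
        b = self.b
        if b.mode == "pinned":
            return grad_nodes[1:-1].ravel()
        ni = self.n_interior
        g = np.empty(self.size)
        g[: 3 * ni] = grad_nodes[2:-2].ravel()
        g[3 * ni] = float(np.dot(b.t_cranial, grad_nodes[1]))
        g[3 * ni + 1] = -float(np.dot(b.t_caudal, grad_nodes[-2]))
        if b.free_caudal_y:
            g[-1] = grad_nodes[-2, 1] + grad_nodes[-1, 1]
        return g

    def bounds(self, spacing: float, rail_limit: float = np.inf):
        if self.b.mode == "pinned":
            return None
        lo = np.full(self.size, -np.inf)
        hi = np.full(self.size, np.inf)
        lo[3 * self.n_interior] = 0.15 * spacing
        lo[3 * self.n_interior + 1] = 0.15 * spacing
        if self.b.free_caudal_y:
            lo[-1] = -rail_limit
            hi[-1] = rail_limit
        return list(zip(lo, hi))


# ---------------------------------------------------------------------------
# fused energy + gradient (the solver's hot path)


def _energy_and_grad_nodes(x: np.ndarray, rest: np.ndarray, config: SimulationConfig,
                           clamp_frames: Optional[np.ndarray], prev_twist: float,
                           twist_active: bool, penalty_stiffness: float,
                           self_contact_active: bool):
    """Total energy and its gradient w.r.t. all node positions.

    Returns (energy, grad (m,3), total_twist).  Clamped coordinates are not
    masked here; the DOF map applies the mask by chain rule.
    """
    from .contact import contact_energy_and_grad

    rod = config.rod
    e = np.diff(x, axis=0)
    l = np.linalg.norm(e, axis=1)
    if np.any(l == 0.0):
        raise DegenerateGeometryError("duplicate consecutive nodes")
    grad = np.zeros_like(x)

    # stretch
    coef = rod.stretch_stiffness * (l - rest) / rest
    energy = float(0.5 * np.sum(coef * (l - rest)))
    ge = (coef / l)[:, None] * e
    grad[:-1] -= ge
    grad[1:] += ge

    # bend
    u, v = e[:-1], e[1:]
    lu, lv = l[:-1], l[1:]
    chi = lu * lv + np.einsum("ij,ij->i", u, v)
    if np.any(chi <= 0.0):
        raise DegenerateGeometryError("edge fold-back (180 degree turn)")
    c = np.cross(u, v)
    c2 = np.einsum("ij,ij->i", c, c)
    lbar = 0.5 * (rest[:-1] + rest[1:])
    w = 2.0 * rod.bend_stiffness / lbar
    energy += float(np.sum(w * c2 / chi ** 2))
    A = (2.0 / chi ** 2)[:, None]
    Bc = (2.0 * c2 / chi ** 3)
    gu = w[:, None] * (A * np.cross(v, c) - Bc[:, None] * ((lv / lu)[:, None] * u + v))
    gv = w[:, None] * (A * np.cross(c, u) - Bc[:, None] * ((lu / lv)[:, None] * v + u))
    grad[:-2] -= gu
    grad[1:-1] += gu - gv
    grad[2:] += gv

    # twist (quasistatic material frame between clamp directors)
    theta = prev_twist
    if twist_active and clamp_frames is not None:
        theta = total_twist(x, clamp_frames, prev=prev_twist)
        L = float(np.sum(rest))
        energy += 0.5 * rod.twist_stiffness * theta * theta / L
        # d(theta)/dx = -d(holonomy)/dx; holonomy gradient via curvature binormals
        kb = 2.0 * c / chi[:, None]
        coef_t = rod.twist_stiffness * theta / L
        hu = kb / (2.0 * lu)[:, None]
        hv = kb / (2.0 * lv)[:, None]
        grad[:-2] += coef_t * (-hu)
        grad[1:-1] += coef_t * (hu - hv)
        grad[2:] += coef_t * hv

    # gravity
    if config.gravity_enabled and rod.weight_per_length != 0.0:
        node_l = np.concatenate([[0.5 * rest[0]],
                                 0.5 * (rest[:-1] + rest[1:]),
                                 [0.5 * rest[-1]]])
        energy += float(rod.weight_per_length * np.sum(node_l * x[:, 2]))
        grad[:, 2] += rod.weight_per_length * node_l

    # contact (dome + floor + self)
    e_c = contact_energy_and_grad(x, e, l, config, grad,
                                  penalty_stiffness=penalty_stiffness,
                                  self_contact=self_contact_active)
    energy += e_c
    return energy, grad, theta


def _twist_is_active(config: SimulationConfig, boundary: BoundarySpec) -> bool:
    return boundary.mode == "clamped" and config.rod.twist_stiffness > 0.0


def total_energy(state: RodState, config: SimulationConfig,
                 boundary: Optional[BoundarySpec] = None) -> float:
    boundary = boundary or BoundarySpec.from_config(config)
    en, _, _ = _energy_and_grad_nodes(
        state.nodes, state.centerline.rest_lengths, config,
        state.clamp_frames, state.twist_total,
        _twist_is_active(config, boundary),
        config.contact_penalty_stiffness,
        self_contact_active=_self_contact_on(state, config),
    )
    return en


def total_gradient(state: RodState, config: SimulationConfig,
                   boundary: Optional[BoundarySpec] = None) -> np.ndarray:
    """Gradient of the total energy over the free coordinates.

    Clamped coordinates are eliminated (not merely zeroed): the returned
    vector matches the DOF packing of the boundary spec — interior node
    coordinates, then the two sliding clamp-edge lengths, then the caudal
    lateral shift when that boundary mode is active.
    """
    boundary = boundary or BoundarySpec.from_config(config)
    dmap = _DofMap(boundary, state.centerline.n_nodes)
    _, grad, _ = _energy_and_grad_nodes(
        state.nodes, state.centerline.rest_lengths, config,
        state.clamp_frames, state.twist_total,
        _twist_is_active(config, boundary),
        config.contact_penalty_stiffness,
        self_contact_active=_self_contact_on(state, config),
    )
    return dmap.chain(grad)


def _self_contact_on(state: RodState, config: SimulationConfig) -> bool:
    return state.fed_length >= config.self_contact_onset_length


# ---------------------------------------------------------------------------
# solver


def minimize_equilibrium(state: RodState, config: SimulationConfig,
                         boundary: Optional[BoundarySpec] = None,
                         raise_on_failure: bool = True) -> RodState:
    """Relax the rod to a quasi-static equilibrium under the clamp constraints.

    Deterministic L-BFGS-B with the analytic gradient; the contact penalty
    is escalated and the solve repeated if the non-penetration invariant
    (max penetration <= 5% of rod radius) is violated.  Raises
    :class:`SolverFailure` (carrying the best state and diagnostics) if the
    gradient tolerance is not met, unless ``raise_on_failure`` is False, in
    which case the flagged state is returned.
    """
    from .contact import max_penetration

    boundary = boundary or BoundarySpec.from_config(config)
    dmap = _DofMap(boundary, state.centerline.n_nodes)
    rest = state.centerline.rest_lengths
    twist_active = _twist_is_active(config, boundary)
    self_on = _self_contact_on(state, config)
    prev_twist = state.twist_total
    clampf = state.clamp_frames

    penalty = config.contact_penalty_stiffness
    escalations = 0
    x0 = dmap.pack(state)
    while True:
        def fun(dof, _penalty=penalty):
            x = dmap.unpack(dof)
            en, grad, _ = _energy_and_grad_nodes(
                x, rest, config, clampf, prev_twist, twist_active,
                _penalty, self_on)
            return en, dmap.chain(grad)

        total_nit = 0
        for attempt in range(3):
            res = _scipy_minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                bounds=dmap.bounds(config.node_spacing, config.caudal_rail_limit),
                options={"maxiter": config.max_iterations,
                         "maxfun": 10 * config.max_iterations,
                         "ftol": 1e-16, "gtol": config.solver_tolerance,
                         "maxcor": 50},
            )
            total_nit += int(res.nit)
            x0 = res.x
            if res.success or float(np.max(np.abs(res.jac))) <= config.solver_tolerance:
                break
            # restart with fresh curvature memory (helps through snap-through)
        nodes = dmap.unpack(res.x)
        pen = max_penetration(nodes, config) if config.confinement_enabled else 0.0
        if pen > 0.05 * config.rod.radius and escalations < 3:
            penalty *= 10.0
            escalations += 1
            x0 = res.x
            continue
        break

    _, grad_final, theta = _energy_and_grad_nodes(
        nodes, rest, config, clampf, prev_twist, twist_active, penalty, self_on)
    gnorm = float(np.max(np.abs(dmap.chain(grad_final)))) if dmap.size else 0.0
    converged = gnorm <= 10.0 * config.solver_tolerance or res.success
    diag = SolveDiagnostics(
        converged=converged, iterations=total_nit, grad_norm=gnorm,
        energy=float(res.fun), message=str(res.message),
        penalty_escalations=escalations,
    )

    new = state.copy()
    new.centerline.nodes = nodes
    new.caudal_y = float(res.x[-1]) if boundary.free_caudal_y else 0.0
    if clampf is not None:
        new.reference_frames = parallel_transport_frames(nodes, clampf[0])
        new.twist_total = theta
        # distribute the total twist at uniform density over the edges
        s_mid = np.cumsum(rest) - 0.5 * rest
        new.edge_twists = theta * s_mid / float(np.sum(rest))
    new.last_solve = diag
    if not converged and raise_on_failure:
        raise SolverFailure(
            f"equilibrium solve did not converge (|grad|_inf = {gnorm:.3e})",
            new, diag)
    return new
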