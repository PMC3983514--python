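"""Contact of the rod with the rigid dome, the dorsal floor, and itself.

All walls are rigid and frictionless by default (the physical rod was
powder-coated precisely to minimize friction); penetration is penalized
with a one-sided quadratic energy 1/2 k_c max(0, -gap)^2, which is smooth
in the positions.  Nodes inside the angular exemption windows around the
cranial and caudal port axes are free of dome contact — the rod passes
through those openings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CavityGeometry, SimulationConfig, resolved_self_contact_skip

CENTER = np.zeros(3)
SELF_CONTACT_MARGIN = 1.0  # mm: candidate pairs listed within this clearance


@dataclass
class ContactSet:
    """Signed clearances of every node to the dome and floor, plus
    self-contact candidate pairs (edge i, edge j, gap mm)."""

    dome_gaps: np.ndarray
    floor_gaps: np.ndarray
    self_pairs: list[tuple[int, int, float]]


def dome_gap(point: np.ndarray, cavity: CavityGeometry, rod_radius: float) -> float:
    """Clearance of the rod surface to the hemispherical dome (negative = penetration)."""
    return float(cavity.inner_radius - np.linalg.norm(np.asarray(point) - CENTER) - rod_radius)


def floor_gap(point: np.ndarray, rod_radius: float) -> float:
    """Clearance of the rod surface to the dorsal floor plane z = 0."""
    return float(np.asarray(point)[2] - rod_radius)


def _port_exempt_mask(x: np.ndarray, cavity: CavityGeometry,
                      caudal_exit: np.ndarray | None = None) -> np.ndarray:
    """True for nodes inside either port exemption window (by angle from center).

    ``caudal_exit`` overrides the caudal window center: when the caudal
    clamp slides along the left-right rail, the opening (a slot in the
    physical rig) follows the rod's actual exit point.
    """
    r = np.linalg.norm(x, axis=1)
    r = np.where(r == 0.0, 1.0, r)
    cranial_axis = cavity.cranial_port / np.linalg.norm(cavity.cranial_port)
    caudal_ref = cavity.caudal_port if caudal_exit is None else np.asarray(caudal_exit)
    caudal_axis = caudal_ref / np.linalg.norm(caudal_ref)
    cos_win = np.cos(np.radians(cavity.port_window_deg))
    c1 = (x @ cranial_axis) / r
    c2 = (x @ caudal_axis) / r
    return (c1 >= cos_win) | (c2 >= cos_win)


def compute_contact_set(state_or_nodes, config: SimulationConfig,
                        skip: int | None = None) -> ContactSet:
    nodes = getattr(state_or_nodes, "nodes", state_or_nodes)
    nodes = np.asarray(nodes, dtype=float)
    r = config.rod.radius
    cav = config.cavity
    dome = cav.inner_radius - np.linalg.norm(nodes, axis=1) - r
    dome[_port_exempt_mask(nodes, cav)] = np.inf
    floor = nodes[:, 2] - r
    e = np.diff(nodes, axis=0)
    pairs = _self_pairs(nodes, e, np.linalg.norm(e, axis=1), r,
                        skip if skip is not None else resolved_self_contact_skip(config))
    return ContactSet(dome_gaps=dome, floor_gaps=floor,
                      self_pairs=[(int(i), int(j), float(g)) for i, j, g, *_ in pairs])


def contact_energy(contacts: ContactSet, penalty_stiffness: float) -> float:
    """Sum of one-sided quadratic penalties over all dome/floor/self entries."""
    en = 0.0
    for gaps in (contacts.dome_gaps, contacts.floor_gaps):
        g = np.asarray(gaps, dtype=float)
        g = g[np.isfinite(g)]
        pen = np.minimum(g, 0.0)
        en += 0.5 * penalty_stiffness * float(np.sum(pen ** 2))
    for _, _, gap in contacts.self_pairs:
        if gap < 0.0:
            en += 0.5 * penalty_stiffness * gap * gap
    return en


def self_contact_pairs(state_or_nodes, rod_radius: float, skip: int = 3,
                       margin: float = SELF_CONTACT_MARGIN) -> list[tuple[int, int, float]]:
    """Non-adjacent edge pairs whose surface clearance is below ``margin``.

    Complete: every pair with segment-segment distance < 2 r + margin is
    listed, with gap = distance - 2 r.
    """
    nodes = getattr(state_or_nodes, "nodes", state_or_nodes)
    nodes = np.asarray(nodes, dtype=float)
    e = np.diff(nodes, axis=0)
    out = _self_pairs(nodes, e, np.linalg.norm(e, axis=1), rod_radius, skip, margin)
    return [(int(i), int(j), float(g)) for i, j, g, *_ in out]


def _segment_pair_distance(p1, d1, p2, d2):
    """Vectorized closest distance between segments p1+s*d1, p2+u*d2, s,u in [0,1].

    Returns (dist, s, u).  Standard clamped quadratic minimization with the
    degenerate (near-parallel) branch handled by a two-stage clamp.
    """
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > 1e-12 * a * e + 1e-300,
                 np.clip((b * f - c * e) / np.where(denom == 0.0, 1.0, denom), 0.0, 1.0),
                 0.0)
    u = (b * s + f) / e
    u_cl = np.clip(u, 0.0, 1.0)
    s = np.where(u != u_cl, np.clip((b * u_cl - c) / a, 0.0, 1.0), s)
    u = u_cl
    diff = p1 + s[:, None] * d1 - p2 - u[:, None] * d2
    return np.linalg.norm(diff, axis=1), s, u


def _self_pairs(nodes, e, lens, rod_radius, skip, margin: float = SELF_CONTACT_MARGIN):
    """All candidate close pairs: arrays (i, j, gap, s, u, nx, ny, nz)."""
    n_edges = e.shape[0]
    if n_edges <= skip:
        return []
    ii, jj = np.triu_indices(n_edges, k=skip)
    mids = nodes[:-1] + 0.5 * e
    # cheap midpoint prune
    cut = 0.5 * (lens[ii] + lens[jj]) + 2.0 * rod_radius + margin
    close = np.einsum("ij,ij->i", mids[ii] - mids[jj], mids[ii] - mids[jj]) < cut ** 2
    ii, jj = ii[close], jj[close]
    if ii.size == 0:
        return []
    d, s, u = _segment_pair_distance(nodes[ii], e[ii], nodes[jj], e[jj])
    hit = d < 2.0 * rod_radius + margin
    ii, jj, d, s, u = ii[hit], jj[hit], d[hit], s[hit], u[hit]
    if ii.size == 0:
        return []
    diff = (nodes[ii] + s[:, None] * e[ii]) - (nodes[jj] + u[:, None] * e[jj])
    safe = np.where(d == 0.0, 1.0, d)
    nvec = diff / safe[:, None]
    return list(zip(ii, jj, d - 2.0 * rod_radius, s, u,
                    nvec[:, 0], nvec[:, 1], nvec[:, 2]))


def contact_energy_and_grad(x: np.ndarray, e: np.ndarray, lens: np.ndarray,
                            config: SimulationConfig, grad: np.ndarray,
                            penalty_stiffness: float,
                            self_contact: bool) -> float:
    """Accumulate contact energy and its node-gradient into ``grad``.

    Floor contact is always active (the dorsal stage is present in every
    experiment); dome contact only when confinement is enabled; rod-rod
    contact only once the loop is long enough to coil onto itself.
    """
    k = penalty_stiffness
    r = config.rod.radius
    cav = config.cavity
    energy = 0.0

    if config.confinement_enabled:
        dist = np.linalg.norm(x, axis=1)
        pen = dist + r - cav.inner_radius
        caudal_exit = x[-1] if config.caudal_boundary == "free_lateral" else None
        active = (pen > 0.0) & ~_port_exempt_mask(x, cav, caudal_exit) & (dist > 0.0)
        if np.any(active):
            p = pen[active]
            energy += 0.5 * k * float(np.sum(p ** 2))
            grad[active] += (k * p / dist[active])[:, None] * x[active]

    if config.floor_enabled:
        pen_f = r - x[:, 2]
        act_f = pen_f > 0.0
        if np.any(act_f):
            p = pen_f[act_f]
            energy += 0.5 * k * float(np.sum(p ** 2))
            grad[act_f, 2] -= k * p

    if self_contact:
        for i, j, gap, s, u, nx, ny, nz in _self_pairs(
                x, e, lens, r, resolved_self_contact_skip(config), margin=0.0):
            if gap >= 0.0:
                continue
            nvec = np.array([nx, ny, nz])
            f = k * (-gap)  # magnitude of d(energy)/d(distance), sign: push apart
            energy += 0.5 * k * gap * gap
            grad[i] += -f * (1.0 - s) * nvec
            grad[i + 1] += -f * s * nvec
            grad[j] += f * (1.0 - u) * nvec
            grad[j + 1] += f * u * nvec
    return energy


def total_contact_energy(state, config: SimulationConfig) -> float:
    """Contact energy of a state under the configuration's wall setup."""
    nodes = state.nodes
    e = np.diff(nodes, axis=0)
    grad = np.zeros_like(nodes)
    from .rod import _self_contact_on
    return contact_energy_and_grad(
        nodes, e, np.linalg.norm(e, axis=1), config, grad,
        penalty_stiffness=config.contact_penalty_stiffness,
        self_contact=_self_contact_on(state, config))


def max_penetration(nodes: np.ndarray, config: SimulationConfig) -> float:
    """Deepest wall or self penetration of the rod surface, mm (0 if clear)."""
    r = config.rod.radius
    cav = config.cavity
    worst = 0.0
    if config.confinement_enabled:
        dist = np.linalg.norm(nodes, axis=1)
        pen = dist + r - cav.inner_radius
        caudal_exit = nodes[-1] if config.caudal_boundary == "free_lateral" else None
        pen[_port_exempt_mask(nodes, cav, caudal_exit)] = 0.0
        worst = max(worst, float(np.max(pen, initial=0.0)))
    if config.floor_enabled:
        worst = max(worst, float(np.max(r - nodes[:, 2], initial=0.0)))
    e = np.diff(nodes, axis=0)
    for *_ij, gap, _s, _u, _nx, _ny, _nz in _self_pairs(
            nodes, e, np.linalg.norm(e, axis=1), r, resolved_self_contact_skip(config), margin=0.0):
        worst = max(worst, -gap if gap < 0 else 0.0)
    return worst


def friction_force(contacts: ContactSet, tangential_velocity_proxy: np.ndarray,
                   mu: float, penalty_stiffness: float,
                   regularization: float = 1e-2) -> np.ndarray:
    """Regularized Coulomb resistance at active wall contacts.

    The tangential resistance at each node opposes the supplied slip proxy,
    with magnitude mu |F_n| saturated via v / sqrt(v^2 + eps^2); identically
    zero for mu = 0.  Available for sensitivity studies only — the default
    configuration is frictionless, like the powder-coated rod.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    v = np.asarray(tangential_velocity_proxy, dtype=float)
    out = np.zeros_like(v)
    if mu == 0.0:
        return out
    normal = np.zeros(len(contacts.dome_gaps))
    for gaps in (contacts.dome_gaps, contacts.floor_gaps):
        g = np.asarray(gaps, dtype=float)
        pen = np.where(np.isfinite(g), np.minimum(g, 0.0), 0.0)
        normal += penalty_stiffness * (-pen)
    speed = np.linalg.norm(v, axis=-1, keepdims=True)
    scale = speed / np.sqrt(speed ** 2 + regularization ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(speed > 0.0, v / np.where(speed == 0.0, 1.0, speed), 0.0)
    return -mu * normal[:, None] * scale * direction
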