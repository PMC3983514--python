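"""Planar Euler-elastica oracles, solved by shooting.

Independent of the discrete-rod energy minimizer: these integrate the
classical elastica ODE

    B theta''(s) = Fx sin(theta) - Fz cos(theta)

with a fixed-step RK4 and solve the boundary conditions by root finding.
Used to cross-check the simulator: the pinned-pinned buckled midpoint
deflection, and the fed length at which the planar clamped bow first
touches the hemispherical dome (which brackets the onset of helical
buckling in the confined experiment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .config import SimulationConfig


def _integrate(theta0: float, m0: float, fx: float, fz: float, length: float,
               bend: float = 1.0, n_steps: int = 400) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4 integration of the planar elastica; returns (x, z, theta) arrays."""
    h = length / n_steps
    x = np.empty(n_steps + 1)
    z = np.empty(n_steps + 1)
    th = np.empty(n_steps + 1)
    x[0] = z[0] = 0.0
    th[0] = theta0
    state = np.array([0.0, 0.0, theta0, m0])

    def deriv(s):
        return np.array([math.cos(s[2]), math.sin(s[2]), s[3],
                         (fx * math.sin(s[2]) - fz * math.cos(s[2])) / bend])

    for i in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * h * k1)
        k3 = deriv(state + 0.5 * h * k2)
        k4 = deriv(state + h * k3)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        x[i + 1], z[i + 1], th[i + 1] = state[0], state[1], state[2]
    return x, z, th


# ---------------------------------------------------------------------------
# pinned-pinned buckled column


def pinned_midpoint_deflection(arc_length: float, span: float, bend: float = 1.0) -> float:
    """Midpoint deflection of the first-mode pinned-pinned buckled elastica.

    The rod has arclength ``arc_length`` compressed between frictionless
    pins a distance ``span`` apart (span < arc_length).  Solved from the
    pendulum closed form: theta(s) with theta'(0) = 0 at the end, zero
    moment at the pins, via the amplitude equation — independent of any
    discrete-rod machinery.
    """
    if not span < arc_length:
        raise ValueError("span must be smaller than the arclength")

    L = arc_length

    def span_of_alpha(alpha: float) -> float:
        # first-mode shape: theta(0) = alpha, quarter-wave symmetric;
        # shoot on the load to close the quarter period, then measure span
        k = math.sin(alpha / 2.0)
        from scipy.special import ellipk, ellipe
        K = ellipk(k * k)
        # wavelength condition: sqrt(P/B) * L = 2 K  (one half-wave)
        # span/L = 2 E/K - 1 (standard elastica relation)
        E = ellipe(k * k)
        return L * (2.0 * E / K - 1.0)

    alpha = brentq(lambda a: span_of_alpha(a) - span, 1e-6, math.pi - 1e-3, xtol=1e-12)
    k = math.sin(alpha / 2.0)
    from scipy.special import ellipk
    K = ellipk(k * k)
    p = 2.0 * K / L          # sqrt(P/B)
    # midpoint deflection: w = 2 k / p  (standard first-mode amplitude)
    return 2.0 * k / p


# ---------------------------------------------------------------------------
# clamped planar bow inside the cavity


@dataclass
class PlanarBowSolution:
    arc_length: float
    x: np.ndarray           # cavity coordinates, mm
    z: np.ndarray
    max_center_distance: float   # max over the curve of |p - cavity center|


def clamped_bow(config: SimulationConfig, arc_length: float,
                guess: np.ndarray | None = None,
                n_steps: int = 400) -> tuple[PlanarBowSolution, np.ndarray]:
    """Planar clamped-clamped elastica spanning the ports at given arclength.

    Both end tangents are tilted ventrally by the port axis tilt; the
    unknowns (end moment and internal force components) are shot to meet
    the far-end position and tangent.  Returns the solution and the root
    vector for warm-starting continuation.
    """
    cav = config.cavity
    tilt = math.radians(cav.port_axis_tilt)
    span = 2.0 * cav.inner_radius
    B = config.rod.bend_stiffness

    def residual(p):
        m0, fx, fz = p
        x, z, th = _integrate(tilt, m0, fx, fz, arc_length, B, n_steps)
        return [x[-1] - span, z[-1], th[-1] + tilt]

    if guess is None:
        guess = np.array([1e-3, -1e-4, 0.0])
    sol = root(residual, guess, method="hybr", tol=1e-12)
    if not sol.success:
        for method, scale in (("lm", 1.0), ("hybr", 1.01), ("hybr", 0.98), ("lm", 1.05)):
            sol = root(residual, np.asarray(guess) * scale, method=method, tol=1e-12)
            if sol.success and np.max(np.abs(residual(sol.x))) < 1e-6:
                break
    if not sol.success:
        raise RuntimeError(f"elastica shooting failed at L={arc_length}: {sol.message}")
    m0, fx, fz = sol.x
    x, z, th = _integrate(tilt, m0, fx, fz, arc_length, B, n_steps)
    # place in cavity coordinates: starts at the cranial port
    xs = x - cav.inner_radius
    zs = z + cav.port_height
    dist = np.sqrt(xs ** 2 + zs ** 2)
    # exclude the port exemption windows, as the contact model does
    cos_win = math.cos(math.radians(cav.port_window_deg))
    safe = np.where(dist == 0.0, 1.0, dist)
    ax_cr = cav.cranial_port / np.linalg.norm(cav.cranial_port)
    ax_cd = cav.caudal_port / np.linalg.norm(cav.caudal_port)
    c1 = (xs * ax_cr[0] + zs * ax_cr[2]) / safe
    c2 = (xs * ax_cd[0] + zs * ax_cd[2]) / safe
    interior = dist.copy()
    interior[(c1 >= cos_win) | (c2 >= cos_win)] = 0.0
    return PlanarBowSolution(arc_length=arc_length, x=xs, z=zs,
                             max_center_distance=float(interior.max())), sol.x


def dome_touch_length(config: SimulationConfig, step: float = 2.0,
                      refine_tol: float = 0.05) -> float:
    """Fed length at which the planar bow first touches the dome.

    Grows the clamped planar elastica from the initial fed length in
    ``step`` increments (warm-starting the shooting) until the rod surface
    reaches the dome (max center distance + rod radius >= inner radius),
    then bisects to ``refine_tol``.  This geometric criterion brackets the
    sinusoidal-to-helical transition: past it, a planar configuration is no
    longer admissible and the rod must coil.
    """
    cav = config.cavity
    limit = cav.inner_radius - config.rod.radius

    # a tilted-end inextensible bow needs arclength strictly above the chord;
    # start the continuation just past the minimum feasible excess
    span = 2.0 * cav.inner_radius
    tilt = math.radians(cav.port_axis_tilt)
    amp = math.tan(tilt) * span / math.pi
    L = max(config.growth.initial_fed_length,
            span + math.pi ** 2 * amp ** 2 / (2.0 * span)) + step
    p_euler = 4.0 * math.pi ** 2 * config.rod.bend_stiffness / span ** 2
    guess = np.array([2.0 * amp * (math.pi / span) ** 2, -p_euler, 0.0])
    sol, guess = clamped_bow(config, L, guess)
    if sol.max_center_distance >= limit:
        return L
    lo, hi = L, None
    guesses = {L: guess}
    while hi is None:
        L += step
        sol, guess = clamped_bow(config, L, guess)
        guesses[L] = guess
        if sol.max_center_distance >= limit:
            hi = L
        else:
            lo = L
        if L > config.growth.final_fed_length + 100.0:
            raise RuntimeError("planar bow never reaches the dome")
    g = guesses[lo]
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        sol, g = clamped_bow(config, mid, g)
        if sol.max_center_distance >= limit:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
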