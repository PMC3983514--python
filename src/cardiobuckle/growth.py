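"""Quasi-static growth loop: feed, perturb, equilibrate, record.

Reproduces the four desk-scale experiments:

1. confined growth (dome + floor, gravity off) through the full buckling
   sequence;
2. unconfined control (dome removed, gravity on) ending in a flagged
   planar "flop" instability;
3. seeded ensembles under midline / laterally offset caudal-end conditions,
   counting D- vs L-loop outcomes (the machine twin of the chirality table);
4. free caudal end: the caudal clamp may slide along the left-right rail,
   and its displacement is recorded alongside the handedness.

Every run starts from a freshly initialized straight state, so there are
no memory effects between runs by construction; all randomness enters
through the perturbation seed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import PerturbationSpec, SimulationConfig, clamp_tangents, validate_config
from .morphometrics import (ChiralityLabel, PhaseLabel, handedness_classify,
                            out_of_sagittal_rms, phase_classify)
from .rod import (BoundarySpec, Centerline, RodState, SolverFailure,
                  minimize_equilibrium, parallel_transport_frames)


class ConfigError(ValueError):
    pass


@dataclass
class Trajectory:
    states: list
    fed_lengths: list
    solver_diagnostics: list
    config_snapshot: SimulationConfig
    seed: int
    truncated: bool = False
    truncation_reason: str = ""
    flop_side: Optional[str] = None          # unconfined runs: "left" | "right"
    caudal_y: list = field(default_factory=list)  # free-caudal runs

    @property
    def final_state(self):
        return self.states[-1]


@dataclass
class ContingencyTable:
    condition: str
    caudal_offset: float
    n_runs: int
    n_d_loop: int          # left-handed helices
    n_l_loop: int          # right-handed helices
    n_indeterminate: int
    seeds: list

    @property
    def d_percent(self) -> float:
        return 100.0 * self.n_d_loop / self.n_runs

    @property
    def l_percent(self) -> float:
        return 100.0 * self.n_l_loop / self.n_runs


def _require_valid(config: SimulationConfig) -> None:
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))


def initialize_straight(config: SimulationConfig) -> RodState:
    """Straight (up to clamp tilt) rod spanning the ports at the initial fed length.

    The clamp tangents are tilted ventrally, so the interior follows a
    shallow sinusoidal bump matching the end slopes; the caudal clamp is
    translated by the configured lateral offset.  Rest lengths sum exactly
    to the initial fed length.
    """
    _require_valid(config)
    boundary = BoundarySpec.from_config(config)
    fed = config.growth.initial_fed_length
    n_edges = max(int(round(fed / config.node_spacing)), 6)
    t_cran, t_caud = clamp_tangents(config)
    a = boundary.cranial_base
    b = boundary.caudal_base
    u = np.linspace(0.0, 1.0, n_edges + 1)
    span = b - a
    # ventral bump whose end slopes match the clamp tilt
    slope = math.tan(math.radians(config.cavity.port_axis_tilt))
    amp = slope * np.linalg.norm(span) / math.pi
    nodes = a[None, :] + u[:, None] * span[None, :]
    nodes[:, 2] += amp * np.sin(math.pi * u)
    # snap the clamp-adjacent nodes onto the clamp rays
    s0 = np.linalg.norm(nodes[1] - nodes[0])
    nodes[1] = a + s0 * t_cran
    s1 = np.linalg.norm(nodes[-1] - nodes[-2])
    nodes[-2] = b - s1 * t_caud
    center = Centerline.from_nodes(nodes, total_rest_length=fed)

    # clamp material directors: +y transported with the tilt (perp to tangent)
    m0 = np.cross([0.0, 0.0, 1.0], t_cran)
    mN = np.cross([0.0, 0.0, 1.0], t_caud)
    clampf = np.array([m0 / np.linalg.norm(m0), mN / np.linalg.norm(mN)])
    frames = parallel_transport_frames(nodes, clampf[0])
    return RodState(
        centerline=center,
        edge_twists=np.zeros(n_edges),
        reference_frames=frames,
        fed_length=fed,
        clamp_frames=clampf,
        twist_total=0.0,
    )


def feed_step(state: RodState, config: SimulationConfig) -> RodState:
    """Add one feed increment of rest length at the cranial clamp.

    The cranial-most edge's rest length grows; when it exceeds 1.5x the
    node spacing a node is inserted on that edge so spacing stays near
    nominal.  The state is not equilibrated here.
    """
    inc = config.growth.feed_increment
    if state.fed_length + inc > config.rod.total_length + 1e-9:
        raise ConfigError("growth exhausted: rod total length exceeded")
    new = state.copy()
    new.centerline.rest_lengths[0] += inc
    new.fed_length = state.fed_length + inc
    while new.centerline.rest_lengths[0] > 1.5 * config.node_spacing:
        rest0 = new.centerline.rest_lengths[0]
        keep = rest0 - config.node_spacing
        frac = keep / rest0
        x0, x1 = new.centerline.nodes[0], new.centerline.nodes[1]
        x_new = x0 + frac * (x1 - x0)
        new.centerline.nodes = np.vstack([x0, x_new, new.centerline.nodes[1:]])
        new.centerline.rest_lengths = np.concatenate(
            [[keep, config.node_spacing], new.centerline.rest_lengths[1:]])
        new.edge_twists = np.concatenate([[new.edge_twists[0]], new.edge_twists])
    if new.clamp_frames is not None:
        new.reference_frames = parallel_transport_frames(
            new.centerline.nodes, new.clamp_frames[0])
    return new


def _sample_by_rest_fraction(nodes: np.ndarray, rest: np.ndarray,
                             u_target: np.ndarray) -> np.ndarray:
    """Sample a polyline at normalized rest-arclength fractions."""
    s = np.concatenate([[0.0], np.cumsum(rest)])
    u = s / s[-1]
    return np.column_stack([np.interp(u_target, u, nodes[:, d]) for d in range(3)])


def _predict_after_feed(state: RodState, config: SimulationConfig,
                        boundary: BoundarySpec,
                        prev: Optional[RodState] = None) -> RodState:
    """Initial guess for the post-feed equilibrium.

    Scales the deviation from the port-to-port baseline by the
    near-inextensible bow relation (amplitude ~ sqrt of excess length) and
    resamples nodes along the scaled curve in proportion to rest length,
    so the fed increment is distributed along the rod instead of jammed in
    the cranial edge.  When the previous equilibrium is supplied, a secant
    continuation term (the shape change over the last feed step, capped at
    two feed increments per node) is added.  Pure predictor: the minimizer
    does the physics, and every operation is linear in the coordinates so
    mirror equivariance is exact.
    """
    nodes = state.nodes
    m = nodes.shape[0]
    frac = np.linspace(0.0, 1.0, m)
    base = nodes[0][None, :] + frac[:, None] * (nodes[-1] - nodes[0])[None, :]
    dev = nodes - base
    chord = float(np.linalg.norm(nodes[-1] - nodes[0]))
    geom = float(np.sum(np.linalg.norm(np.diff(nodes, axis=0), axis=1)))
    inc = config.growth.feed_increment
    excess_old = max(geom - chord, 1e-6)
    scale = math.sqrt((excess_old + inc) / excess_old)
    cur = base + scale * dev
    # resample at arclength fractions matching cumulative rest length
    rest = state.centerline.rest_lengths
    target = np.concatenate([[0.0], np.cumsum(rest)])
    u_target = target / target[-1]
    pts = _sample_by_rest_fraction(cur, rest, u_target)
    if prev is not None:
        # secant continuation in normalized-arclength parametrization
        prev_pts = _sample_by_rest_fraction(
            prev.nodes, prev.centerline.rest_lengths, u_target)
        cur_pts = _sample_by_rest_fraction(nodes, rest, u_target)
        delta = cur_pts - prev_pts
        norms = np.linalg.norm(delta, axis=1, keepdims=True)
        cap = 2.0 * inc
        delta = delta * np.minimum(1.0, cap / np.where(norms == 0.0, 1.0, norms))
        pts = pts + delta
    pts[0] = nodes[0]
    pts[-1] = nodes[-1]
    # keep the clamp-adjacent nodes on the clamp rays
    pts[1] = pts[0] + np.linalg.norm(pts[1] - pts[0]) * boundary.t_cranial
    pts[-2] = pts[-1] - np.linalg.norm(pts[-1] - pts[-2]) * boundary.t_caudal
    new = state.copy()
    new.centerline.nodes = pts
    return new


def inject_perturbation(state: RodState, spec: PerturbationSpec,
                        rng: np.random.Generator, mirror: bool = False) -> RodState:
    """Seeded zero-mean lateral (y) noise on the interior nodes.

    ``mirror`` negates the draws (used by the mirror-equivariance checks
    and properties: a mirrored run must see the mirrored noise stream).
    Zero amplitude is the identity and consumes no randomness.
    """
    if spec.noise_amplitude < 0:
        raise ConfigError("noise_amplitude must be >= 0")
    if spec.noise_amplitude == 0.0:
        return state
    new = state.copy()
    n_interior = new.centerline.n_nodes - 4
    if n_interior <= 0:
        return state
    noise = rng.normal(0.0, spec.noise_amplitude, size=n_interior)
    noise -= noise.mean()
    if mirror:
        noise = -noise
    new.centerline.nodes[2:-2, 1] += noise
    return new


def _planar(phase: PhaseLabel) -> bool:
    return phase in (PhaseLabel.STRAIGHT, PhaseLabel.SINUSOIDAL)


def _grow(config: SimulationConfig, *, unconfined: bool = False,
          mirror_noise: bool = False) -> Trajectory:
    _require_valid(config)
    config = copy.deepcopy(config)
    if unconfined:
        config.confinement_enabled = False
        config.gravity_enabled = True
    boundary = BoundarySpec.from_config(config)
    rng = np.random.default_rng(config.perturbation.seed)
    traj = Trajectory(states=[], fed_lengths=[], solver_diagnostics=[],
                      config_snapshot=config, seed=config.perturbation.seed)

    def record(st: RodState) -> None:
        traj.states.append(st)
        traj.fed_lengths.append(st.fed_length)
        traj.solver_diagnostics.append(st.last_solve)
        if boundary.free_caudal_y:
            traj.caudal_y.append(float(st.nodes[-1, 1] - boundary.caudal_base[1]))

    state = initialize_straight(config)
    try:
        state = minimize_equilibrium(state, config, boundary)
    except SolverFailure as exc:
        traj.truncated = True
        traj.truncation_reason = str(exc)
        record(exc.state)
        return traj
    record(state)
    planar_so_far = True

    prev_eq: Optional[RodState] = None
    while state.fed_length + config.growth.feed_increment <= config.growth.final_fed_length + 1e-9:
        cur_eq = state
        state = feed_step(state, config)
        state = _predict_after_feed(state, config, boundary, prev=prev_eq)
        prev_eq = cur_eq
        if planar_so_far:
            state = inject_perturbation(state, config.perturbation, rng, mirror=mirror_noise)
        try:
            state = minimize_equilibrium(state, config, boundary)
        except SolverFailure as exc:
            traj.truncated = True
            traj.truncation_reason = str(exc)
            record(exc.state)
            return traj
        record(state)
        phase = phase_classify(
            state.nodes, config.cavity,
            straight_frac=config.straight_deflection_frac,
            planar_frac=config.planarity_rms_frac,
            run_min_frac=config.torsion_run_min_frac)
        if planar_so_far and not _planar(phase):
            planar_so_far = False
        if unconfined:
            rms = out_of_sagittal_rms(state.nodes)
            if rms > config.flop_rms_frac * config.cavity.inner_radius:
                mean_y = float(np.mean(state.nodes[:, 1] - np.linspace(
                    state.nodes[0, 1], state.nodes[-1, 1], state.nodes.shape[0])))
                traj.truncated = True
                traj.truncation_reason = "planar instability (flop)"
                traj.flop_side = "left" if mean_y > 0 else "right"
                break
    return traj


def run_growth(config: SimulationConfig, mirror_noise: bool = False) -> Trajectory:
    """One confined quasi-static growth run (Experiment 1/3 conditions)."""
    return _grow(config, mirror_noise=mirror_noise)


def run_unconfined(config: SimulationConfig, mirror_noise: bool = False) -> Trajectory:
    """Growth with the dome removed and gravity on (Experiment 2 control).

    The dorsal stage (floor) remains.  The run terminates, flagged, at the
    first state whose out-of-sagittal RMS exceeds the flop threshold, and
    reports which side the loop flopped to.
    """
    return _grow(config, unconfined=True, mirror_noise=mirror_noise)


def run_free_caudal(config: SimulationConfig, mirror_noise: bool = False) -> Trajectory:
    """Growth with the caudal clamp free to slide along the left-right axis."""
    config = copy.deepcopy(config)
    config.caudal_boundary = "free_lateral"
    return _grow(config, mirror_noise=mirror_noise)


def final_handedness(traj: Trajectory, config: Optional[SimulationConfig] = None
                     ) -> ChiralityLabel:
    config = config or traj.config_snapshot
    if traj.truncated:
        return ChiralityLabel.INDETERMINATE
    return handedness_classify(traj.final_state.nodes,
                               dead_zone=config.writhe_dead_zone)


@dataclass
class CaudalCoupling:
    """Handedness and caudal displacement at helix emergence."""
    chirality: ChiralityLabel
    caudal_y: float
    fed_length: float

    @property
    def consistent(self) -> bool:
        """Leftward (+y) displacement with a D-loop, rightward with an L-loop."""
        if self.chirality is ChiralityLabel.D_LOOP:
            return self.caudal_y > 0
        if self.chirality is ChiralityLabel.L_LOOP:
            return self.caudal_y < 0
        return False


def caudal_coupling(traj: Trajectory, config: Optional[SimulationConfig] = None
                    ) -> Optional[CaudalCoupling]:
    """Displacement-handedness coupling of a free-caudal run.

    The displacement accompanies the emerging helix, so the coupling is
    read at the last recorded state whose handedness is determinate and
    whose caudal end has moved by at least 1 mm — for the default run
    length (stopping shortly after helical onset) that is the settled
    emergence coil.  The snap-through transient just before it can kick
    the end the other way for a few steps, and far beyond onset the
    displaced end can reorganize the coil, which is why free-caudal runs
    are stopped near 200 mm.  Returns None if no state qualifies.
    """
    config = config or traj.config_snapshot
    if not traj.caudal_y:
        return None
    for st, y in zip(reversed(traj.states), reversed(traj.caudal_y)):
        if abs(y) < 1.0:
            continue
        label = handedness_classify(st.nodes, dead_zone=config.writhe_dead_zone)
        if label is not ChiralityLabel.INDETERMINATE:
            return CaudalCoupling(chirality=label, caudal_y=float(y),
                                  fed_length=float(st.fed_length))
    return None


def run_ensemble(config: SimulationConfig, n_runs: int, seed_base: int = 0,
                 mirror_noise: bool = False) -> ContingencyTable:
    """Seeded batch of independent growth runs; counts loop enantiomorphs.

    Run k uses seed ``seed_base + k`` on a fresh straight state.  Failed or
    chirality-ambiguous runs are counted as indeterminate.
    """
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    _require_valid(config)
    seeds = [int(seed_base) + k for k in range(n_runs)]
    n_d = n_l = n_ind = 0
    for seed in seeds:
        cfg = copy.deepcopy(config)
        cfg.perturbation.seed = seed
        traj = run_growth(cfg, mirror_noise=mirror_noise)
        label = final_handedness(traj, cfg)
        if label is ChiralityLabel.D_LOOP:
            n_d += 1
        elif label is ChiralityLabel.L_LOOP:
            n_l += 1
        else:
            n_ind += 1
    off = config.perturbation.caudal_offset
    if off == 0:
        condition = "midline"
    else:
        condition = f"{abs(off):g} mm {'leftward' if off > 0 else 'rightward'}"
    return ContingencyTable(condition=condition, caudal_offset=off,
                            n_runs=n_runs, n_d_loop=n_d, n_l_loop=n_l,
                            n_indeterminate=n_ind, seeds=seeds)
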