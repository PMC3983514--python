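"""Morphometrics: buckling phase, loop handedness, writhe, perversions.

The buckling sequence of the confined growing rod is classified into the
four phases seen in looping morphogenesis — STRAIGHT, SINUSOIDAL (planar
bending), SIMPLE_HELICAL (single-handed coiling after wall contact) and
COMPLEX_HELICAL (a two-handed helix whose limbs of opposite chirality meet
at a perversion).  Handedness is measured by the open-curve writhe (Gauss
double integral): in the right-handed frame with +x cranio-caudal and
+y = embryo-left, a right-handed helix has positive writhe, so

    D-loop (left-handed helix)  <=>  writhe < -dead_zone
    L-loop (right-handed helix) <=>  writhe > +dead_zone

This sign convention lives here and only here; the mirror-antisymmetry
property tests guard it structurally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import CavityGeometry, RodModel, SimulationConfig
from .rod import Centerline, DegenerateGeometryError


class PhaseLabel(enum.Enum):
    STRAIGHT = "STRAIGHT"
    SINUSOIDAL = "SINUSOIDAL"
    SIMPLE_HELICAL = "SIMPLE_HELICAL"
    COMPLEX_HELICAL = "COMPLEX_HELICAL"


class ChiralityLabel(enum.Enum):
    D_LOOP = "D_LOOP"            # left-handed helix
    L_LOOP = "L_LOOP"            # right-handed helix
    INDETERMINATE = "INDETERMINATE"


@dataclass
class TorsionRun:
    sign: int
    start_mm: float
    end_mm: float

    @property
    def length_mm(self) -> float:
        return self.end_mm - self.start_mm


@dataclass
class PerversionInfo:
    position_mm: float
    cranial_handedness: str   # "left" | "right"
    caudal_handedness: str


@dataclass
class LoopMetrics:
    phase: PhaseLabel
    chirality: ChiralityLabel
    writhe: float
    torsion_signs: np.ndarray        # (k, 2): arclength mm, sign in {-1, 0, +1}
    perversion: Optional[PerversionInfo]
    fed_length: float
    length_to_diameter: float
    loop_to_cavity_ratio: float


@dataclass
class TransitionRecord:
    """Fed lengths at the first phase switches along a growth trajectory."""
    helical_onset_mm: Optional[float]    # first SINUSOIDAL -> SIMPLE_HELICAL
    complex_onset_mm: Optional[float]    # first SIMPLE -> COMPLEX_HELICAL
    phases: list


def _as_nodes(obj) -> np.ndarray:
    nodes = getattr(obj, "nodes", obj)
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of nodes")
    return nodes


# ---------------------------------------------------------------------------
# writhe


def writhe(centerline) -> float:
    """Open-curve writhe by the exact discrete Gauss double integral.

    Sums the signed solid-angle contribution of every non-adjacent segment
    pair (the Levitt / Klenin-Langowski closed form).  Antisymmetric under
    mirror reflection; identically zero for planar curves.
    """
    nodes = _as_nodes(centerline)
    if nodes.shape[0] < 4:
        raise ValueError("writhe needs at least 4 nodes")
    seg = np.diff(nodes, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) == 0.0):
        raise DegenerateGeometryError("duplicate consecutive nodes")
    n = seg.shape[0]
    ii, jj = np.triu_indices(n, k=2)
    p1, d1 = nodes[ii], seg[ii]
    p2, d2 = nodes[jj], seg[jj]

    r13 = p2 - p1
    r14 = p2 + d2 - p1
    r23 = p2 - (p1 + d1)
    r24 = p2 + d2 - (p1 + d1)

    def _norm_cross(a, b):
        c = np.cross(a, b)
        nc = np.linalg.norm(c, axis=1, keepdims=True)
        return np.divide(c, nc, out=np.zeros_like(c), where=nc > 1e-300)

    n1 = _norm_cross(r13, r14)
    n2 = _norm_cross(r14, r24)
    n3 = _norm_cross(r24, r23)
    n4 = _norm_cross(r23, r13)

    def _asin_dot(a, b):
        return np.arcsin(np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0))

    omega = _asin_dot(n1, n2) + _asin_dot(n2, n3) + _asin_dot(n3, n4) + _asin_dot(n4, n1)
    sign = np.sign(np.einsum("ij,ij->i", np.cross(d2, d1), r13))
    return float(np.sum(omega * sign) / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# torsion sign profile


def _resample(nodes: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample the polyline at uniform arclength ``step``; returns (points, s)."""
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    k = max(int(np.floor(total / step)) + 1, 5)
    si = np.linspace(0.0, total, k)
    pts = np.column_stack([np.interp(si, s, nodes[:, d]) for d in range(3)])
    return pts, si


def _smoothed_curve(nodes: np.ndarray, window_frac: float,
                    n_fine: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Arclength-uniform resample followed by a box filter of the given
    arclength fraction.  Linear in the coordinates (so exactly equivariant
    under reflections); suppresses node-level jitter before curvature or
    torsion estimates."""
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n_fine)
    pts = np.column_stack([np.interp(si, s, nodes[:, d]) for d in range(3)])
    w = max(int(round(window_frac * n_fine)), 1)
    if w > 1:
        pad = w // 2
        padded = np.pad(pts, ((pad, pad + (w - 1) % 2), (0, 0)), mode="edge")
        kernel = np.ones(w) / w
        pts = np.column_stack([np.convolve(padded[:, d], kernel, mode="valid")
                               for d in range(3)])
        pts = pts[: n_fine]
    return pts, si[: pts.shape[0]]


def torsion_sign_profile(centerline, window_frac: float = 0.05,
                         dead_zone: float = 5e-3) -> np.ndarray:
    """Sign of the discrete torsion along arclength, smoothed over a window.

    The centerline is resampled at an arclength step of ``window_frac`` of
    its total length (which filters node-level jitter), and the normalized
    triple product (t_{i-1} x t_i) . t_{i+1} is evaluated on the resampled
    curve.  Magnitudes below ``dead_zone`` report sign 0.  Returns an
    (k, 2) array of (arclength mm, sign).
    """
    nodes = _as_nodes(centerline)
    if nodes.shape[0] < 5:
        raise ValueError("torsion profile needs at least 5 nodes")
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    total = float(seg.sum())
    smooth, _ = _smoothed_curve(nodes, window_frac)
    pts, si = _resample(smooth, window_frac * total)
    e = np.diff(pts, axis=0)
    le = np.linalg.norm(e, axis=1)
    t = e / np.where(le == 0.0, 1.0, le)[:, None]
    triple = np.einsum("ij,ij->i", np.cross(t[:-2], t[1:-1]), t[2:])
    sign = np.where(np.abs(triple) <= dead_zone, 0, np.sign(triple)).astype(int)
    s_mid = 0.5 * (si[1:-2] + si[2:-1])
    return np.column_stack([s_mid, sign])


def torsion_runs(profile: np.ndarray, total_length: float,
                 min_frac: float = 0.15) -> list[TorsionRun]:
    """Persistent constant-sign runs covering at least ``min_frac`` of arclength.

    Each profile sample represents one smoothing window of arclength, so a
    k-sample run covers k windows; the run interval is widened by half a
    window on each side accordingly.
    """
    s = profile[:, 0]
    sg = profile[:, 1].astype(int)
    half = 0.5 * float(s[1] - s[0]) if len(s) > 1 else 0.0
    runs: list[TorsionRun] = []
    i = 0
    while i < len(sg):
        if sg[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(sg) and sg[j + 1] == sg[i]:
            j += 1
        runs.append(TorsionRun(sign=int(sg[i]),
                               start_mm=float(s[i]) - half,
                               end_mm=float(s[j]) + half))
        i = j + 1
    return [r for r in runs if r.length_mm >= min_frac * total_length]


# ---------------------------------------------------------------------------
# classifiers


def _chord_deflection(nodes: np.ndarray) -> float:
    """Max distance of any node from the end-to-end chord."""
    a, b = nodes[0], nodes[-1]
    axis = b - a
    na = np.linalg.norm(axis)
    if na == 0.0:
        return float(np.max(np.linalg.norm(nodes - a, axis=1)))
    axis = axis / na
    rel = nodes - a
    perp = rel - np.outer(rel @ axis, axis)
    return float(np.max(np.linalg.norm(perp, axis=1)))


def out_of_sagittal_rms(nodes: np.ndarray) -> float:
    """RMS lateral (y) deviation from the straight baseline between the ends.

    The baseline interpolates the end nodes' y linearly along the chord, so
    a caudal offset does not by itself count as non-planarity.
    """
    frac = np.linspace(0.0, 1.0, nodes.shape[0])
    base = nodes[0, 1] + frac * (nodes[-1, 1] - nodes[0, 1])
    return float(np.sqrt(np.mean((nodes[:, 1] - base) ** 2)))


def port_axis_winding(state_or_centerline, axis_height: float = 11.5,
                      smooth_frac: float = 0.05) -> tuple[float, float]:
    """Winding of the curve about the cranio-caudal port-to-port line.

    Returns (net, max_excursion) winding angles in degrees, measured on
    the smoothed curve with near-axis points discarded.  A bent-but-planar
    configuration lies in a plane containing the port axis, so both values
    stay near zero; a coiling configuration accumulates tens of degrees.
    """
    nodes = _as_nodes(state_or_centerline)
    smooth, _ = _smoothed_curve(nodes, smooth_frac)
    n = smooth.shape[0]
    trim = max(n // 10, 1)          # port regions sit on the port axis
    yz = smooth[:, 1:]
    interior = yz[trim: n - trim]
    # candidate axes: the port line, and the coil centroid (the right axis
    # for idealized helices not anchored at the ports); keep the one the
    # curve stays farthest from, i.e. the better-conditioned angle origin
    candidates = [np.array([0.0, axis_height]), interior.mean(axis=0)]
    scores = [np.min(np.linalg.norm(interior - c, axis=1)) for c in candidates]
    axis = candidates[int(np.argmax(scores))]
    rel = yz - axis
    rho = np.linalg.norm(rel, axis=1)
    keep = rho > 2.0
    if np.count_nonzero(keep) < 3:
        return 0.0, 0.0
    phi = np.unwrap(np.arctan2(rel[keep, 1], rel[keep, 0]))
    dev = np.degrees(phi - phi[0])
    return float(dev[-1]), float(np.max(np.abs(dev)))


def phase_classify(state_or_centerline, cavity: CavityGeometry,
                   straight_frac: float = 0.05, planar_frac: float = 0.05,
                   run_min_frac: float = 0.15, window_frac: float = 0.05,
                   torsion_dead_zone: float = 5e-3,
                   winding_min_deg: float = 20.0) -> PhaseLabel:
    """Classify a configuration into the four buckling phases.

    STRAIGHT: every node within ``straight_frac`` of the cavity radius from
    the end-to-end chord.  SINUSOIDAL: bent but with out-of-sagittal RMS
    below ``planar_frac`` of the cavity radius, or bent out of the sagittal
    plane without actually coiling (a leaning planar loop neither winds
    about the cranio-caudal axis nor holds a persistent torsion sign).
    SIMPLE_HELICAL: persistent single-signed torsion plus net winding of at
    least ``winding_min_deg`` about the port axis.  COMPLEX_HELICAL:
    persistent torsion runs of both signs (a perversion) with a winding
    excursion of at least ``winding_min_deg``.
    """
    nodes = _as_nodes(state_or_centerline)
    R = cavity.inner_radius
    if _chord_deflection(nodes) < straight_frac * R:
        return PhaseLabel.STRAIGHT
    if out_of_sagittal_rms(nodes) < planar_frac * R:
        return PhaseLabel.SINUSOIDAL
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    total = float(seg.sum())
    profile = torsion_sign_profile(nodes, window_frac, torsion_dead_zone)
    runs = torsion_runs(profile, total, run_min_frac)
    signs = {r.sign for r in runs}
    net, excursion = port_axis_winding(nodes, axis_height=cavity.port_height,
                                       smooth_frac=window_frac)
    if 1 in signs and -1 in signs and excursion >= winding_min_deg:
        return PhaseLabel.COMPLEX_HELICAL
    if signs and abs(net) >= winding_min_deg:
        return PhaseLabel.SIMPLE_HELICAL
    return PhaseLabel.SINUSOIDAL


def handedness_classify(state_or_centerline, dead_zone: float = 0.05,
                        smooth_frac: float = 0.05) -> ChiralityLabel:
    """Map net writhe to the loop enantiomorph (D = left-handed = negative).

    The writhe is evaluated on a lightly smoothed resampling of the
    centerline (box window of ``smooth_frac`` of arclength) so node-level
    jitter does not masquerade as coiling; smoothing is linear, hence the
    mirror antisymmetry of the label is exact.
    """
    nodes = _as_nodes(state_or_centerline)
    smooth, _ = _smoothed_curve(nodes, smooth_frac)
    w = writhe(smooth[::4])
    if w < -dead_zone:
        return ChiralityLabel.D_LOOP
    if w > dead_zone:
        return ChiralityLabel.L_LOOP
    return ChiralityLabel.INDETERMINATE


def perversion_locate(state_or_centerline, cavity: Optional[CavityGeometry] = None,
                      run_min_frac: float = 0.15, window_frac: float = 0.05,
                      torsion_dead_zone: float = 5e-3) -> Optional[PerversionInfo]:
    """Arclength of the junction between opposite-handed helical limbs.

    Returns None unless persistent torsion runs of both signs exist.  The
    junction is the midpoint between the end of the first and the start of
    the last persistent run; positive torsion marks right-handed winding.
    """
    nodes = _as_nodes(state_or_centerline)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    total = float(seg.sum())
    profile = torsion_sign_profile(nodes, window_frac, torsion_dead_zone)
    runs = torsion_runs(profile, total, run_min_frac)
    pos = [r for r in runs if r.sign > 0]
    neg = [r for r in runs if r.sign < 0]
    if not pos or not neg:
        return None
    first = min(runs, key=lambda r: r.start_mm)
    last = max(runs, key=lambda r: r.end_mm)
    if first.sign == last.sign:
        # pick the dominant opposite pair by length
        first = max(pos, key=lambda r: r.length_mm)
        last = max(neg, key=lambda r: r.length_mm)
        if first.start_mm > last.start_mm:
            first, last = last, first
    junction = 0.5 * (first.end_mm + last.start_mm)
    hand = {1: "right", -1: "left"}
    return PerversionInfo(
        position_mm=float(junction),
        cranial_handedness=hand[first.sign],
        caudal_handedness=hand[last.sign],
    )


def loop_ratios(fed_length: float, cavity: CavityGeometry, rod: RodModel
                ) -> tuple[float, float]:
    """(length-to-diameter, loop-to-cavity) ratios of the intra-cavity rod."""
    if fed_length <= 0:
        raise ValueError("fed_length must be > 0")
    return fed_length / (2.0 * rod.radius), fed_length / (2.0 * cavity.inner_radius)


def compute_metrics(state, config: SimulationConfig) -> LoopMetrics:
    """All morphometrics of one equilibrated state under a configuration."""
    cav = config.cavity
    nodes = state.nodes
    phase = phase_classify(
        nodes, cav,
        straight_frac=config.straight_deflection_frac,
        planar_frac=config.planarity_rms_frac,
        run_min_frac=config.torsion_run_min_frac)
    w = writhe(nodes)
    chir = handedness_classify(nodes, dead_zone=config.writhe_dead_zone)
    perv = None
    if phase is PhaseLabel.COMPLEX_HELICAL:
        perv = perversion_locate(nodes, run_min_frac=config.torsion_run_min_frac)
    ld, lc = loop_ratios(state.fed_length, cav, config.rod)
    return LoopMetrics(
        phase=phase, chirality=chir, writhe=w,
        torsion_signs=torsion_sign_profile(nodes),
        perversion=perv, fed_length=state.fed_length,
        length_to_diameter=ld, loop_to_cavity_ratio=lc)


_PHASE_ORDER = {PhaseLabel.STRAIGHT: 0, PhaseLabel.SINUSOIDAL: 1,
                PhaseLabel.SIMPLE_HELICAL: 2, PhaseLabel.COMPLEX_HELICAL: 3}


def _median_filter_phases(phases: list) -> list:
    """Width-3 median on the phase order, removing single-state flickers."""
    if len(phases) < 3:
        return list(phases)
    order = [_PHASE_ORDER[p] for p in phases]
    inv = {v: k for k, v in _PHASE_ORDER.items()}
    out = [phases[0]]
    for i in range(1, len(order) - 1):
        out.append(inv[sorted(order[i - 1: i + 2])[1]])
    out.append(phases[-1])
    return out


def onset_lengths(trajectory, config: Optional[SimulationConfig] = None) -> TransitionRecord:
    """Fed lengths of the sinusoidal->helical and helical->complex switches.

    Labels are median-filtered (width 3) so single-state flickers do not
    register.  The helical onset is the first state labeled (simple or
    complex) helical.  The complex onset is the start of the *terminal*
    contiguous complex block: the snap through the planar-to-spatial
    bifurcation can pass transiently through two-handed shapes, and the
    sustained two-handed configuration is the one the transition lengths
    describe.  Either onset is None if never reached.
    """
    config = config or trajectory.config_snapshot
    phases = []
    for st in trajectory.states:
        phases.append(phase_classify(
            st.nodes, config.cavity,
            straight_frac=config.straight_deflection_frac,
            planar_frac=config.planarity_rms_frac,
            run_min_frac=config.torsion_run_min_frac))
    smoothed = _median_filter_phases(phases)
    fed = [float(f) for f in trajectory.fed_lengths]
    helical = None
    for f, ph in zip(fed, smoothed):
        if ph in (PhaseLabel.SIMPLE_HELICAL, PhaseLabel.COMPLEX_HELICAL):
            helical = f
            break
    complex_ = None
    if smoothed and smoothed[-1] is PhaseLabel.COMPLEX_HELICAL:
        k = len(smoothed) - 1
        while k > 0 and smoothed[k - 1] is PhaseLabel.COMPLEX_HELICAL:
            k -= 1
        complex_ = fed[k]
    return TransitionRecord(helical_onset_mm=helical, complex_onset_mm=complex_,
                            phases=phases)
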