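"""Morphometric classifiers against analytic fixtures and quadrature oracles."""

import numpy as np
import pytest

import cardiobuckle as cb
from cardiobuckle.fixtures import FixtureSpec, generate_fixture
from cardiobuckle.morphometrics import (ChiralityLabel, PhaseLabel,
                                        perversion_locate, torsion_sign_profile,
                                        writhe)


def gauss_writhe_quadrature(curve, n=800):
    """Independent dense-quadrature writhe of a smooth parametric curve.

    Direct Riemann evaluation of the Gauss double integral
    (1/4pi) * int int (t x t') . (r - r') / |r - r'|^3 ds ds'
    on a fine uniform grid, Richardson-extrapolated in the grid spacing
    (the excluded diagonal strip gives a first-order error) — no shared
    code with the production path.
    """
    def riemann(m):
        t = np.linspace(0.0, 1.0, m)
        pts = curve(t)
        d = np.gradient(pts, t, axis=0)
        r = pts[:, None, :] - pts[None, :, :]
        dist = np.linalg.norm(r, axis=2)
        cross = np.cross(d[:, None, :], d[None, :, :])
        num = np.einsum("ijk,ijk->ij", cross, r)
        mask = dist > 1e-9
        integrand = np.where(mask, num / np.where(mask, dist, 1.0) ** 3, 0.0)
        h = t[1] - t[0]
        return integrand.sum() * h * h / (4.0 * np.pi)

    coarse, fine = riemann(n), riemann(2 * n)
    return 2.0 * fine - coarse


def helix_curve(a, pitch, turns, right=True):
    def f(t):
        ang = 2 * np.pi * turns * t
        c = pitch / (2 * np.pi)
        s = 1.0 if right else -1.0
        return np.column_stack([c * ang, a * np.cos(ang), s * a * np.sin(ang)])
    return f


class TestWrithe:
    def test_planar_curve_zero(self):
        arc = generate_fixture(FixtureSpec(kind="planar_arc", n_nodes=150))
        assert abs(writhe(arc)) < 1e-8

    def test_matches_quadrature_oracle(self):
        curve = helix_curve(20.0, 40.0, 2.0, right=True)
        nodes = curve(np.linspace(0, 1, 400))
        w = writhe(nodes)
        w_oracle = gauss_writhe_quadrature(curve)
        assert w > 0           # right-handed helix positive in our frame
        assert w == pytest.approx(w_oracle, abs=1e-3)

    def test_convergence_with_node_count(self):
        curve = helix_curve(20.0, 40.0, 2.0)
        w_oracle = gauss_writhe_quadrature(curve)
        errs = [abs(writhe(curve(np.linspace(0, 1, n))) - w_oracle)
                for n in (50, 100, 200)]
        assert errs[2] < errs[0]
        assert errs[2] < 5e-3

    def test_mirror_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        nodes = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 5.0
        mirrored = nodes * np.array([1.0, -1.0, 1.0])
        assert writhe(mirrored) == -writhe(nodes)

    def test_needs_four_nodes(self):
        with pytest.raises(ValueError):
            writhe(np.zeros((3, 3)) + np.arange(3)[:, None])


class TestTorsionProfile:
    def test_single_helix_constant_sign(self):
        h = generate_fixture(FixtureSpec(kind="helix", handedness="right", n_nodes=300))
        prof = torsion_sign_profile(h.nodes)
        inner = prof[2:-2, 1]
        assert np.all(inner == 1)

    def test_planar_arc_all_zero(self):
        arc = generate_fixture(FixtureSpec(kind="planar_arc", n_nodes=200))
        prof = torsion_sign_profile(arc.nodes)
        assert np.all(prof[:, 1] == 0)

    def test_perversion_one_persistent_sign_change(self):
        p = generate_fixture(FixtureSpec(kind="perversion", n_nodes=400))
        prof = torsion_sign_profile(p.nodes)
        nz = prof[prof[:, 1] != 0, 1]
        changes = np.sum(np.diff(nz) != 0)
        assert changes == 1


FIXTURE_CASES = [
    (FixtureSpec(kind="straight", n_nodes=80), PhaseLabel.STRAIGHT, ChiralityLabel.INDETERMINATE),
    (FixtureSpec(kind="planar_arc", n_nodes=150), PhaseLabel.SINUSOIDAL, ChiralityLabel.INDETERMINATE),
    (FixtureSpec(kind="helix", handedness="right", n_nodes=300), PhaseLabel.SIMPLE_HELICAL, ChiralityLabel.L_LOOP),
    (FixtureSpec(kind="helix", handedness="left", n_nodes=300), PhaseLabel.SIMPLE_HELICAL, ChiralityLabel.D_LOOP),
    (FixtureSpec(kind="helix", handedness="right", radius=30.0, pitch=80.0, n_nodes=300), PhaseLabel.SIMPLE_HELICAL, ChiralityLabel.L_LOOP),
    (FixtureSpec(kind="helix", handedness="left", radius=12.0, pitch=25.0, turns=3.0, n_nodes=300), PhaseLabel.SIMPLE_HELICAL, ChiralityLabel.D_LOOP),
    (FixtureSpec(kind="perversion", n_nodes=400), PhaseLabel.COMPLEX_HELICAL, ChiralityLabel.INDETERMINATE),
]


class TestClassifiers:
    @pytest.mark.parametrize("spec, phase, chir", FIXTURE_CASES)
    def test_fixture_suite_clean(self, config, spec, phase, chir):
        c = generate_fixture(spec)
        assert cb.phase_classify(c.nodes, config.cavity) is phase
        assert cb.handedness_classify(c.nodes) is chir

    @pytest.mark.parametrize("spec, phase, chir", FIXTURE_CASES)
    @pytest.mark.parametrize("seed", [1, 2])
    def test_fixture_suite_with_jitter(self, config, spec, phase, chir, seed):
        """Labels survive node jitter up to 1% of the cavity radius."""
        import dataclasses
        jspec = dataclasses.replace(spec, jitter=0.01 * config.cavity.inner_radius,
                                    seed=seed)
        c = generate_fixture(jspec)
        assert cb.phase_classify(c.nodes, config.cavity) is phase
        assert cb.handedness_classify(c.nodes) is chir

    def test_mirror_swaps_handedness_preserves_phase(self, config):
        for spec, phase, chir in FIXTURE_CASES:
            nodes = generate_fixture(spec).nodes
            mirrored = nodes * np.array([1.0, -1.0, 1.0])
            assert cb.phase_classify(mirrored, config.cavity) is phase
            got = cb.handedness_classify(mirrored)
            swap = {ChiralityLabel.D_LOOP: ChiralityLabel.L_LOOP,
                    ChiralityLabel.L_LOOP: ChiralityLabel.D_LOOP,
                    ChiralityLabel.INDETERMINATE: ChiralityLabel.INDETERMINATE}
            assert got is swap[chir]


class TestPerversion:
    def test_single_helix_has_none(self):
        h = generate_fixture(FixtureSpec(kind="helix", n_nodes=300))
        assert perversion_locate(h.nodes) is None

    def test_symmetric_junction_at_midlength(self):
        p = generate_fixture(FixtureSpec(kind="perversion", n_nodes=400))
        seg = np.linalg.norm(np.diff(p.nodes, axis=0), axis=1)
        total = seg.sum()
        info = perversion_locate(p.nodes)
        assert info is not None
        # within one smoothing window (5% of arclength) of the middle
        assert info.position_mm == pytest.approx(total / 2, abs=0.05 * total)

    def test_limbs_have_opposite_handedness(self):
        p = generate_fixture(FixtureSpec(kind="perversion", handedness="left", n_nodes=400))
        info = perversion_locate(p.nodes)
        assert {info.cranial_handedness, info.caudal_handedness} == {"left", "right"}
        assert info.caudal_handedness == "left"


class TestWritheProperties:
    """Invariances of the Gauss-integral writhe on arbitrary polylines."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mirror_antisymmetry_and_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        nodes = np.cumsum(rng.normal(scale=5.0, size=(25, 3)), axis=0)
        w = writhe(nodes)
        # exact antisymmetry under reflection
        assert writhe(nodes * np.array([1.0, -1.0, 1.0])) == -w
        # invariance under translation and rotation (to round-off)
        shifted = nodes + np.array([10.0, -40.0, 7.0])
        assert writhe(shifted) == pytest.approx(w, abs=1e-9)
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                        [np.sin(ang), np.cos(ang), 0.0],
                        [0.0, 0.0, 1.0]])
        assert writhe(nodes @ rot.T) == pytest.approx(w, abs=1e-8)


class TestRatios:
    def test_printed_apparatus_values(self, config):
        ld, lc = cb.loop_ratios(136.0, config.cavity, config.rod)
        assert ld == pytest.approx(5.91, abs=0.005)
        assert lc == pytest.approx(1.00, abs=0.005)

    def test_final_loop_to_cavity(self, config):
        _, lc = cb.loop_ratios(350.0, config.cavity, config.rod)
        assert lc == pytest.approx(2.57, abs=0.005)

    def test_complex_onset_ratio(self, config):
        ld, _ = cb.loop_ratios(327.0, config.cavity, config.rod)
        assert ld == pytest.approx(14.22, abs=0.005)

    def test_rejects_nonpositive(self, config):
        with pytest.raises(ValueError):
            cb.loop_ratios(0.0, config.cavity, config.rod)
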