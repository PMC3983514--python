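"""Rod energetics: closed forms, gradient consistency, solver contracts."""

import numpy as np
import pytest

import cardiobuckle as cb
from cardiobuckle.rod import (BoundarySpec, Centerline, RodState, _DofMap,
                              _energy_and_grad_nodes, frame_deviation,
                              minimize_equilibrium, parallel_transport_frames,
                              total_twist)


class StiffRod:
    stretch_stiffness = 100.0
    bend_stiffness = 1.0
    twist_stiffness = 1.0


def make_state(nodes, rest=None, clamp_frames=None, twists=None, twist_total=0.0):
    c = (Centerline(np.asarray(nodes, float), np.asarray(rest, float))
         if rest is not None else Centerline.from_nodes(np.asarray(nodes, float)))
    n_e = c.n_nodes - 1
    frames = parallel_transport_frames(c.nodes, clamp_frames[0]
                                       if clamp_frames is not None else [0.0, 1.0, 0.0])
    return RodState(centerline=c,
                    edge_twists=np.zeros(n_e) if twists is None else np.asarray(twists),
                    reference_frames=frames, fed_length=float(c.rest_lengths.sum()),
                    clamp_frames=clamp_frames, twist_total=twist_total)


class TestStretchEnergy:
    def test_rest_state_zero(self):
        st = make_state([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        assert cb.stretch_energy(st, StiffRod) == 0.0

    def test_single_edge_closed_form(self):
        # 10 mm edge stretched to 11 mm at k_s = 100: 0.5*100*1/10 = 5
        st = make_state([[0, 0, 0], [11, 0, 0]], rest=[10.0])
        assert cb.stretch_energy(st, StiffRod) == pytest.approx(5.0)

    def test_linear_in_stiffness(self):
        st = make_state([[0, 0, 0], [10.1, 0, 0]], rest=[10.0])
        class Doubled(StiffRod):
            stretch_stiffness = 200.0
        assert cb.stretch_energy(st, Doubled) == pytest.approx(
            2 * cb.stretch_energy(st, StiffRod))

    def test_zero_rest_length_rejected(self):
        st = make_state([[0, 0, 0], [1, 0, 0]], rest=[0.0])
        with pytest.raises(ValueError):
            cb.stretch_energy(st, StiffRod)


class TestBendEnergy:
    def test_straight_zero(self):
        st = make_state([[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]])
        assert cb.bend_energy(st, StiffRod) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("n_nodes, rtol", [(51, 2.5e-2), (201, 6e-3), (801, 1.5e-3)])
    def test_arc_closed_form_converges(self, n_nodes, rtol):
        # arc radius 100, length 100, B = 1 -> E = L / (2 R^2) = 5e-3,
        # approached first-order in node count (the end half-edges carry
        # no discrete curvature)
        th = np.linspace(0.0, 1.0, n_nodes)
        nodes = np.column_stack([100 * np.sin(th), np.zeros(n_nodes),
                                 100 * (1 - np.cos(th))])
        st = make_state(nodes)
        assert cb.bend_energy(st, StiffRod) == pytest.approx(5.0e-3, rel=rtol)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(5)
        nodes = np.cumsum(rng.normal(size=(12, 3)) + [3, 0, 0], axis=0)
        st = make_state(nodes)
        st_m = make_state(nodes * np.array([1.0, -1.0, 1.0]))
        assert cb.bend_energy(st_m, StiffRod) == pytest.approx(
            cb.bend_energy(st, StiffRod), rel=1e-12)


class TestTwistEnergy:
    def test_untwisted_zero(self):
        clampf = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        x = np.column_stack([np.linspace(0, 100, 21), np.zeros(21), np.zeros(21)])
        st = make_state(x, clamp_frames=clampf)
        assert cb.twist_energy(st, StiffRod) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_twist_closed_form(self):
        # end-to-end twist 2*pi on a straight 100 mm rod, C = 1:
        # E = C theta^2 / (2 L) ~ 0.19739
        clampf = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        n = 41
        x = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.zeros(n)])
        rest = np.full(n - 1, 100.0 / (n - 1))
        s_mid = np.cumsum(rest) - 0.5 * rest
        theta = 2 * np.pi
        st = make_state(x, rest=rest, clamp_frames=clampf,
                        twists=theta * s_mid / 100.0, twist_total=theta)
        assert cb.twist_energy(st, StiffRod) == pytest.approx(
            theta ** 2 / 200.0, rel=1e-9)

    def test_negated_twists_same_energy(self):
        clampf = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        n = 21
        x = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.zeros(n)])
        rest = np.full(n - 1, 5.0)
        s_mid = np.cumsum(rest) - 0.5 * rest
        th = 2 * np.pi
        a = make_state(x, rest=rest, clamp_frames=clampf,
                       twists=th * s_mid / 100.0, twist_total=th)
        b = make_state(x, rest=rest, clamp_frames=clampf,
                       twists=-th * s_mid / 100.0, twist_total=-th)
        assert cb.twist_energy(a, StiffRod) == pytest.approx(
            cb.twist_energy(b, StiffRod), rel=1e-12)


class TestFramesAndTwist:
    def test_frames_orthonormal_and_tangent(self):
        rng = np.random.default_rng(7)
        nodes = np.cumsum(rng.normal(size=(30, 3)) + [4, 0, 0], axis=0)
        frames = parallel_transport_frames(nodes, [0.0, 1.0, 0.0])
        e = np.diff(nodes, axis=0)
        t = e / np.linalg.norm(e, axis=1)[:, None]
        assert np.allclose(np.linalg.norm(frames, axis=1), 1.0, atol=1e-12)
        assert np.max(np.abs(np.einsum("ij,ij->i", frames, t))) < 1e-12

    def test_total_twist_unwrap_branch(self):
        clampf = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        n = 21
        x = np.column_stack([np.linspace(0, 100, n), np.zeros(n), np.zeros(n)])
        raw = total_twist(x, clampf, prev=0.0)
        assert raw == pytest.approx(0.0, abs=1e-12)
        # continuation near 2*pi picks the wound branch
        assert total_twist(x, clampf, prev=2 * np.pi) == pytest.approx(2 * np.pi)


class TestTotalGradient:
    def test_matches_finite_differences(self, config):
        config.gravity_enabled = True
        st = cb.initialize_straight(config)
        rng = np.random.default_rng(0)
        b = BoundarySpec.from_config(config)
        dmap = _DofMap(b, st.centerline.n_nodes)
        dof = dmap.pack(st) + rng.normal(0.0, 1.5, dmap.size)
        rest = st.centerline.rest_lengths

        def f(d):
            x = dmap.unpack(d)
            en, g, _ = _energy_and_grad_nodes(
                x, rest, config, st.clamp_frames, 0.0, True,
                config.contact_penalty_stiffness, True)
            return en, dmap.chain(g)

        e0, g0 = f(dof)
        h = 1e-6
        fd = np.empty_like(g0)
        for i in range(dof.size):
            dp, dm = dof.copy(), dof.copy()
            dp[i] += h
            dm[i] -= h
            fd[i] = (f(dp)[0] - f(dm)[0]) / (2 * h)
        rel = np.abs(g0 - fd) / (np.abs(fd) + np.abs(g0) + 1e-7)
        assert rel.max() < 1e-5

    def test_straight_unloaded_rod_at_rest(self, config):
        config.cavity.port_axis_tilt = 0.0
        st = cb.initialize_straight(config)
        g = cb.total_gradient(st, config)
        assert np.max(np.abs(g)) < 1e-9

    def test_gradient_excludes_clamped_coordinates(self, config):
        st = cb.initialize_straight(config)
        g = cb.total_gradient(st, config)
        n_interior = st.centerline.n_nodes - 4
        assert g.shape == (3 * n_interior + 2,)


class TestEnergyBreakdown:
    def test_total_is_sum_of_parts(self, config):
        config.gravity_enabled = True
        st = cb.initialize_straight(config)
        br = cb.energy_breakdown(st, config)
        assert br.total == pytest.approx(
            br.stretch + br.bend + br.twist + br.gravity + br.contact)


class TestMinimizeEquilibrium:
    def test_untilted_straight_rod_unchanged(self, config):
        config.cavity.port_axis_tilt = 0.0
        st = cb.initialize_straight(config)
        eq = minimize_equilibrium(st, config)
        assert np.max(np.abs(eq.nodes - st.nodes)) < 1e-6

    def test_deterministic(self, config):
        st = cb.initialize_straight(config)
        a = minimize_equilibrium(st, config)
        b = minimize_equilibrium(st, config)
        assert np.array_equal(a.nodes, b.nodes)

    def test_energy_does_not_increase(self, config):
        st = cb.initialize_straight(config)
        e0 = cb.rod.total_energy(st, config)
        eq = minimize_equilibrium(st, config)
        assert cb.rod.total_energy(eq, config) <= e0 + 1e-12

    def test_near_inextensible_at_equilibrium(self, config):
        st = cb.initialize_straight(config)
        eq = minimize_equilibrium(st, config)
        rest = eq.centerline.rest_lengths
        strain = np.abs(eq.centerline.edge_lengths() - rest) / rest
        assert strain.max() <= 0.01

    def test_frames_rederivable_after_solve(self, config):
        st = cb.initialize_straight(config)
        eq = minimize_equilibrium(st, config)
        assert frame_deviation(eq) <= 1e-10

    def test_pinned_elastica_matches_shooting_oracle(self):
        """Euler buckling of a pinned-pinned rod vs the elastica closed form."""
        from cardiobuckle.elastica import pinned_midpoint_deflection
        cfg = cb.default_config()
        cfg.confinement_enabled = False
        cfg.floor_enabled = False         # free space: no walls at all
        cfg.rod.twist_stiffness = 1e-12   # no imposed end frames when pinned
        L, span = 150.0, 140.0
        n = 40
        boundary = BoundarySpec(mode="pinned",
                                cranial_base=np.array([0.0, 0.0, 0.0]),
                                caudal_base=np.array([span, 0.0, 0.0]))
        # initial guess: shallow circular bow in the x-z plane
        u = np.linspace(0.0, 1.0, n + 1)
        amp = np.sqrt(4.0 * (L - span) * L) / np.pi
        nodes = np.column_stack([span * u, np.zeros(n + 1),
                                 amp * np.sin(np.pi * u)])
        c = Centerline.from_nodes(nodes, total_rest_length=L)
        st = RodState(centerline=c, edge_twists=np.zeros(n),
                      reference_frames=parallel_transport_frames(nodes, [0, 1, 0]),
                      fed_length=L, clamp_frames=None)
        eq = minimize_equilibrium(st, cfg, boundary=boundary)
        w_sim = np.max(np.abs(eq.nodes[:, 2]))
        w_oracle = pinned_midpoint_deflection(L, span)
        assert w_sim == pytest.approx(w_oracle, rel=0.02)


class TestReflectionEquivariance:
    def test_energies_invariant_and_solution_mirrors(self, config):
        config.perturbation.caudal_offset = 3.0
        st = cb.initialize_straight(config)
        rng = np.random.default_rng(11)
        st.centerline.nodes[2:-2, 1] += rng.normal(0, 1.0, st.centerline.n_nodes - 4)

        cfg_m = cb.default_config()
        cfg_m.perturbation.caudal_offset = -3.0
        st_m = st.copy()
        st_m.centerline.nodes = st.nodes * np.array([1.0, -1.0, 1.0])
        st_m.clamp_frames = st.clamp_frames * np.array([1.0, -1.0, 1.0])
        st_m.reference_frames = parallel_transport_frames(
            st_m.nodes, st_m.clamp_frames[0])

        e = cb.rod.total_energy(st, config)
        e_m = cb.rod.total_energy(st_m, cfg_m)
        assert e_m == e  # bitwise: all reductions are even in mirrored coords

        eq = minimize_equilibrium(st, config)
        eq_m = minimize_equilibrium(st_m, cfg_m)
        assert np.array_equal(eq_m.nodes,
                              eq.nodes * np.array([1.0, -1.0, 1.0]))
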