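"""Boundary-element duct solver: kernels, no-slip, tractions, Lambda."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import lambda_single_level
from torquepuck import channel_hydro as ch

vec = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False), min_size=3, max_size=3
)


class TestFreeSpaceRotlet:
    def test_parallel_displacement_gives_zero(self):
        u = ch.free_space_rotlet_velocity((1, 0, 0), (0, 0, 0), (2, 0, 0), 1.0)
        assert np.allclose(u, 0.0)

    def test_hand_evaluated_kernel(self):
        # torque 8 pi mu x_hat at the origin, field point y_hat: u = x_hat x y_hat = z_hat
        mu = 1.0
        u = ch.free_space_rotlet_velocity(
            (8 * np.pi * mu, 0, 0), (0, 0, 0), (0, 1.0, 0), mu
        )
        assert np.allclose(u, (0, 0, 1.0), atol=1e-14)

    def test_coincident_point_raises(self):
        with pytest.raises(ch.GeometryError):
            ch.free_space_rotlet_velocity((1, 0, 0), (1, 1, 1), (1, 1, 1), 1.0)

    @given(torque=vec, point=vec)
    def test_antisymmetric_and_orthogonal(self, torque, point):
        point = np.asarray(point) + np.array([0.11, 0.23, 0.37])  # avoid origin
        up = ch.free_space_rotlet_velocity(torque, (0, 0, 0), point, 1.0)
        um = ch.free_space_rotlet_velocity(-np.asarray(torque), (0, 0, 0), point, 1.0)
        assert np.allclose(up, -um, atol=1e-12)
        # u = Gamma x r is orthogonal to both the torque and the displacement
        assert abs(np.dot(up, torque)) < 1e-10 * max(np.linalg.norm(torque), 1)
        assert abs(np.dot(up, point)) < 1e-10 * max(np.linalg.norm(point), 1)


class TestGeometry:
    def test_invalid_parameters_raise(self):
        with pytest.raises(ch.GeometryError):
            ch.ChannelGeometry(half_width=-1.0)
        with pytest.raises(ch.GeometryError):
            ch.ChannelGeometry(half_width=1.0, truncation_length=5.0)
        with pytest.raises(ch.GeometryError):
            ch.ChannelGeometry(half_width=1.0, panel_size=0.5)
        with pytest.raises(ch.GeometryError):
            ch.ChannelGeometry(half_width=1.0, truncation_length=10.0, dead_end=9.0)

    def test_source_outside_duct_raises(self, geo_short):
        with pytest.raises(ch.GeometryError):
            ch.solve_channel_flow(
                geo_short, [ch.Rotlet((0, 0, 1.0), (1, 0, 0))]
            )


class TestChannelFlow:
    def test_zero_torque_source_gives_null_solution(self, geo_short):
        sol = ch.solve_channel_flow(geo_short, [ch.Rotlet((0, 0, 0), (0, 0, 0))])
        assert np.allclose(sol.densities, 0.0)
        assert np.allclose(sol.velocity(np.array([[0.5, 0.2, 0.1]])), 0.0)

    def test_noslip_residual_small(self, sol_unit_rotlet):
        assert sol_unit_rotlet.noslip_residual < 1e-3

    def test_superposition_over_sources(self, geo_short):
        r1 = ch.Rotlet((0.5, 0, 0), (1.0, 0, 0))
        r2 = ch.Rotlet((-0.5, 0, 0), (-1.0, 0, 0))
        both = ch.solve_channel_flow(geo_short, [r1, r2])
        s1 = ch.solve_channel_flow(geo_short, [r1])
        s2 = ch.solve_channel_flow(geo_short, [r2])
        assert np.allclose(both.densities, s1.densities + s2.densities, atol=1e-10)

    def test_velocity_matches_fd_oracle(self, sol_unit_rotlet, fd_oracle):
        """Cross-check the confined velocity field against the independent
        staggered-grid Stokes solve at probes ~1 half-width from the source."""
        rel = []
        for node in [(29, 8, 7), (31, 7, 8), (28, 9, 6)]:
            v_fd, pt = fd_oracle.v_node(*node)
            v_bem = sol_unit_rotlet.velocity(pt)[1]
            rel.append(abs(v_bem - v_fd) / abs(v_fd))
        assert max(rel) < 0.15

    def test_axial_screening(self, sol_unit_rotlet):
        """Duct confinement screens the flow: 100-fold decay within 5 W."""
        near = sol_unit_rotlet.velocity(np.array([1.0, 0.3, 0.3]))
        far = sol_unit_rotlet.velocity(np.array([4.8, 0.3, 0.3]))
        assert np.linalg.norm(far) < 0.01 * np.linalg.norm(near)


class TestTraction:
    def test_zero_solution_zero_traction(self, geo_short):
        sol = ch.solve_channel_flow(geo_short, [ch.Rotlet((0, 0, 0), (0, 0, 0))])
        tr = ch.top_wall_traction(sol)
        assert np.allclose(tr.traction, 0.0)

    def test_sign_reversal(self, geo_short, sol_unit_rotlet):
        neg = ch.solve_channel_flow(geo_short, [ch.Rotlet((0, 0, 0), (-1.0, 0, 0))])
        tp = ch.top_wall_traction(sol_unit_rotlet)
        tn = ch.top_wall_traction(neg)
        assert np.allclose(tp.traction, -tn.traction, atol=1e-12)

    def test_window_exceeding_truncation_raises(self, sol_unit_rotlet):
        with pytest.raises(ch.GeometryError):
            ch.top_wall_traction(sol_unit_rotlet, axial_window=(-6.0, 6.0))

    def test_weights_cover_area(self, sol_unit_rotlet):
        tr = ch.top_wall_traction(sol_unit_rotlet, axial_window=(-4.0, 4.0))
        assert np.isclose(tr.weights.sum(), 8.0 * 2.0, rtol=1e-12)

    def test_finite_difference_variant_is_attenuated_but_consistent(
        self, sol_unit_rotlet
    ):
        """The FD traction probes inside the regularization layer; it must
        reproduce the panel-density traction's sign and order of magnitude
        (it attenuates by ~30% at the default step, which is why the panel
        route is the default)."""
        t_panel = ch.top_wall_traction(sol_unit_rotlet, method="panel")
        t_fd = ch.top_wall_traction(sol_unit_rotlet, method="finite_difference")
        f_p = t_panel.total_force()[1]
        f_d = t_fd.total_force()[1]
        assert np.sign(f_p) == np.sign(f_d)
        assert 0.5 < f_d / f_p < 1.0

    def test_torque_zero_at_source_station(self, sol_unit_rotlet):
        tr = ch.top_wall_traction(sol_unit_rotlet)
        tau = ch.puck_torque_from_traction(tr, puck_center=(0.0, 0.0))
        scale = abs(tr.total_force()[1])  # ~ Lambda / W
        assert abs(tau) < 1e-8 * scale

    def test_torque_linear_in_offset(self, geo_short):
        sols = {}
        for x1 in (1.0, 2.0):
            s = ch.solve_channel_flow(geo_short, [ch.Rotlet((x1, 0, 0), (1, 0, 0))])
            tr = ch.top_wall_traction(s)
            sols[x1] = ch.puck_torque_from_traction(tr, puck_center=(0.0, 0.0))
        assert sols[2.0] / sols[1.0] == pytest.approx(2.0, rel=0.02)

    def test_dipole_torque_translation_invariant(self, geo_short):
        taus = []
        for shift in (0.0, 1.0):
            srcs = [
                ch.Rotlet((shift + 0.75, 0, 0), (1, 0, 0)),
                ch.Rotlet((shift - 0.75, 0, 0), (-1, 0, 0)),
            ]
            s = ch.solve_channel_flow(geo_short, srcs)
            tr = ch.top_wall_traction(s)
            taus.append(ch.puck_torque_from_traction(tr, puck_center=(0.0, 0.0)))
        assert taus[1] == pytest.approx(taus[0], rel=0.01)

    def test_dipole_is_force_free_on_top_wall(self, geo_short):
        srcs = [
            ch.Rotlet((0.75, 0, 0), (1, 0, 0)),
            ch.Rotlet((-0.75, 0, 0), (-1, 0, 0)),
        ]
        s = ch.solve_channel_flow(geo_short, srcs)
        tr = ch.top_wall_traction(s)
        net = tr.total_force()
        single = ch.top_wall_traction(
            ch.solve_channel_flow(geo_short, [srcs[0]])
        ).total_force()
        assert np.linalg.norm(net) < 1e-6 * np.linalg.norm(single)

    def test_x_weighted_integral_reproduces_linear_transmission(
        self, geo_short, sol_unit_rotlet
    ):
        """The torque about any center obeys -Lambda (x1 - xC)/W Gamma_M with
        the Lambda read off the same solution's force integral."""
        lam_h = lambda_single_level(sol_unit_rotlet)
        tr = ch.top_wall_traction(sol_unit_rotlet)
        for xc in (-2.0, 1.5):
            tau = ch.puck_torque_from_traction(tr, puck_center=(xc, 0.0))
            assert tau == pytest.approx(-lam_h * (0.0 - xc), rel=1e-6)


class TestLambda:
    def test_positive_with_uncertainty_and_monotone_levels(self, lambda_converged):
        res = lambda_converged
        assert res.value > 0
        assert res.uncertainty > 0
        levels = [res.per_level[h] for h in sorted(res.per_level, reverse=True)]
        assert all(a > b for a, b in zip(levels, levels[1:]))

    def test_requires_two_levels(self):
        geo = ch.ChannelGeometry(half_width=1.0, truncation_length=10.0)
        with pytest.raises(ValueError):
            ch.compute_lambda(geo, refinement_levels=[0.25])

    def test_scale_invariance(self):
        """Lambda is dimensionless: identical at W = 1 um and W = 2 um when
        the mesh is scaled along."""
        lam = {}
        for w in (1.0, 2.0):
            geo = ch.ChannelGeometry(
                half_width=w, truncation_length=10.0 * w, panel_size=0.25 * w
            )
            sol = ch.solve_channel_flow(
                geo, [ch.Rotlet((0, 0, 0), (1.0, 0, 0))]
            )
            lam[w] = lambda_single_level(sol)
        assert lam[2.0] == pytest.approx(lam[1.0], rel=1e-8)

    def test_truncation_insensitivity(self):
        """Axial screening makes the 20 W and 40 W truncations agree to <1%."""
        vals = {}
        for L in (20.0, 40.0):
            geo = ch.ChannelGeometry(
                half_width=1.0, truncation_length=L, panel_size=0.25
            )
            sol = ch.solve_channel_flow(geo, [ch.Rotlet((0, 0, 0), (1.0, 0, 0))])
            vals[L] = lambda_single_level(sol)
        assert vals[40.0] == pytest.approx(vals[20.0], rel=0.01)

    def test_agrees_with_fd_oracle(self, sol_unit_rotlet, fd_oracle):
        lam_bem = lambda_single_level(sol_unit_rotlet)
        lam_fd = fd_oracle.lambda_estimate()
        assert abs(lam_bem - lam_fd) / lam_fd < 0.2


class TestClosedChamber:
    def test_requires_dead_end(self, geo_short):
        with pytest.raises(ch.GeometryError):
            ch.closed_chamber_solution(geo_short, [ch.Rotlet((0, 0, 0), (1, 0, 0))])

    def test_source_beyond_dead_end_raises(self):
        geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25, dead_end=2.0
        )
        with pytest.raises(ch.GeometryError):
            ch.closed_chamber_solution(geo, [ch.Rotlet((3.0, 0, 0), (1, 0, 0))])

    def test_normal_velocity_vanishes_on_dead_end_plane(self):
        geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25,
            dead_end=4.0, viscosity=1.0,
        )
        srcs = [
            ch.Rotlet((3.0, 0, 0), (1.0, 0, 0)),
            ch.Rotlet((1.5, 0, 0), (-1.0, 0, 0)),
        ]
        sol = ch.closed_chamber_solution(geo, srcs)
        assert ch.dead_end_normal_velocity(sol) < 1e-3

    def test_far_sources_recover_open_channel_torque(self):
        """A dipole many half-widths from the dead end transmits the
        open-channel torque: the image contribution is screened out."""
        geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25,
            dead_end=7.0, viscosity=1.0,
        )
        srcs = [
            ch.Rotlet((0.75, 0, 0), (1.0, 0, 0)),
            ch.Rotlet((-0.75, 0, 0), (-1.0, 0, 0)),
        ]
        closed = ch.closed_chamber_solution(geo, srcs)
        tr_c = ch.top_wall_traction(closed, axial_window=(-8.0, 7.0))
        tau_c = ch.puck_torque_from_traction(tr_c, puck_center=(7.5, 0.0))
        open_geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25, viscosity=1.0
        )
        opened = ch.solve_channel_flow(open_geo, srcs)
        tau_o = ch.puck_torque_from_traction(
            ch.top_wall_traction(opened), puck_center=(7.5, 0.0)
        )
        assert tau_c == pytest.approx(tau_o, rel=0.02)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_image_system_vs_explicit_end_wall(self):
        """The mirror-image construction agrees with paneling the end wall."""
        geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25,
            dead_end=4.0, viscosity=1.0,
        )
        srcs = [
            ch.Rotlet((3.25, 0, 0), (1.0, 0, 0)),
            ch.Rotlet((1.75, 0, 0), (-1.0, 0, 0)),
        ]
        taus = {}
        for explicit in (False, True):
            sol = ch.closed_chamber_solution(geo, srcs, explicit_end_wall=explicit)
            tr = ch.top_wall_traction(sol, axial_window=(-8.0, 4.0))
            taus[explicit] = ch.puck_torque_from_traction(tr, puck_center=(4.5, 0.0))
        assert taus[True] == pytest.approx(taus[False], rel=0.2)

    def test_correction_factor_order_unity(self):
        geo = ch.ChannelGeometry(
            half_width=1.0, truncation_length=16.0, panel_size=0.25,
            dead_end=4.0, viscosity=1.0,
        )
        kappa = ch.closed_chamber_correction(
            geo, dipole_length=7.5, body_length=5.0, lam=0.195
        )
        assert 0.5 < kappa < 2.0
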