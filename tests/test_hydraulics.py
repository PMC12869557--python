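"""Channel and porous-media flow: duct series solution, network, Darcy."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from hypothesis import given, strategies as st

from organoflux.materials import WATER, ORGANOID
from organoflux.geometry import ChannelProfile, MembraneSpec, SpheroidDomain
from organoflux.hydraulics import (
    rectangular_duct_flow,
    duct_flow_rate,
    network_flow,
    reynolds_number,
    peclet_number,
    darcy_radial_flow,
)


class TestDuctFlow:
    def test_parallel_plate_limit(self):
        """Width ≫ depth: max velocity tends to h²Δp/(8ηL) ≈ 736 μm/s."""
        h, dp, Lmm = 10.0, 690.0, 11.7
        sol = rectangular_duct_flow(5000.0, h, Lmm, dp, WATER, n_terms=60)
        expected = h**2 * dp / (8.0 * WATER.viscosity * Lmm * 1e3)
        assert expected == pytest.approx(736.0, rel=1e-3)
        assert sol.max_velocity == pytest.approx(expected, rel=2e-3)

    def test_zero_pressure_gives_zero_field(self):
        sol = rectangular_duct_flow(200.0, 10.0, 11.7, 0.0, WATER)
        assert np.all(sol.velocity == 0.0)
        assert sol.flow_rate == 0.0

    def test_no_slip_on_walls(self):
        sol = rectangular_duct_flow(50.0, 10.0, 1.0, 100.0, WATER)
        assert np.allclose(sol.velocity[0, :], 0.0, atol=1e-9 * sol.max_velocity)
        assert np.allclose(sol.velocity[-1, :], 0.0, atol=1e-9 * sol.max_velocity)
        assert np.allclose(sol.velocity[:, 0], 0.0, atol=1e-6 * sol.max_velocity)
        assert np.allclose(sol.velocity[:, -1], 0.0, atol=1e-6 * sol.max_velocity)

    def test_square_duct_matches_fd_poisson_oracle(self):
        """Series solution vs an independent finite-difference Poisson solve."""
        w = h = 10.0
        dp, Lmm = 690.0, 11.7
        n = 161
        d = w / (n - 1)
        one = sp.diags([1.0, -2.0, 1.0], [-1, 0, 1], shape=(n - 2, n - 2))
        lap = (sp.kron(sp.eye(n - 2), one) + sp.kron(one, sp.eye(n - 2))) / d**2
        rhs = -np.full((n - 2) ** 2, dp / (WATER.viscosity * Lmm * 1e3))
        u_fd = spsolve(lap.tocsr(), rhs)
        sol = rectangular_duct_flow(w, h, Lmm, dp, WATER, n_terms=80, n_grid=n)
        assert sol.max_velocity == pytest.approx(u_fd.max(), rel=1e-3)

    def test_symmetric_under_width_depth_exchange(self):
        a = rectangular_duct_flow(30.0, 10.0, 1.0, 50.0, WATER)
        b = rectangular_duct_flow(10.0, 30.0, 1.0, 50.0, WATER)
        assert a.max_velocity == pytest.approx(b.max_velocity, rel=1e-12)
        assert a.flow_rate == pytest.approx(b.flow_rate, rel=1e-12)

    def test_flow_rate_equals_velocity_integral(self):
        sol = rectangular_duct_flow(50.0, 10.0, 1.0, 100.0, WATER, n_grid=201)
        q_int = np.trapezoid(np.trapezoid(sol.velocity, sol.y, axis=1), sol.z)
        assert q_int == pytest.approx(sol.flow_rate, rel=1e-3)

    @given(dp=st.floats(1.0, 5000.0))
    def test_linearity_in_pressure(self, dp):
        base = duct_flow_rate(50.0, 10.0, 1.0, 1.0, WATER)
        assert duct_flow_rate(50.0, 10.0, 1.0, dp, WATER) == pytest.approx(
            dp * base, rel=1e-12
        )

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            rectangular_duct_flow(-1.0, 10.0, 1.0, 100.0, WATER)
        with pytest.raises(ValueError):
            rectangular_duct_flow(10.0, 10.0, 1.0, 100.0, WATER, n_terms=5)


class TestNetworkFlow:
    def test_doubling_pressure_doubles_flow(self):
        p = ChannelProfile()
        q1 = network_flow(p, 690.0, WATER)["flow_rate"]
        q2 = network_flow(p, 1380.0, WATER)["flow_rate"]
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_segment_refinement_converges(self):
        p = ChannelProfile()
        r50 = network_flow(p, 690.0, WATER, n_segments=50)["resistance"]
        r500 = network_flow(p, 690.0, WATER, n_segments=500)["resistance"]
        assert abs(r50 - r500) / r500 < 0.005

    def test_uniform_channel_equals_single_duct(self):
        p = ChannelProfile(inner_width_center=100.0, inner_width_edge=100.0)
        net = network_flow(p, 690.0, WATER, n_segments=50)
        q = duct_flow_rate(100.0, p.depth, p.r_max_mm, 690.0, WATER)
        assert net["flow_rate"] == pytest.approx(q, rel=1e-9)

    def test_taper_reduces_resistance_vs_narrow_uniform(self):
        tapered = network_flow(ChannelProfile(), 690.0, WATER)["resistance"]
        narrow = 1.0 / duct_flow_rate(20.0, 10.0, 11.7, 1.0, WATER)
        assert tapered < narrow


class TestDimensionlessNumbers:
    def test_reynolds_example(self):
        # 200×10 μm duct: D_h = 2wh/(w+h) = 19.05 μm; u = 100 μm/s
        d_h = 2.0 * 200.0 * 10.0 / 210.0
        assert reynolds_number(100.0, d_h, WATER) == pytest.approx(1.90e-3, rel=0.01)

    def test_reynolds_zero_velocity(self):
        assert reynolds_number(0.0, 19.05, WATER) == 0.0

    @given(u=st.floats(0.1, 1e4), scale=st.floats(0.1, 10.0))
    def test_reynolds_linear_in_velocity(self, u, scale):
        assert reynolds_number(u * scale, 19.05, WATER) == pytest.approx(
            scale * reynolds_number(u, 19.05, WATER), rel=1e-12
        )

    def test_peclet_unit_combination(self):
        assert peclet_number(1.0, 100.0, 100.0) == pytest.approx(1.0)

    def test_peclet_membrane_scale(self):
        # ~0.55 μm/s over the back-computed characteristic length vs D_m
        assert peclet_number(0.55, 12.27, 450.0) == pytest.approx(0.015, rel=0.01)

    def test_peclet_halves_when_diffusivity_doubles(self):
        assert peclet_number(1.0, 10.0, 200.0) == pytest.approx(
            peclet_number(1.0, 10.0, 100.0) / 2.0
        )


class TestDarcyRadialFlow:
    def test_zero_pressure_zero_velocity(self):
        field = darcy_radial_flow(
            SpheroidDomain(), ORGANOID, MembraneSpec(), 0.0, WATER
        )
        assert np.all(field.face_velocity == 0.0)

    def test_continuity_r2u_constant_outside_shell(self):
        field = darcy_radial_flow(
            SpheroidDomain(), ORGANOID, MembraneSpec(), 690.0, WATER
        )
        r = field.grid.nodes
        mask = r >= field.source_radius
        flux = r[mask] ** 2 * field.face_velocity[mask]
        assert np.max(np.abs(flux - flux[0])) / flux[0] < 1e-6

    def test_no_flow_inside_source_shell(self):
        field = darcy_radial_flow(
            SpheroidDomain(), ORGANOID, MembraneSpec(), 690.0, WATER
        )
        r = field.grid.nodes
        assert np.all(field.face_velocity[r < field.source_radius - 1e-9] == 0.0)

    def test_linear_in_pressure(self):
        f1 = darcy_radial_flow(SpheroidDomain(), ORGANOID, MembraneSpec(), 100.0, WATER)
        f2 = darcy_radial_flow(SpheroidDomain(), ORGANOID, MembraneSpec(), 300.0, WATER)
        assert f2.flow_rate == pytest.approx(3.0 * f1.flow_rate, rel=1e-12)

    def test_max_velocity_at_source_shell(self):
        field = darcy_radial_flow(
            SpheroidDomain(), ORGANOID, MembraneSpec(), 690.0, WATER
        )
        assert field.max_velocity_radius == pytest.approx(field.source_radius)
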