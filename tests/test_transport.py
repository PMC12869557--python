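"""Transient advection–diffusion solver: analytic benchmarks and invariants."""

import math

import numpy as np
import pytest
from scipy.special import erfc

import organoflux.materials as mats
from organoflux.geometry import (
    PhantomDomain,
    SpheroidDomain,
    Grid1D,
    build_phantom_grid,
    build_spheroid_radial_grid,
    MATERIAL_TISSUE,
)
from organoflux.hydraulics import darcy_radial_flow
from organoflux.geometry import MembraneSpec
from organoflux.transport import (
    TransportConfig,
    phantom_config,
    organoid_config,
    solve_transport,
    solve_phantom,
    solve_organoid_radial,
    solve_agarose_3d_embedding,
    system_operator,
    DEFAULT_PHANTOM_TIMES,
)

C0 = 10.0


def homogeneous_slab_config(dx=10.0, output_times=(500.0, 1000.0, 2000.0), **kw):
    """Agarose-only slab, fixed C0 at x=0, sink at x=L."""
    base = build_phantom_grid(PhantomDomain(), dx=dx)
    grid = Grid1D(
        nodes=base.nodes,
        material=np.full(base.n_cells, MATERIAL_TISSUE),
        geometry="planar",
    )
    return TransportConfig(
        grid=grid,
        materials={MATERIAL_TISSUE: mats.AGAROSE},
        solute=mats.SULFORHODAMINE_B,
        bc_left=("dirichlet", C0),
        bc_right=("dirichlet", 0.0),
        output_times=np.asarray(output_times, dtype=float),
        **kw,
    )


class TestAnalyticBenchmarks:
    def test_half_space_erfc_profile(self):
        """Early-time solution matches c0·erfc(x/(2√(Dt))) within 1% RMS.

        In a homogeneous porous slab the porosity cancels between storage
        and flux, so the apparent diffusivity is the free diffusivity D.
        """
        cfg = homogeneous_slab_config()
        res = solve_transport(cfg)
        D = mats.SULFORHODAMINE_B.diffusivity
        x = cfg.grid.centers
        for k, t in enumerate(res.times):
            exact = C0 * erfc(x / (2.0 * np.sqrt(D * t)))
            rms = np.sqrt(np.mean((res.concentrations[k] - exact) ** 2)) / C0
            assert rms < 0.01

    def test_zero_source_stays_zero(self):
        cfg = phantom_config(source_concentration=0.0)
        res = solve_phantom(cfg)
        assert np.max(np.abs(res.concentrations)) == 0.0

    def test_long_time_linear_steady_profile(self):
        cfg = homogeneous_slab_config(output_times=(0.0, 2e5, 4e5))
        res = solve_transport(cfg)
        x = cfg.grid.centers
        linear = C0 * (1.0 - x / 5000.0)
        assert np.max(np.abs(res.concentrations[-1] - linear)) / C0 < 0.005

    def test_spatial_convergence_order(self):
        """Observed order of accuracy on the erfc benchmark is >= 1.9."""
        errs = {}
        for dx in (40.0, 20.0):
            cfg = homogeneous_slab_config(
                dx=dx, output_times=(1000.0,), dt_cap_frac=0.005
            )
            res = solve_transport(cfg)
            D = mats.SULFORHODAMINE_B.diffusivity
            exact = C0 * erfc(cfg.grid.centers / (2.0 * np.sqrt(D * 1000.0)))
            errs[dx] = np.sqrt(np.mean((res.concentrations[-1] - exact) ** 2))
        order = math.log2(errs[40.0] / errs[20.0])
        assert order >= 1.9

    def test_implicit_matches_small_step_explicit(self):
        """BDF solve agrees with brute-force forward Euler on 50 cells to 1e-6."""
        n, L, T = 50, 500.0, 10.0
        grid = Grid1D(
            nodes=np.linspace(0.0, L, n + 1),
            material=np.full(n, MATERIAL_TISSUE),
            geometry="planar",
        )
        init = 5.0 * np.sin(np.pi * grid.centers / L)
        cfg = TransportConfig(
            grid=grid,
            materials={MATERIAL_TISSUE: mats.AGAROSE},
            solute=mats.SULFORHODAMINE_B,
            bc_left=("dirichlet", 0.0),
            bc_right=("dirichlet", 0.0),
            initial=init,
            output_times=np.array([T]),
            dt_init=0.005,
            dt_growth=1.05,
            dt_cap_frac=0.002,
        )
        res = solve_transport(cfg)
        lo, di, up, b, M = system_operator(cfg, 0.0)
        c = init.copy()
        dt = 2e-4
        for _ in range(int(T / dt)):
            Ac = di * c
            Ac[:-1] += up[:-1] * c[1:]
            Ac[1:] += lo[1:] * c[:-1]
            c += dt * (Ac + b) / M
        assert np.max(np.abs(res.concentrations[-1] - c)) / np.max(np.abs(c)) < 1e-6


class TestConservationAndBounds:
    def test_mass_balance_residual(self, phantom_run):
        """Porosity-weighted mass change equals the net boundary flux integral."""
        assert phantom_run.mass_residual_rel < 1e-8

    def test_discrete_maximum_principle(self, phantom_run):
        c = phantom_run.concentrations
        src = phantom_run.config.bc_left[1]
        assert np.all(c >= -1e-12 * src)
        assert np.all(c <= src * (1.0 + 1e-9))

    def test_delivered_mass_positive_and_growing(self, phantom_run):
        cum = phantom_run.cumulative_delivered
        assert cum[-1] > 0.0
        assert np.all(np.diff(cum) >= -1e-9 * cum[-1])

    def test_interface_flux_series_recorded_densely(self, phantom_run):
        assert phantom_run.step_times.size == phantom_run.interface_flux.size
        assert phantom_run.step_times.size > phantom_run.times.size


class TestSphericalSolver:
    def test_uniform_closed_sphere_is_equilibrium(self):
        grid = build_spheroid_radial_grid(SpheroidDomain())
        cfg = TransportConfig(
            grid=grid,
            materials={MATERIAL_TISSUE: mats.ORGANOID},
            solute=mats.MAGNEVIST,
            bc_left=("neumann", 0.0),
            bc_right=("neumann", 0.0),
            initial=3.0,
            output_times=np.array([0.0, 1e4]),
        )
        res = solve_transport(cfg)
        assert np.max(np.abs(res.concentrations[-1] - 3.0)) < 1e-9

    def test_two_region_steady_profile(self):
        """Shell held at c_m: inner region uniform, outer follows 1/r − 1/R."""
        cfg = organoid_config(output_times=np.array([0.0, 2e5]))
        res = solve_organoid_radial(cfg)
        r = cfg.grid.centers
        r_s = cfg.grid.nodes[cfg.shell[0]]
        R = cfg.grid.nodes[-1]
        c_m = cfg.shell[1]
        exact = np.where(r < r_s, c_m, c_m * (1.0 / r - 1.0 / R) / (1.0 / r_s - 1.0 / R))
        assert np.max(np.abs(res.concentrations[-1] - exact)) / c_m < 0.005

    def test_interior_enriched_over_exterior(self):
        """After 1 h the region inside the source shell holds more solute
        than the sink-facing exterior at equal distance from the shell."""
        cfg = organoid_config(output_times=np.array([0.0, 3600.0]))
        res = solve_organoid_radial(cfg)
        r = cfg.grid.centers
        r_s = cfg.grid.nodes[cfg.shell[0]]
        c = res.concentrations[-1]
        for dist in (100.0, 200.0, 300.0):
            inner = np.interp(r_s - dist, r, c)
            outer = np.interp(r_s + dist, r, c)
            assert inner >= outer

    def test_initial_condition_returned_at_t0(self):
        cfg = organoid_config(output_times=np.array([0.0]))
        res = solve_organoid_radial(cfg)
        assert np.all(res.concentrations[0] == 0.0)
        assert res.delivered_mass == 0.0

    def test_slower_solute_lags(self):
        """At equal early times the Iohexol front trails the Magnevist front."""
        t = 120.0
        slow = solve_agarose_3d_embedding(output_times=(0.0, t))
        fast = solve_agarose_3d_embedding(
            solute=mats.MAGNEVIST, output_times=(0.0, t)
        )
        r = slow.grid.centers
        r_s = slow.grid.nodes[slow.config.shell[0]]
        outside = r > r_s + 20.0
        c_slow = slow.concentrations[-1] / slow.config.shell[1]
        c_fast = fast.concentrations[-1] / fast.config.shell[1]
        assert np.all(c_fast[outside] >= c_slow[outside] - 1e-9)
        assert np.max(c_fast[outside] - c_slow[outside]) > 1e-3

    def test_advection_grid_mismatch_rejected(self):
        dom = SpheroidDomain()
        field = darcy_radial_flow(dom, mats.ORGANOID, MembraneSpec(), 690.0, mats.WATER)
        other = build_spheroid_radial_grid(dom, dr=25.0)
        with pytest.raises(ValueError):
            TransportConfig(
                grid=other,
                materials={MATERIAL_TISSUE: mats.ORGANOID},
                solute=mats.MAGNEVIST,
                advection=field,
                output_times=np.array([10.0]),
            )

    def test_advection_increases_delivery(self):
        """Pressure-driven leakage adds to diffusive delivery into the tissue."""
        t = np.array([0.0, 1800.0])
        field = darcy_radial_flow(
            SpheroidDomain(), mats.ORGANOID, MembraneSpec(), 690.0, mats.WATER
        )
        with_adv = solve_organoid_radial(organoid_config(advection=field, output_times=t))
        without = solve_organoid_radial(organoid_config(output_times=t))
        assert with_adv.delivered_mass > without.delivered_mass


class TestWrapperGuards:
    def test_phantom_requires_planar_grid(self):
        cfg = organoid_config(output_times=np.array([10.0]))
        with pytest.raises(ValueError):
            solve_phantom(cfg)

    def test_organoid_requires_spherical_grid(self):
        cfg = phantom_config()
        with pytest.raises(ValueError):
            solve_organoid_radial(cfg)

    def test_default_output_schedule(self):
        assert DEFAULT_PHANTOM_TIMES.size == 11
        assert DEFAULT_PHANTOM_TIMES[-1] == 400 * 60.0
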