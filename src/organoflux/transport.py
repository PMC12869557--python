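"""Transient advection–diffusion in layered porous media.

This is the core computation of the package: solute transport from the
microchannel, across the time-saturating nanoporous membrane, into an
agarose phantom (1D planar) or a spheroidal organoid (1D spherical).

Governing equation per porous domain (internal units μm, s, μM)::

    ε ∂c/∂t = ∇·(D_eff ∇c − u c),    D_eff = s(t)·ε·D/τ

Porosity enters the storage term; the effective diffusivity enters the
flux; the saturation factor s(t) applies to membrane cells only (all other
domains are fully saturated). The optional advection field ``u`` is the
superficial Darcy velocity.

Discretization
--------------
Cell-centred finite volumes with harmonic-mean interface diffusivities
(flux continuity across material boundaries) and first-order upwinding for
advection (cell Péclet numbers are ≪ 1 here, so the upwind accuracy loss
is negligible while monotonicity is guaranteed). Time integration is a
variable-step BDF scheme (backward Euler start, BDF2 thereafter) with a
geometric step ramp from a small initial step; the step size is capped at
a fraction of elapsed time so the logarithmically decaying transient stays
resolved. Cumulative boundary fluxes are integrated with the *same* BDF
recurrence as the concentrations, which makes the discrete mass balance
exact to round-off at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .materials import (
    PorousMaterial,
    Solute,
    SaturationModel,
    saturation_at,
    effective_diffusivity,
    PETE_MEMBRANE,
    AGAROSE,
    ORGANOID,
    SULFORHODAMINE_B,
    MAGNEVIST,
    IOHEXOL,
    MEMBRANE_SATURATION,
)
from .geometry import (
    Grid1D,
    PhantomDomain,
    SpheroidDomain,
    build_phantom_grid,
    build_spheroid_radial_grid,
    MATERIAL_MEMBRANE,
    MATERIAL_TISSUE,
)
from .hydraulics import DarcyField

__all__ = [
    "TransportConfig",
    "TransportResult",
    "phantom_config",
    "organoid_config",
    "solve_transport",
    "solve_phantom",
    "solve_organoid_radial",
    "solve_agarose_3d_embedding",
    "system_operator",
    "DEFAULT_PHANTOM_TIMES",
]

# Default phantom output schedule: 0–400 min sampled every 40 min.
DEFAULT_PHANTOM_TIMES = np.arange(0.0, 401.0, 40.0) * 60.0


@dataclass
class TransportConfig:
    """Full description of one transport solve."""

    grid: Grid1D
    materials: dict[int, PorousMaterial]
    solute: Solute
    saturation: SaturationModel | None = None
    membrane_index: int = MATERIAL_MEMBRANE
    bc_left: tuple = ("neumann", 0.0)
    bc_right: tuple = ("neumann", 0.0)
    shell: tuple | None = None  # (face index, fixed concentration)
    advection: DarcyField | None = None
    output_times: np.ndarray = field(
        default_factory=lambda: DEFAULT_PHANTOM_TIMES.copy()
    )
    initial: float | np.ndarray = 0.0
    dt_init: float = 0.1
    dt_growth: float = 1.3
    dt_cap_frac: float = 0.02
    dt_max: float = np.inf

    def __post_init__(self) -> None:
        self.output_times = np.sort(np.asarray(self.output_times, dtype=float))
        if self.output_times[0] < 0:
            raise ValueError("output times must be non-negative")
        for bc in (self.bc_left, self.bc_right):
            if bc[0] not in ("dirichlet", "neumann"):
                raise ValueError(f"unknown boundary condition {bc[0]!r}")
        if self.advection is not None and (
            self.advection.grid.n_cells != self.grid.n_cells
            or not np.allclose(self.advection.grid.nodes, self.grid.nodes)
        ):
            raise ValueError("advection field grid does not match transport grid")


@dataclass
class TransportResult:
    """Space–time concentration field with flux bookkeeping.

    ``interface_flux`` is the diffusive flux per unit area (μM·μm/s) on the
    tissue side of the membrane interface (or source face when there is no
    membrane), recorded densely at every accepted time step.
    """

    grid: Grid1D
    times: np.ndarray
    concentrations: np.ndarray  # (n_times, n_cells)
    step_times: np.ndarray
    interface_flux: np.ndarray
    delivered_mass: float
    cumulative_delivered: np.ndarray
    mass_residual: float  # max |mass change − net boundary influx|
    mass_residual_rel: float  # relative to delivered mass
    config: TransportConfig

    def profile(self, t: float) -> np.ndarray:
        """Concentration profile at the output time closest to ``t`` (s)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.concentrations[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time_s, position_um, concentration_uM) table."""
        t = np.repeat(self.times, self.grid.n_cells)
        x = np.tile(self.grid.centers, len(self.times))
        return pd.DataFrame(
            {"time_s": t, "position_um": x, "concentration_uM": self.concentrations.ravel()}
        )


# ---------------------------------------------------------------------------
# assembly


def _cell_coefficients(config: TransportConfig, t: float):
    """Per-cell porosity and effective diffusivity at time ``t``."""
    grid = config.grid
    eps = np.empty(grid.n_cells)
    Deff = np.empty(grid.n_cells)
    for idx, mat in config.materials.items():
        mask = grid.material == idx
        s = 1.0
        if config.saturation is not None and idx == config.membrane_index:
            s = saturation_at(config.saturation, t)
        eps[mask] = mat.porosity
        Deff[mask] = effective_diffusivity(config.solute, mat, s)
    return eps, Deff


def system_operator(config: TransportConfig, t: float):
    """Assemble the semi-discrete system  M dc/dt = A c + b  at time ``t``.

    Returns ``(lower, diag, upper, b, M)`` where the tridiagonal A has
    ``lower[i]`` multiplying c[i-1] and ``upper[i]`` multiplying c[i+1] in
    equation i, and M = ε·V is the storage per cell. Exposed so that
    reference (brute-force explicit) integrations can reuse the identical
    spatial operator.
    """
    grid = config.grid
    n = grid.n_cells
    centers, nodes = grid.centers, grid.nodes
    areas = grid.face_areas
    eps, Deff = _cell_coefficients(config, t)
    M = eps * grid.cell_volumes

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    b = np.zeros(n)

    d_left = centers - nodes[:-1]  # centre to left face
    d_right = nodes[1:] - centers  # centre to right face

    u_faces = (
        config.advection.face_velocity if config.advection is not None else None
    )
    shell_face = config.shell[0] if config.shell is not None else -1

    # interior faces f = 1 .. n-1 between cells f-1 and f
    f = np.arange(1, n)
    interior = f[f != shell_face]
    g = areas[interior] / (
        d_right[interior - 1] / Deff[interior - 1] + d_left[interior] / Deff[interior]
    )
    np.add.at(diag, interior - 1, -g)
    np.add.at(upper, interior - 1, g)
    np.add.at(diag, interior, -g)
    np.add.at(lower, interior, g)
    if u_faces is not None:
        phi = areas[interior] * u_faces[interior]
        pos = phi > 0
        np.add.at(diag, interior[pos] - 1, -phi[pos])
        np.add.at(lower, interior[pos], phi[pos])
        neg = phi < 0
        np.add.at(upper, interior[neg] - 1, -phi[neg])
        np.add.at(diag, interior[neg], phi[neg])

    # left boundary (face 0)
    if config.bc_left[0] == "dirichlet":
        cb = config.bc_left[1]
        g0 = areas[0] * Deff[0] / d_left[0]
        diag[0] -= g0
        b[0] += g0 * cb
        if u_faces is not None and areas[0] > 0:
            phi = areas[0] * u_faces[0]
            if phi > 0:
                b[0] += phi * cb
            elif phi < 0:
                diag[0] += phi
    # right boundary (face n)
    if config.bc_right[0] == "dirichlet":
        cb = config.bc_right[1]
        gn = areas[n] * Deff[n - 1] / d_right[n - 1]
        diag[n - 1] -= gn
        b[n - 1] += gn * cb
        if u_faces is not None:
            phi = areas[n] * u_faces[n]
            if phi > 0:
                diag[n - 1] -= phi  # outflow carries cell concentration
            elif phi < 0:
                b[n - 1] += -phi * cb

    # internal fixed-concentration shell (membrane-fed source surface)
    if config.shell is not None:
        j, cs = config.shell
        gl = areas[j] * Deff[j - 1] / d_right[j - 1]
        diag[j - 1] -= gl
        b[j - 1] += gl * cs
        gr = areas[j] * Deff[j] / d_left[j]
        diag[j] -= gr
        b[j] += gr * cs
        if u_faces is not None:
            phi = areas[j] * u_faces[j]
            if phi > 0:  # injected fluid enters the outward cell at c_s
                b[j] += phi * cs
            elif phi < 0:
                diag[j] += phi

    return lower, diag, upper, b, M


def _interface_face(config: TransportConfig) -> int:
    """Face index where the interface flux is reported (tissue side)."""
    if config.shell is not None:
        return config.shell[0]
    mat = config.grid.material
    changes = np.nonzero(np.diff(mat))[0]
    if changes.size:
        return int(changes[0]) + 1
    return 0  # homogeneous: report at the source boundary face


def _interface_flux(config, c, t: float, face: int) -> float:
    """Diffusive flux per unit area across ``face``, positive into tissue."""
    grid = config.grid
    centers, nodes = grid.centers, grid.nodes
    _, Deff = _cell_coefficients(config, t)
    if config.shell is not None and face == config.shell[0]:
        j, cs = config.shell
        return Deff[j] * (cs - c[j]) / (centers[j] - nodes[j])
    if face == 0:
        cb = config.bc_left[1] if config.bc_left[0] == "dirichlet" else c[0]
        return Deff[0] * (cb - c[0]) / (centers[0] - nodes[0])
    dL = nodes[face] - centers[face - 1]
    dR = centers[face] - nodes[face]
    g = 1.0 / (dL / Deff[face - 1] + dR / Deff[face])
    return g * (c[face - 1] - c[face])


def _source_influx(config, c, t: float) -> float:
    """Instantaneous solute influx (μM·μm³/s) through the source surface."""
    grid = config.grid
    areas = grid.face_areas
    centers, nodes = grid.centers, grid.nodes
    _, Deff = _cell_coefficients(config, t)
    u_faces = config.advection.face_velocity if config.advection is not None else None
    total = 0.0
    if config.shell is not None:
        j, cs = config.shell
        total += areas[j] * Deff[j - 1] * (cs - c[j - 1]) / (nodes[j] - centers[j - 1])
        total += areas[j] * Deff[j] * (cs - c[j]) / (centers[j] - nodes[j])
        if u_faces is not None and u_faces[j] > 0:
            total += areas[j] * u_faces[j] * cs
    elif config.bc_left[0] == "dirichlet":
        cb = config.bc_left[1]
        total += areas[0] * Deff[0] * (cb - c[0]) / (centers[0] - nodes[0])
        if u_faces is not None and areas[0] > 0 and u_faces[0] > 0:
            total += areas[0] * u_faces[0] * cb
    return total


# ---------------------------------------------------------------------------
# time integration


def solve_transport(config: TransportConfig) -> TransportResult:
    """Integrate the transport problem over the configured output schedule."""
    grid = config.grid
    n = grid.n_cells
    out_times = config.output_times
    t_end = out_times[-1]

    c = np.full(n, float(config.initial)) if np.isscalar(config.initial) else np.asarray(
        config.initial, dtype=float
    ).copy()
    if c.size != n:
        raise ValueError("initial condition length does not match grid")

    iface = _interface_face(config)

    snapshots = []
    snap_iter = iter(out_times)
    next_out = next(snap_iter)

    _, _, _, _, M = system_operator(config, 0.0)
    mass0 = float(M @ c)
    if next_out == 0.0:
        snapshots.append(c.copy())
        next_out = next(snap_iter, None)

    step_times = [0.0]
    iface_flux = [_interface_flux(config, c, 0.0, iface)]
    cum_delivered = [0.0]

    if t_end == 0.0:
        return TransportResult(
            grid=grid,
            times=out_times,
            concentrations=np.array(snapshots),
            step_times=np.array(step_times),
            interface_flux=np.array(iface_flux),
            delivered_mass=0.0,
            cumulative_delivered=np.array(cum_delivered),
            mass_residual=0.0,
            mass_residual_rel=0.0,
            config=config,
        )

    t = 0.0
    dt_prev = None
    c_prev = None  # c^{n-1}
    cumnet = 0.0
    cumnet_prev = 0.0
    cumsrc = 0.0
    cumsrc_prev = 0.0
    max_residual = 0.0
    dt = min(config.dt_init, t_end)

    ab = np.zeros((3, n))
    while t < t_end - 1e-12:
        # clip the step to land exactly on the next output time
        target = next_out if next_out is not None else t_end
        dt_step = min(dt, target - t)
        t_new = t + dt_step

        lo, di, up, b, M = system_operator(config, t_new)
        if c_prev is None or dt_prev is None:
            kappa, a1, a2 = 1.0, 1.0, 0.0  # backward Euler start
        else:
            w = dt_step / dt_prev
            kappa = (1.0 + w) / (1.0 + 2.0 * w)
            a1 = (1.0 + w) ** 2 / (1.0 + 2.0 * w)
            a2 = -(w**2) / (1.0 + 2.0 * w)

        ab[0, 1:] = -kappa * dt_step * up[:-1]
        ab[1, :] = M - kappa * dt_step * di
        ab[2, :-1] = -kappa * dt_step * lo[1:]
        rhs = M * (a1 * c + (a2 * c_prev if c_prev is not None else 0.0))
        rhs += kappa * dt_step * b
        c_new = solve_banded((1, 1), ab, rhs)

        # net boundary influx at the new state; interior fluxes cancel exactly
        Ac = di * c_new
        Ac[:-1] += up[:-1] * c_new[1:]
        Ac[1:] += lo[1:] * c_new[:-1]
        net = float(np.sum(Ac + b))
        src = _source_influx(config, c_new, t_new)
        cumnet_new = a1 * cumnet + a2 * cumnet_prev + kappa * dt_step * net
        cumsrc_new = a1 * cumsrc + a2 * cumsrc_prev + kappa * dt_step * src

        residual = abs(float(M @ c_new) - mass0 - cumnet_new)
        max_residual = max(max_residual, residual)

        c_prev, c = c, c_new
        cumnet_prev, cumnet = cumnet, cumnet_new
        cumsrc_prev, cumsrc = cumsrc, cumsrc_new
        dt_prev = dt_step
        t = t_new

        step_times.append(t)
        iface_flux.append(_interface_flux(config, c, t, iface))
        cum_delivered.append(cumsrc)

        if next_out is not None and t >= next_out - 1e-9:
            snapshots.append(c.copy())
            next_out = next(snap_iter, None)

        dt = min(
            dt * config.dt_growth,
            max(config.dt_cap_frac * t, config.dt_init),
            config.dt_max,
        )

    delivered = abs(cumsrc)
    scale = max(delivered, abs(mass0), 1e-300)
    return TransportResult(
        grid=grid,
        times=out_times,
        concentrations=np.array(snapshots),
        step_times=np.array(step_times),
        interface_flux=np.array(iface_flux),
        delivered_mass=cumsrc,
        cumulative_delivered=np.array(cum_delivered),
        mass_residual=max_residual,
        mass_residual_rel=max_residual / scale,
        config=config,
    )


# ---------------------------------------------------------------------------
# configuration builders and wrappers


def phantom_config(
    domain: PhantomDomain | None = None,
    solute: Solute = SULFORHODAMINE_B,
    saturation: SaturationModel | None = MEMBRANE_SATURATION,
    membrane: PorousMaterial = PETE_MEMBRANE,
    tissue: PorousMaterial = AGAROSE,
    grid: Grid1D | None = None,
    output_times: np.ndarray | None = None,
    source_concentration: float | None = None,
    **kwargs,
) -> TransportConfig:
    """Phantom delivery setup: fixed source at the channel face, membrane
    layer, agarose bulk, zero-concentration sink at x = L."""
    domain = domain or PhantomDomain()
    if grid is None:
        grid = build_phantom_grid(domain, dx=5.0, n_membrane=8, dx_max=40.0)
    c_src = (
        source_concentration
        if source_concentration is not None
        else solute.source_concentration
    )
    return TransportConfig(
        grid=grid,
        materials={MATERIAL_MEMBRANE: membrane, MATERIAL_TISSUE: tissue},
        solute=solute,
        saturation=saturation,
        bc_left=("dirichlet", c_src),
        bc_right=("dirichlet", 0.0),
        output_times=(
            output_times if output_times is not None else DEFAULT_PHANTOM_TIMES.copy()
        ),
        **kwargs,
    )


def organoid_config(
    domain: SpheroidDomain | None = None,
    solute: Solute = MAGNEVIST,
    tissue: PorousMaterial = ORGANOID,
    grid: Grid1D | None = None,
    advection: DarcyField | None = None,
    output_times: np.ndarray | None = None,
    source_concentration: float | None = None,
    **kwargs,
) -> TransportConfig:
    """Organoid delivery setup: fixed concentration on the membrane source
    shell, zero-flux centre, sink (culture well) at the outer surface."""
    domain = domain or SpheroidDomain()
    if grid is None:
        grid = advection.grid if advection is not None else build_spheroid_radial_grid(domain)
    shell_face = int(np.argmin(np.abs(grid.nodes - domain.source_radius)))
    if not 0 < shell_face < grid.n_cells:
        raise ValueError("source shell must be an interior grid face")
    c_src = (
        source_concentration
        if source_concentration is not None
        else solute.source_concentration
    )
    outer = ("dirichlet", 0.0) if domain.outer_bc == "sink" else ("neumann", 0.0)
    if output_times is None:
        output_times = np.array([0.0, 3600.0])  # 1 h delivery by default
    return TransportConfig(
        grid=grid,
        materials={MATERIAL_TISSUE: tissue},
        solute=solute,
        saturation=None,
        bc_left=("neumann", 0.0),
        bc_right=outer,
        shell=(shell_face, c_src),
        advection=advection,
        output_times=np.asarray(output_times, dtype=float),
        **kwargs,
    )


def solve_phantom(config: TransportConfig) -> TransportResult:
    """Transient solve of the membrane + agarose phantom configuration."""
    if config.grid.geometry != "planar":
        raise ValueError("phantom solves require a planar grid")
    return solve_transport(config)


def solve_organoid_radial(config: TransportConfig) -> TransportResult:
    """Transient solve of the 1D spherical organoid configuration."""
    if config.grid.geometry != "spherical":
        raise ValueError("organoid solves require a spherical grid")
    return solve_transport(config)


def solve_agarose_3d_embedding(
    solute: Solute = IOHEXOL,
    domain: SpheroidDomain | None = None,
    output_times: Sequence[float] = (0.0, 3600.0, 4 * 3600.0, 24 * 3600.0),
    **kwargs,
) -> TransportResult:
    """Delivery from the cage into surrounding agarose (contrast imaging
    setup): the radial solver with agarose material and Iohexol defaults,
    snapshots at 1, 4 and 24 h."""
    config = organoid_config(
        domain=domain,
        solute=solute,
        tissue=AGAROSE,
        output_times=np.asarray(output_times, dtype=float),
        **kwargs,
    )
    return solve_organoid_radial(config)
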