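"""Pressure-driven channel flow and Darcy leakage flow.

Flow in the device is firmly in the creeping (Stokes) regime — Reynolds
numbers are of order 1e-3 — so every flow quantity is strictly linear in
the applied pressure. Channel flow uses the classical Fourier-series
solution for laminar flow in a rectangular duct; the tapered channel is a
series chain of uniform duct segments (lubrication approximation); leakage
into the organoid is incompressible Darcy flow with the membrane acting as
a hydraulic resistance in series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Fluid, PorousMaterial, PETE_MEMBRANE
from .geometry import (
    ChannelProfile,
    MembraneSpec,
    SpheroidDomain,
    Grid1D,
    build_spheroid_radial_grid,
    channel_width_at,
)

__all__ = [
    "DuctFlowSolution",
    "DarcyField",
    "rectangular_duct_flow",
    "duct_flow_rate",
    "network_flow",
    "reynolds_number",
    "peclet_number",
    "darcy_radial_flow",
]


@dataclass(frozen=True)
class DuctFlowSolution:
    """Laminar flow through one uniform rectangular duct.

    Velocity in μm/s on the (y, z) cross-section grid; flow rate in μm³/s.
    """

    pressure_drop: float
    length_mm: float
    width: float
    depth: float
    y: np.ndarray
    z: np.ndarray
    velocity: np.ndarray  # shape (len(z), len(y))
    max_velocity: float
    mean_velocity: float
    flow_rate: float


@dataclass(frozen=True)
class DarcyField:
    """Steady radial Darcy (superficial) velocity field in the organoid."""

    grid: Grid1D
    face_velocity: np.ndarray  # μm/s at grid faces, positive outward
    pressure_drop: float
    flow_rate: float  # μm³/s through the source shell
    source_radius: float

    @property
    def max_velocity(self) -> float:
        return float(np.max(np.abs(self.face_velocity)))

    @property
    def max_velocity_radius(self) -> float:
        return float(self.grid.nodes[np.argmax(np.abs(self.face_velocity))])


def _series_sum_Q(w: float, h: float, n_terms: int) -> float:
    """Bracket factor of the rectangular-duct flow-rate formula (w >= h)."""
    n = np.arange(1, 2 * n_terms, 2, dtype=float)
    return 1.0 - (192.0 * h) / (np.pi**5 * w) * np.sum(
        np.tanh(n * np.pi * w / (2.0 * h)) / n**5
    )


def duct_flow_rate(
    width: float, depth: float, length_mm: float, dp: float, fluid: Fluid, n_terms: int = 40
) -> float:
    """Volumetric flow rate (μm³/s) through a w×h duct under pressure drop dp."""
    if min(width, depth, length_mm, dp) < 0 or width * depth * length_mm == 0:
        raise ValueError("geometry must be positive")
    w, h = (width, depth) if width >= depth else (depth, width)
    L = length_mm * 1e3
    return dp * h**3 * w * _series_sum_Q(w, h, n_terms) / (12.0 * fluid.viscosity * L)


def rectangular_duct_flow(
    width: float,
    depth: float,
    length_mm: float,
    dp: float,
    fluid: Fluid,
    n_terms: int = 40,
    n_grid: int = 41,
) -> DuctFlowSolution:
    """Fourier-series velocity profile for pressure-driven duct flow.

    The no-slip solution for a rectangular cross-section w×h is a cosh/sin
    series; with w ≫ h it reduces to the parallel-plate parabola with
    maximum h²Δp/(8ηL). The solution is symmetric under exchanging width
    and depth.
    """
    if width <= 0 or depth <= 0 or length_mm <= 0:
        raise ValueError("width, depth and length must be positive")
    if n_terms < 10:
        raise ValueError("n_terms must be >= 10")
    swapped = depth > width
    w, h = (width, depth) if not swapped else (depth, width)
    L = length_mm * 1e3
    G = dp / (fluid.viscosity * L)  # pressure gradient / viscosity

    y = np.linspace(0.0, w, n_grid)
    z = np.linspace(0.0, h, n_grid)
    Y, Z = np.meshgrid(y, z)
    u = np.zeros_like(Y)
    for n in range(1, 2 * n_terms, 2):
        a = n * np.pi / h
        # cosh(x)/cosh(X) for |x| <= X, overflow-safe exponential form
        x = np.abs(a * (Y - w / 2.0))
        X = a * w / 2.0
        ratio = np.exp(x - X) * (1.0 + np.exp(-2.0 * x)) / (1.0 + np.exp(-2.0 * X))
        u += (1.0 / n**3) * (1.0 - ratio) * np.sin(a * Z)
    u *= 4.0 * h**2 * G / np.pi**3

    Q = duct_flow_rate(width, depth, length_mm, dp, fluid, n_terms) if dp != 0 else 0.0
    if swapped:
        y, z, u = z, y, u.T
    return DuctFlowSolution(
        pressure_drop=dp,
        length_mm=length_mm,
        width=width,
        depth=depth,
        y=y,
        z=z,
        velocity=u,
        max_velocity=float(u.max()) if dp > 0 else 0.0,
        mean_velocity=Q / (width * depth),
        flow_rate=Q,
    )


def network_flow(
    profile: ChannelProfile,
    dp: float,
    fluid: Fluid,
    n_segments: int = 200,
    n_terms: int = 40,
) -> dict:
    """Flow through the tapered channel as N uniform duct segments in series.

    Each segment of the taper is treated as a uniform rectangular duct at
    its midpoint width (lubrication approximation); hydraulic resistances
    add in series. Returns the flow rate, total resistance and per-segment
    mean velocities for a single channel.
    """
    if n_segments < 10:
        raise ValueError("n_segments must be >= 10")
    L = profile.r_max_mm  # mm
    edges = np.linspace(0.0, L, n_segments + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    seg_len = np.diff(edges)
    widths = np.array([channel_width_at(profile, r) for r in mids])
    h = profile.depth
    # resistance of each segment: dp/Q for unit pressure
    resist = np.array(
        [
            1.0 / duct_flow_rate(w, h, l, 1.0, fluid, n_terms)
            for w, l in zip(widths, seg_len)
        ]
    )
    R_total = float(np.sum(resist))
    Q = dp / R_total
    return {
        "flow_rate": Q,
        "resistance": R_total,
        "segment_r_mm": mids,
        "segment_width": widths,
        "segment_mean_velocity": Q / (widths * h),
    }


def reynolds_number(mean_velocity: float, hydraulic_diameter: float, fluid: Fluid) -> float:
    """Re = ρ·u·D_h/η for u in μm/s and D_h in μm."""
    return fluid.density * (mean_velocity * 1e-6) * (hydraulic_diameter * 1e-6) / fluid.viscosity


def peclet_number(velocity: float, length: float, diffusivity: float) -> float:
    """Pe = u·L/D, the advective-to-diffusive transport ratio."""
    return velocity * length / diffusivity


def darcy_radial_flow(
    domain: SpheroidDomain,
    material: PorousMaterial,
    membrane: MembraneSpec,
    dp: float,
    fluid: Fluid,
    membrane_material: PorousMaterial = PETE_MEMBRANE,
    channel_profile: ChannelProfile | None = None,
    source_area: float | None = None,
    grid: Grid1D | None = None,
) -> DarcyField:
    """Steady incompressible Darcy leakage flow into the spherical organoid.

    Fluid enters across the membrane at the source shell (hydraulic
    conductance k_membrane/thickness over the exposed wetted area), flows
    radially outward through the organoid and leaves at the outer surface
    held at 0 Pa. Incompressibility makes r²·u(r) constant outside the
    shell; the velocity is the superficial (volume-flux) Darcy velocity.

    ``source_area`` overrides the wetted membrane area; by default it is
    the parylene-defined exposed area summed over all wings.
    """
    if dp < 0:
        raise ValueError("pressure drop must be non-negative")
    if material.permeability_um2 <= 0 or membrane_material.permeability_um2 <= 0:
        raise ValueError("permeability must be positive")
    if grid is None:
        grid = build_spheroid_radial_grid(domain)
    r_s = domain.source_radius
    r_eq = domain.equivalent_radius
    eta = fluid.viscosity
    if source_area is None:
        source_area = membrane.exposed_area(channel_profile or ChannelProfile())
    # series hydraulic resistances (Pa·s/μm³)
    R_mem = eta * membrane.thickness / (membrane_material.permeability_um2 * source_area)
    R_org = eta / (4.0 * np.pi * material.permeability_um2) * (1.0 / r_s - 1.0 / r_eq)
    Q = dp / (R_mem + R_org)
    faces = grid.nodes
    u = np.zeros_like(faces)
    outside = faces >= r_s - 1e-9
    u[outside & (faces > 0)] = Q / (4.0 * np.pi * faces[outside & (faces > 0)] ** 2)
    u[faces < r_s - 1e-9] = 0.0
    return DarcyField(
        grid=grid,
        face_velocity=u,
        pressure_drop=dp,
        flow_rate=Q,
        source_radius=r_s,
    )
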