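"""Device and simulation-domain geometry, plus finite-volume grid builders.

The device is a buckled 3D microfluidic "cage": eight tapered rectangular
microchannels (inner width 20 → 200 μm over 11.7 mm, constant 10 μm depth)
sealed by a 10 μm nanoporous PETE membrane whose parylene coating leaves
lithographically defined exposed openings. The cage encloses an oblate
spheroidal organoid (semi-axes 1.0 / 0.98 mm).

Two simulation domains are modelled:

* a rectangular agarose phantom, 5 mm along x with a zero-concentration
  sink at the far end (solved in 1D along x, membrane first);
* the organoid, reduced to 1D spherical symmetry about the cage centre
  with a source shell where the membrane contacts the tissue.

All coordinates are in μm. Grids are cell-centred finite-volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelProfile",
    "MembraneSpec",
    "CageSpec",
    "SpheroidDomain",
    "PhantomDomain",
    "Grid1D",
    "channel_width_at",
    "cage_diameter_at",
    "build_phantom_grid",
    "build_spheroid_radial_grid",
]

MATERIAL_MEMBRANE = 0
MATERIAL_TISSUE = 1  # agarose or organoid bulk, set by the run config


@dataclass(frozen=True)
class ChannelProfile:
    """Tapered rectangular microchannel: widths in μm, radial extent in mm."""

    inner_width_center: float = 20.0
    inner_width_edge: float = 200.0
    outer_width_center: float = 60.0
    outer_width_edge: float = 2000.0
    r_max_mm: float = 11.7
    depth: float = 10.0
    count: int = 8

    def __post_init__(self) -> None:
        if min(self.inner_width_center, self.outer_width_center, self.depth) <= 0:
            raise ValueError("channel widths and depth must be positive")
        if self.inner_width_edge < self.inner_width_center:
            raise ValueError("inner width must be non-decreasing with r")
        if self.r_max_mm <= 0:
            raise ValueError("r_max must be positive")


@dataclass(frozen=True)
class MembraneSpec:
    """Nanoporous PETE membrane bonded over the channels.

    Pore diameter and density are retained for documentation; hydraulic
    conductance is computed from Darcy permeability through the thickness.
    The parylene barrier restricts solute/fluid exchange to exposed
    openings; per wing these are modelled as a segment of length
    ``exposed_length_mm`` starting at radial position ``exposed_start_mm``
    along the channel, of the local inner channel width.
    """

    thickness: float = 10.0  # μm
    pore_diameter_nm: float = 200.0
    pore_density_per_cm2: float = 3e8
    barrier_thickness: float = 1.0  # μm parylene
    exposed_start_mm: float = 2.5
    exposed_length_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.pore_density_per_cm2 <= 0:
            raise ValueError("thickness and pore density must be positive")

    def exposed_area(self, profile: ChannelProfile) -> float:
        """Total wetted nanoporous area (μm²) over all wings.

        Per wing: exposed segment length × local inner channel width,
        evaluated at the segment midpoint of the taper.
        """
        mid_r = self.exposed_start_mm + 0.5 * self.exposed_length_mm
        width = channel_width_at(profile, min(mid_r, profile.r_max_mm))
        return profile.count * self.exposed_length_mm * 1e3 * width


@dataclass(frozen=True)
class CageSpec:
    """Buckled cage silhouette: (height z in μm, diameter in μm) anchors."""

    anchors: tuple[tuple[float, float], ...] = (
        (398.0, 771.0),
        (1480.0, 339.0),
        (2130.0, 1580.0),
    )

    def __post_init__(self) -> None:
        heights = [z for z, _ in self.anchors]
        if any(b <= a for a, b in zip(heights, heights[1:])):
            raise ValueError("anchor heights must be strictly increasing")
        if any(d <= 0 for _, d in self.anchors):
            raise ValueError("anchor diameters must be positive")


@dataclass(frozen=True)
class SpheroidDomain:
    """Oblate-spheroid organoid, reduced to a volume-equivalent sphere.

    ``source_radius`` marks the shell where the membrane interfaces the
    tissue; the default is half the maximum cage diameter in the
    organoid-enclosing region (771 μm → 385.5 μm).
    """

    r0_mm: float = 1.0  # equatorial semi-axis
    r0z_mm: float = 0.98  # polar semi-axis
    source_radius: float = 385.5  # μm
    outer_bc: str = "sink"  # concentration boundary at the culture well

    def __post_init__(self) -> None:
        if not 0 < self.source_radius < min(self.r0_mm, self.r0z_mm) * 1e3:
            raise ValueError("source radius must lie strictly inside the spheroid")

    @property
    def equivalent_radius(self) -> float:
        """Radius (μm) of the sphere with the spheroid's volume: (r0²·r0z)^(1/3)."""
        return (self.r0_mm**2 * self.r0z_mm) ** (1.0 / 3.0) * 1e3


@dataclass(frozen=True)
class PhantomDomain:
    """Agarose phantom slab: membrane + agarose along x, sink at x = L."""

    length_mm: float = 5.0  # total x extent incl. membrane
    height_um: float = 500.0
    membrane_thickness: float = 10.0  # μm

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("domain length must be positive")
        if not 0 < self.membrane_thickness < self.length_mm * 1e3:
            raise ValueError("membrane must be thinner than the domain")

    @property
    def length(self) -> float:
        return self.length_mm * 1e3


@dataclass(frozen=True)
class Grid1D:
    """Cell-centred 1D finite-volume grid (planar or spherical).

    ``nodes`` are the cell faces (length n+1, strictly increasing);
    ``material`` holds one material index per cell.
    """

    nodes: np.ndarray
    material: np.ndarray
    geometry: str = "planar"  # "planar" (unit cross-section) or "spherical"

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing, length >= 2")
        if len(self.material) != nodes.size - 1:
            raise ValueError("one material index per cell required")
        if self.geometry not in ("planar", "spherical"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "material", np.asarray(self.material, dtype=int))

    @property
    def n_cells(self) -> int:
        return self.nodes.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.nodes[:-1] + self.nodes[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.nodes)

    @property
    def face_areas(self) -> np.ndarray:
        """Area of each face (n+1). Planar grids use unit cross-section."""
        if self.geometry == "planar":
            return np.ones_like(self.nodes)
        return 4.0 * np.pi * self.nodes**2

    @property
    def cell_volumes(self) -> np.ndarray:
        """Cell measures: widths (planar, per unit area) or shell volumes."""
        if self.geometry == "planar":
            return self.widths
        return 4.0 / 3.0 * np.pi * np.diff(self.nodes**3)


def channel_width_at(profile: ChannelProfile, r_mm: float) -> float:
    """Inner channel width (μm) at radial position ``r_mm``, linear taper."""
    if not 0.0 <= r_mm <= profile.r_max_mm:
        raise ValueError(f"r={r_mm} mm outside [0, {profile.r_max_mm}] mm")
    frac = r_mm / profile.r_max_mm
    return profile.inner_width_center + frac * (
        profile.inner_width_edge - profile.inner_width_center
    )


def cage_diameter_at(cage: CageSpec, z: float) -> float:
    """Cage diameter (μm) at height ``z`` (μm), piecewise-linear through anchors.

    Below the first anchor the silhouette is extrapolated linearly to a
    vanishing diameter at z = 0 (the wings emerge from the central bond).
    """
    heights = np.array([a[0] for a in cage.anchors])
    diams = np.array([a[1] for a in cage.anchors])
    if not 0.0 <= z <= heights[-1]:
        raise ValueError(f"z={z} μm outside [0, {heights[-1]}] μm")
    xs = np.concatenate([[0.0], heights])
    ys = np.concatenate([[0.0], diams])
    return float(np.interp(z, xs, ys))


def _graded_segment(x0: float, x1: float, dx0: float, dx_max: float, ratio: float = 1.15) -> np.ndarray:
    """Faces over [x0, x1] starting at spacing dx0, growing geometrically to dx_max."""
    faces = [x0]
    dx = dx0
    while faces[-1] + dx < x1 - 1e-9:
        faces.append(faces[-1] + dx)
        dx = min(dx * ratio, dx_max)
    faces.append(x1)
    # merge a too-thin final cell into its neighbour
    if len(faces) > 2 and faces[-1] - faces[-2] < 0.25 * (faces[-2] - faces[-3]):
        del faces[-2]
    return np.asarray(faces)


def build_phantom_grid(
    domain: PhantomDomain,
    dx: float = 10.0,
    n_membrane: int | None = None,
    dx_max: float | None = None,
) -> Grid1D:
    """Finite-volume grid over membrane + agarose along x.

    With ``n_membrane=None`` the grid is uniform at spacing ``dx`` and the
    membrane occupies whichever leading cells fall inside its thickness
    (a 5 mm domain at 10 μm spacing gives 501 nodes). With ``n_membrane``
    set, the membrane is resolved by that many cells (each thinner than
    half the membrane) and the agarose spacing grades from ``dx`` at the
    interface up to ``dx_max`` toward the sink.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    L = domain.length
    t_m = domain.membrane_thickness
    if n_membrane is None:
        n = int(round(L / dx))
        if n < 2:
            raise ValueError("grid too coarse for the domain")
        nodes = np.linspace(0.0, L, n + 1)
    else:
        if n_membrane < 2:
            raise ValueError("membrane must be resolved by >= 2 cells")
        mem = np.linspace(0.0, t_m, n_membrane + 1)
        aga = _graded_segment(t_m, L, dx, dx_max if dx_max else 8.0 * dx)
        nodes = np.concatenate([mem, aga[1:]])
    centers = 0.5 * (nodes[:-1] + nodes[1:])
    material = np.where(centers < t_m, MATERIAL_MEMBRANE, MATERIAL_TISSUE)
    return Grid1D(nodes=nodes, material=material, geometry="planar")


def build_spheroid_radial_grid(
    domain: SpheroidDomain, dr: float = 10.0
) -> Grid1D:
    """1D spherical grid from r = 0 to the volume-equivalent radius.

    A face is placed exactly at the source-shell radius so the membrane
    interface coincides with a finite-volume face. Cell volumes telescope
    to the analytic sphere volume by construction.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    r_eq = domain.equivalent_radius
    r_s = domain.source_radius
    if r_s >= r_eq:
        raise ValueError("source shell must lie strictly inside the sphere")
    n_in = max(int(round(r_s / dr)), 2)
    n_out = max(int(round((r_eq - r_s) / dr)), 2)
    nodes = np.concatenate(
        [np.linspace(0.0, r_s, n_in + 1), np.linspace(r_s, r_eq, n_out + 1)[1:]]
    )
    material = np.full(nodes.size - 1, MATERIAL_TISSUE)
    return Grid1D(nodes=nodes, material=material, geometry="spherical")
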