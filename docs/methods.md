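# Methods

This note documents the physical model behind `organoflux`, the numerical
choices, the synthetic-data generator, and the limits of what the test
suite demonstrates.

## Physical model

### Channel hydraulics

Flow in the device's rectangular microchannels is inertia-free: with
water at room temperature, channel depths of 10 μm and velocities of
order 100 μm/s, Reynolds numbers are ~10⁻³. Velocity profiles therefore
come from the classical Fourier-series solution of Poisson's equation for
fully developed laminar flow in a rectangular duct,

u(y,z) = (4h²Δp)/(π³ηL) Σₙ odd n⁻³ [1 − cosh(nπ(y−w/2)/h)/cosh(nπw/(2h))] sin(nπz/h),

with the matching series for the flow rate. The cosh ratio is evaluated
in an exponential form that cannot overflow for wide ducts. In the
parallel-plate limit (w ≫ h) the peak velocity tends to h²Δp/(8ηL); for
the 10 μm channel depth, 690 Pa head and 11.7 mm length this is
≈ 736 μm/s. The tapered channel (inner width 20 → 200 μm over 11.7 mm) is
treated as N uniform duct segments in series (lubrication approximation,
N = 200 by default; refining 50 → 500 changes the total resistance by
< 0.5%).

### Darcy leakage into the organoid

Leakage from the channels through the nanoporous membrane into the tissue
is incompressible Darcy flow, u = −(k/η)∇p. The full buckled-wing
geometry is reduced to spherical symmetry about the cage centre: fluid
enters at a source shell of radius r_s = 385.5 μm (half the maximum cage
diameter of 771 μm), crosses the membrane (conductance k_mem/t_mem over
the wetted area), spreads radially through the organoid and leaves at the
outer surface held at 0 Pa. Incompressibility makes r²u(r) constant
outside the shell, so the peak superficial velocity sits at the shell.
The organoid is the volume-equivalent sphere of the measured oblate
spheroid (semi-axes 1.0/0.98 mm → r_eq = 993.3 μm).

The wetted membrane area is the parylene-defined exposed region, not the
whole shell: per wing, an exposed segment of length 1 mm starting at
radial position 2.5 mm along the channel, times the local inner channel
width, summed over 8 wings (≈ 5.3 × 10⁵ μm²). The opening location is a
device parameter; the segment length is not printed anywhere and 1 mm was
chosen once as the natural scale of the opening. Both are config
parameters. At 690 Pa this model gives a peak Darcy velocity of
≈ 1.9 μm/s at the shell — the right order of magnitude for intra-organoid
leakage, but quantitatively above the ~0.5 μm/s scale seen in the full 3D
geometry, where flow enters through discrete patches rather than a
uniform shell and the peak sits deeper inside the tissue. The spherical
reduction is a desk-scale estimate, not a replacement for the 3D solve.

### Transport in layered porous media

Solute transport obeys the volume-averaged advection–diffusion equation

ε ∂c/∂t = ∇·(D_eff ∇c − u c),  D_eff = s·ε·D/τ,

with porosity ε in the storage term, effective diffusivity in the flux,
tortuosity τ = 1 throughout, and partition coefficients between media set
to 1. A consequence worth noting: in a *homogeneous* porous slab the
porosity cancels and the apparent diffusivity is the free-solution D, so
the slab relaxation time constant is τ₁ = L²/(π²D), not L²/(π²εD).
Porosity still matters at material interfaces and for stored mass.

The nanoporous membrane wets gradually. Its saturation follows
s(t) = min(s₀ + kₛt, 1) with s₀ = 0.075 and kₛ = 3.7 × 10⁻⁵ s⁻¹, reaching
full saturation at (1 − s₀)/kₛ = 25,000 s ≈ 6.9 h. The linear law is
capped at 1 because physical saturation cannot exceed full; the crossover
time is exposed as `SaturationModel.saturation_time`. Non-membrane
domains are treated as fully saturated (s = 1).

Two configurations are solved:

* **Phantom** (planar 1D): membrane occupying x ∈ [0, 10 μm], agarose to
  x = 5 mm; fixed source concentration at the channel face (reservoir
  assumption — the channel is continuously perfused at constant head),
  zero-concentration sink at x = 5 mm, closed elsewhere.
* **Organoid** (spherical 1D): fixed concentration on the source shell at
  r_s, zero-flux regularity at r = 0, sink (culture well) at r_eq.
  Advection from the Darcy field is optional and off by default — the
  Péclet number u·t_mem/D ≈ 0.01–0.04 confirms diffusion-dominated
  delivery.

## Numerical scheme

* **Space**: cell-centred finite volumes, harmonic-mean interface
  diffusivities (exact flux continuity across the membrane/tissue
  contrast), first-order upwinding for advection (cell Péclet ≪ 1, so the
  scheme's monotonicity is bought at negligible accuracy cost). The
  default phantom grid resolves the membrane with 8 cells (1.25 μm) and
  grades the agarose spacing from 5 μm at the interface to 40 μm at the
  sink (142 cells); the spherical grid uses 10 μm shells with a face
  placed exactly at r_s. Observed spatial order on the erfc benchmark is
  ≈ 2.
* **Time**: variable-step BDF — backward Euler on the first step, BDF2
  thereafter — with a geometric ramp from 0.1 s and a cap of 2% of
  elapsed time per step (≈ 600 steps for a 24 h horizon). The membrane
  saturation is evaluated at the new time level each step (kₛΔt ≪ 1, so
  coefficient lagging within the step is immaterial).
* **Conservation**: cumulative boundary fluxes are integrated with the
  same BDF recurrence as the state, which makes the discrete mass balance
  an algebraic identity; the recorded residual is round-off
  (~10⁻¹³ relative) against a 10⁻⁸ tolerance.
* **Steady state**: earliest output time whose profile is within a 5%
  relative L∞ distance of the long-horizon profile (the criterion is a
  flag). Tolerances below ~3% cannot resolve before 6 h on principle,
  because the membrane keeps wetting until 6.9 h and the profile drifts
  at the ~1% level until then: measured 1% → 7.7 h, 3% → 6.0 h,
  5% → 5.0 h, 10% → 4.0 h.
* **Interface flux**: J = −D_eff ∂c/∂n per unit area on the tissue side
  of the membrane face, recorded at every accepted step. Because the
  early transient is strong (the semi-infinite agarose initially draws
  ~3 μM·μm/s against a steady 0.93), the three natural averaging
  conventions differ: time-averaged over the approach to steady state
  ≈ 1.6, steady value ≈ 0.93, whole-run average ≈ 1.1 μM·μm/s. All three
  are reported; the approach-to-steady average is the headline value.

## Calibration

`fit_saturation` estimates (s₀, kₛ), optionally with the free diffusivity
D, by bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) wrapping the phantom solver as forward model.
The loss is unweighted unless per-observation weights are supplied.
Identifiability needs dynamics: s₀ sets the early-time influx, kₛ the
subsequent acceleration, so at least two positive observation times are
required. Defaults: start (0.1, 10⁻⁵), bounds s₀ ∈ [0, 1],
kₛ ∈ [0, 10⁻²] s⁻¹; optional multistart draws seeded extra starts
(uniform in s₀, log-uniform in kₛ) and keeps the best optimum — at the
parameter scales of interest all starts agree, indicating no spurious
local minima. Inside the fitting loop the forward model runs on a
coarsened grid (5 membrane cells, agarose graded 10 → 100 μm, ~70 cells)
and a 5% step-cap; coarse-vs-fine model discrepancy is ~0.2% of signal,
which bounds the noiseless recovery error (measured < 0.3% on both
parameters). Standard errors come from the Gauss–Newton Jacobian and are
flagged NaN when the normal matrix is ill-conditioned (non-identifiable
regimes such as kₛ pinned at zero).

## Synthetic data

The generator emulates the two measurement modalities used to
characterize delivery, with the package's own solvers as ground truth:

* fluorescence line profiles along the phantom, 11 times from 0 to
  400 min in 40-min steps, positions every 50 μm;
* a normalized radial intensity profile of the loaded organoid after 1 h,
  intensity affine (monotone) in concentration.

Noise is multiplicative Gaussian at 1% of signal plus an additive floor
at 0.5% of peak signal — a fluorescence-like heteroscedastic model chosen
once as typical of line-profile measurements. One integer seed drives all
draws; the noiseless channel is stored alongside the noisy one and every
set carries a manifest sufficient for bit-identical regeneration.

What the generator does *not* emulate: optical blur and background
drift, detector nonlinearity, the 2D wing footprint in the phantom (the
source spans the membrane-contact face in the 1D reduction), MRI partial
volume and k-space artefacts, and any tissue heterogeneity. Passing the
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to real imaging
systematics.

## Problem sizes

Default problem sizes were chosen as the coarsest that hold every
benchmark comfortably inside its tolerance: 142 cells / ~600 steps for
the 24 h phantom run, ~70 cells / ~250 steps per forward solve inside the
fitting loop, 100 shells for the spherical solves. A full Monte-Carlo
recovery study (20 replicates at 1% noise) fits in well under a minute.

## Known limitations

* 1D reductions throughout; no reconstruction of the buckled 3D wing
  geometry, and the phantom's 2D wing footprint is not modelled.
* The exposed-membrane wetted area (and hence the Darcy flow rate) is
  known only to the order of magnitude; it is a config parameter.
* No solute uptake/reaction, no concentration-dependent viscosity, no
  temperature dependence, single solute at a time.
* The reservoir (fixed-concentration) source assumes perfusion is fast
  compared with leakage — valid at the flow rates computed here, but not
  checked self-consistently.
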