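# organoflux

Transport modelling for 3D microfluidic intra-organoid delivery.

Organoids beyond a few hundred micrometres develop starved, necrotic
cores because nutrients and reagents must diffuse in from the outside. A
recently developed class of buckled 3D microfluidic "cages" addresses
this by wrapping an organoid in tapered microchannels sealed with a
nanoporous membrane, so that solutes delivered under a small hydrostatic
head (a few hundred Pa) leak outward through the membrane directly into
the tissue interior. `organoflux` is a simulator and analysis package for
the transport physics of such devices: it answers how fast a solute
crosses the membrane, how far and how quickly it spreads through tissue
or a gel phantom, and how to calibrate the membrane's wetting kinetics
from measured concentration profiles.

## Model

Three coupled ingredients, all in the creeping-flow regime (Re ~ 10⁻³):

* **Channel hydraulics** — the Fourier-series solution for laminar flow
  in a rectangular duct; the tapered channel (20 → 200 μm inner width
  over 11.7 mm, 10 μm deep) as duct segments in series.
* **Darcy leakage** — incompressible porous-media flow
  u = −(k/η)∇p from the channels, across the membrane (conductance
  k_mem/t_mem over the exposed area), radially through the organoid to
  the culture well.
* **Advection–diffusion in layered porous media** —

      ε ∂c/∂t = ∇·(D_eff ∇c − u c),   D_eff = s(t)·ε·D/τ

  with the membrane's saturation growing linearly in time,
  s(t) = min(s₀ + kₛt, 1): a freshly primed nanoporous membrane wets
  gradually, so its effective diffusivity rises over the first hours.

Built-in constants (all overridable): membrane ε = 0.094,
k = 1.2×10⁻¹⁶ m², 10 μm thick; organoid ε = 0.2, k = 3.75×10⁻¹⁵ m²;
agarose ε = 0.99, k = 8.2×10⁻¹⁶ m²; free diffusivities 450 (Magnevist),
470 (sulforhodamine B), 250 (iohexol) μm²/s; saturation s₀ = 0.075,
kₛ = 3.7×10⁻⁵ s⁻¹; driving pressures 690/510/196 Pa.

The solver is a conservative finite-volume scheme (harmonic-mean
interface diffusivities, upwinded advection) with variable-step BDF time
integration; boundary fluxes are integrated with the same recurrence as
the state, so discrete mass balance holds to round-off. See
`docs/methods.md` for the full account.

## Worked example

Simulate dye delivery into the 5 mm agarose phantom and summarize it:

```python
import numpy as np
import organoflux as of
from organoflux.metrics import steady_state_time, interface_flux

config = of.phantom_config(output_times=np.arange(0, 86401, 1200.0))
run = of.solve_phantom(config)

steady = steady_state_time(run, rel_tol=0.05)
flux = interface_flux(run, window=(0.0, steady.time))
d_eff = of.effective_diffusivity(of.MAGNEVIST, of.PETE_MEMBRANE, s=1.0)
field = of.darcy_radial_flow(of.SpheroidDomain(), of.ORGANOID,
                             of.MembraneSpec(), 690.0, of.WATER)

print(f"membrane D_eff (saturated): {d_eff:.1f} um^2/s")
print(f"steady state reached at {steady.time/3600:.1f} h")
print(f"mean interface flux: {flux.mean_flux:.2f} uM*um/s "
      f"(steady {flux.steady_flux:.2f}, whole-run {flux.whole_run_mean:.2f})")
print(f"peak Darcy velocity: {field.max_velocity:.2f} um/s "
      f"at r = {field.max_velocity_radius:.0f} um")
```

Output:

```
membrane D_eff (saturated): 42.3 um^2/s
steady state reached at 5.0 h
mean interface flux: 1.63 uM*um/s (steady 0.91, whole-run 1.07)
peak Darcy velocity: 1.93 um/s at r = 386 um
```

Reading: the fully wetted membrane passes the MRI contrast agent at an
effective diffusivity of ~42 μm²/s (about a tenth of its free value); the
phantom settles to its linear steady profile within 5 hours; the average
flux across the nanoporous interface during that approach is
~1.6 μM·μm/s (higher than the 0.91 steady value, because the initially
empty gel draws solute fastest early on); and pressure-driven leakage
peaks at ~2 μm/s at the membrane shell — small enough that delivery is
diffusion-dominated (Pe ≈ 0.01–0.04).

The same pipeline is scriptable from a shell:

```sh
organoflux simulate-phantom --out-dir runs/phantom
organoflux synth --seed 7 --out-dir runs/synth
organoflux fit runs/synth/synthetic_phantom.csv --out-dir runs/fit
organoflux hydraulics --out-dir runs/hyd
```

`fit` recovers the saturation parameters (s₀, kₛ) from profile time
series by bounded nonlinear least squares around the forward solver;
`synth` generates seeded noisy datasets with the measurement schedule of
the fluorescence experiments (11 times × 40 min, positions every 50 μm).
Every run directory contains a `manifest.json` recording the resolved
configuration, seed and output digests.

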