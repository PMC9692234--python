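# Methods

`ssadose` simulates the dosimetry of a *spot-scanning aperture* (SSA): a
small-bore metal collimator, with an attached range shifter, that a robot
aligns with each individual pencil-beam-scanning (PBS) proton beamlet.
Collimating every spot shrinks the lateral spot size — most valuable for
shallow targets, where a range shifter is mandatory and inflates spots badly —
at the price of reduced beamlet transmission, degraded depth-dose shape from
slit-scattered protons, secondary neutrons, and extra delivery time.  The
package quantifies each of these tradeoffs with a desk-scale Monte Carlo
pipeline plus deterministic side models.

## Geometry and coordinates

A beamlet travels along +z through an ordered stack (all distances in mm):
range shifter (polycarbonate slab, thickness set by its water-equivalent
thickness, WET), an optional air gap, the aperture (metal slab with one
cylindrical bore of radius 1–4 mm), an air gap equal to the
aperture-to-surface distance (ASD), and a water phantom starting at z = 0
with 1×1×1 mm voxels (half-open voxel ownership, lateral grid centered on
the beam axis).  The isocenter sits at z = +50 mm.  A proton is inside the
bore iff its distance to the (possibly laterally offset) bore axis is
*strictly* less than the bore radius; the test is re-evaluated at every
substep, so protons can cross between wall and bore mid-aperture — the
slit-scattering channel.  Default aperture thicknesses are 11.1 mm
(tungsten) and 18.5 mm (nickel), slightly above the computed minimum
stopping thickness for protons with 100 mm residual water range.

Comparator geometries: *extended range shifter* (ERS, the 45 mm WET shifter
with its downstream face 300 mm upstream of isocenter), *moveable range
shifter* (the shifter at the SSA's position, no aperture), *open beam* (no
devices) and the *infinitesimal beamlet* (point source, zero divergence —
the theoretical lower limit on spot size).

## Transport model

The condensed-history kernel is vectorized over protons and advances them
in z-slabs:

* **Energy loss.**  Mean loss from embedded Bethe-formula stopping-power
  tables (log-log interpolated; see *Reference data*), with per-step energy
  loss capped at 5% of the current energy by adaptive substepping.
  Straggling is Gaussian (Bohr), with the width capped at the mean step
  loss so the zero floor cannot bias thin-medium (air) steps.  Protons are
  terminated below 1 MeV, depositing their residual energy locally.
* **Multiple Coulomb scattering.**  Highland's formula per step with the
  correlated lateral-displacement sampling.  The logarithmic correction is
  evaluated at the *cumulative* radiative thickness each proton has
  traversed (tracked per proton), i.e. the differential form of the
  formula: applying the log term to each 0.2–1 mm substep instead would
  underscatter thick slabs by ~20% in sigma.  A fresh proton taking a
  single step reproduces the textbook single-slab expression exactly.
* **Step sizes.**  ≤ 1 mm in water and plastic, ≤ 0.2 mm in metals (to
  resolve slit scattering through the thin aperture), and up to 50 mm in
  air — one Highland sample over a long air path is statistically
  equivalent to summed substeps, and the (negligible) air energy loss is
  still integrated.
* **Nuclear interactions.**  Simplified removal model: primaries above
  10 MeV are removed with an exponential attenuation length of 120 g/cm² in
  water, scaled by the A^(1/3) dependence of the per-nucleus cross section;
  a removed proton deposits 60% of its energy locally and the rest is
  booked as escaped.  No secondary-particle cascade.  This yields realistic
  peak-to-entrance ratios; halo-sensitive quantities inherit its
  approximation.
* **Scoring.**  Deposited energy per voxel (dose, arbitrary per-proton
  units — every reported quantity is a ratio or a width), and dose-averaged
  LET accumulators Σ(ε·S), Σ(ε) with S the water linear stopping power at
  the mid-step energy (keV/µm).  An energy ledger (per-element deposits +
  escapes) closes to the injected energy within 1% and is asserted in the
  tests.
* **Randomness.**  One seeded PCG64 generator per transport call, consumed
  in fixed array order, so every run is bit-reproducible from (source,
  geometry, seed).  Study-level seeds are derived from the user seed by
  hashing the configuration tag.

## Beam model (synthetic data)

The machine model emulates a modern PBS system: 17 nominal energies from
70 to 230 MeV, in-air spot sigma at isocenter interpolated monotonically in
1/E between 6 mm (70 MeV) and 2 mm (230 MeV).  Beamlets are parallel
Gaussian bundles (zero divergence by default, configurable) sampled at a
plane 500 mm upstream of isocenter, so the free-drift sigma at isocenter
equals the configured value.  The nominal energy for a target Bragg-peak
depth makes the water CSDA range equal target depth + upstream WET;
energies below 70 MeV are rejected (shallow targets require the shifter).

What this emulates — and does not: real beams have energy spread, nonzero
divergence/emittance correlations and nozzle scattering; collimator-edge
physics lacks nuclear secondaries; lateral halos are Gaussian-only.
Consequently quantities dominated by the *core* phase space (spot sigma,
transmission ordering, depth-dose shape) are trustworthy at the few-percent
level, while halo- and spectrum-tail-sensitive quantities are approximate.
Notably the in-air sigma at intermediate energies follows the two-anchor
interpolation, not a measured machine curve: the global transmission
maximum at the deepest Bragg peak (which depends directly on the beam sigma
at the aperture at ~140 MeV) comes out ≈ 0.59 here versus ≈ 0.7 reported
for the clinical machine — reproducing that value would require the
machine's actual sigma(E) ≈ 2.6 mm at that energy.

Synthetic treatment fields stand in for clinical head-and-neck plans: per
field, a proximal WET depth drawn from 15–38 mm and an extent from
20–55 mm (capped at 99 mm), energy layers every 5 mm WET, spots on a 5 mm
grid inside per-layer randomized ellipses (semi-axes 10–30 mm), and
log-normal protons-per-spot (median 10⁷, log-sigma 0.5).  The defaults are
chosen so every generated field satisfies the shallow-field eligibility
rule (WET minimum < 40 mm, maximum < 100 mm).

## Deterministic side models

**Minimum stopping thickness.**  The aperture must stop the highest-energy
protons it will see.  The thickness is defined as the depth at which the
depth-dose in the aperture material falls to 0.1% of its Bragg-peak value,
times a 1.05 safety margin.  It is computed deterministically: slow a
proton down along its CSDA path, project path onto depth through the
mean-cosine detour implied by the accumulated Highland variance (a ~2-3%
shortening in high-Z metals, negligible in water), and convolve with the
Bohr range-straggling width.  The "plus 5%" is interpreted as
multiplicative on the falloff depth (the alternative — 5% of something
else — is not well defined); for the 100 mm-residual-range design energy
this gives 11.1 mm in tungsten and 17.5 mm in nickel, consistent with the
published device thicknesses (11.1 / 18.5 mm).

**Neutron model.**  Neutrons are not transported.  Thick-target yields per
stopped proton are a power law in proton energy, Y_W(E) = 0.06·(E/100)^2.1
for tungsten, with per-material ratios calibrated once against published
thick-target collimator comparisons: nickel at 60–70% of tungsten (70% at
230 MeV), lead at 90%, brass at 80%.  The dose kernel combines the
solid-angle-averaged fluence over a 20 cm diameter water cylinder behind
the block with a water kerma factor (6×10⁻¹¹ Gy·cm²) and a 2× forward
enhancement.  Absolute doses are order-of-magnitude; every reported
comparison is a ratio or an ordering, and the calibration provenance is
recorded in the yield fixture.  The field-level estimator rescales each
spot's fluence so the planned protons still pass the aperture
(delivered = planned / transmission) and attributes the absorbed remainder,
at the range-shifter-degraded energy, to neutron production.

**Delivery time.**  t_add = N·x/v for N spots at spacing x and constant
motor speed v; acceleration is ignored.

## Analysis conventions

* Integrated depth dose (IDD): lateral sum per 1 mm depth bin, optionally
  normalized to the first bin ("entrance").  Peak-to-entrance =
  max / first bin.
* Bragg-peak depth: 3-point parabolic refinement around the IDD maximum.
* Spot sigma: Gaussian least-squares fit to the central x-profile
  (y summed over the central 3 rows) restricted to |x − center| ≤ 3× the
  RMS estimate — collimated spots are non-Gaussian in the shoulders and the
  fit-to-core mimics clinical sigma reporting.  A plain RMS width is
  available as an option.  Sigma is evaluated at each run's own Bragg-peak
  depth.
* Transmission: Σdose(with aperture) / Σdose(without), from paired runs
  sharing one source phase space; values above 1 are rejected as mismatched
  inputs.
* Dose-averaged LET profile (ILD): let_num/let_den along the central-axis
  voxel column.

## Problem sizes and numerical choices

Sweeps default to 2×10⁵ histories per configuration and the IDD-shape
studies to 5×10⁵, on a 61×61×120 voxel grid — enough that spot sigmas repeat
to ~1% and transmissions to ~0.005 between seeds.  Curve fits use
scipy's Levenberg–Marquardt with an RMS-based initial guess; degenerate
inputs (all-zero profiles, flat depth curves, zero entrance dose, geometry
overlaps, out-of-table energies) raise explicit errors rather than
returning NaNs.

## Known limitations

* Gaussian-only straggling and scattering: no Landau/Vavilov tails, no
  single-scattering halo, so profile far-tails are underestimated.
* No secondary protons from nuclear interactions — the low-energy exit
  spectrum contains only slit-scattered primaries.
* The range-shifter-to-aperture gap tradeoff comes out slightly steeper
  than reported for the clinical system: transmission falls ~5–6× faster
  than spot sigma here versus ~4× reported; the parallel-beam phase space
  grows faster at the aperture with gap than the real machine optics.
* Neutron results are calibrated ratios, not transport; equivalent dose
  (Sv) is out of scope.
* Water phantom only; no patient heterogeneity, no beam optics magnets.
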