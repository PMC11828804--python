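# Methods

## Scope and model geometry

The package models a two-layer PDMS zonation-on-chip device bonded to a
glass slide: a lower gas layer (2 mm) whose serpentine channel network
(0.2 × 0.1 mm channels) is fed with incubator air (19% O2) on one side and
nitrogen on the other, and an upper layer (3 mm) carrying the perfused
cell-culture chamber (1 mm deep). Oxygen permeates the PDMS membrane above
the channels and imprints three zones on the culture surface — a
periportal→pericentral analogue aligned with the medium flow, so the
nutrient gradient runs parallel to the oxygen gradient.

All solvers work on a 2-D vertical cross-section (x = flow direction,
z = vertical, z = 0 at the glass). The quantities of interest — outlet
glucose, zone-wise oxygen, wall shear — vary chiefly along x and z, and the
width is treated as homogeneous. The full 3-D serpentine geometry is out of
scope; under zone 2, where the two gas lines interleave, the channel pattern
is represented as alternating Dirichlet stripes at a configurable pitch
(default 0.5 mm; a mid-value option exists). Because the membrane and medium
are much thicker than the pitch, the culture surface sees the stripe average
either way.

### Reconstructed chamber footprint

The chamber footprint is not a published dimension. The defaults,

* chamber height h = 1.0 mm (the PMMA mold sheet thickness),
* chamber width w = 13.7 mm, chosen so the parallel-plate wall shear
  τ = 6µQ/(wh²) reproduces the reported 3.4 × 10⁻⁶ Pa at 0.5 µL/min with
  µ = 0.93 mPa·s,
* chamber length L = 49.4 mm, chosen so that seeding the chamber volume at
  400k cells/mL gives N_total = 270,712 cells, the count consistent with
  the reported glucose drop 5.5 → 4.2 mM at 0.5 µL/min via the mass balance
  C_out = C_in − r·N/Q,

are reconstructions, not measurements, and every field is overridable in
the configuration. Uncertainty in this reconstruction propagates directly
into the glucose and shear predictions (roughly linearly), which is why
those comparisons carry ~10% bands.

## Hydrodynamics

At the working flow rates the chamber Reynolds number is ≪ 1, so the
steady incompressible Navier–Stokes problem reduces exactly to fully
developed plane Poiseuille flow: u(z) = (6Q/(wh³))·z(h−z), with wall shear
τ = 6µQ/(wh²). A numerical Stokes solver is deliberately omitted — the
closed form *is* the solution of the reduced geometry. The closed form is
strictly linear in Q; reported 3-D values for the same device are not
mutually linear (2 × 10⁻⁵ Pa at 5.0 vs 3.4 × 10⁻⁶ Pa at 0.5 µL/min), so
comparisons at flow rates other than the 0.5 µL/min anchor are made within
a factor-of-1.5 band (the reported value must lie within ±50% of the model
value), documented rather than hidden.

## Oxygen transport

Oxygen is solved over the entire cross-section (channels, PDMS bulk,
medium) with:

* diffusivities D_O2 = 2.69 × 10⁻⁹ m²/s (medium) and 3.25 × 10⁻⁹ m²/s
  (PDMS);
* an equilibrium partition condition at every PDMS/medium interface,
  C_pdms = K·C_medium with K = 10, adopted in the direction consistent with
  C_sat,pdms = 1.8 mol/m³ against ~0.18 mol/m³ in air-saturated medium;
* gas channels as Dirichlet patches at the channel-top face (zone 1 at the
  19% saturation value, zone 3 at 0, zone 2 striped), the patch plane
  sitting one channel height above the glass so the membrane is
  1.9 mm thick;
* ambient-exposed faces (device top and the PDMS side faces) held at the
  19% saturation value — the device is deliberately not sealed against the
  incubator atmosphere;
* a Michaelis–Menten surface sink on the culture surface,
  OCR = (q·N_t/A_t)·C/(K_m + C) with q = 3.5 × 10⁻¹⁶ mol/s per cell and
  K_m = 6.3 × 10⁻³ mol/m³, multiplied by a Heaviside necrosis cutoff at
  C_nec = 1.0 × 10⁻⁴ mol/m³ (consumption stops where cells would be
  necrotic). The cutoff is a hard step by default; an optional cubic smooth
  step over a configurable half-width (suggested 0.1·C_nec) is available to
  aid convergence on marginal grids.

**Partition-potential formulation.** The solver works in the potential
ψ = C_medium = C_pdms/K, continuous across interfaces, with effective
diffusivity K·D_pdms in PDMS and D_medium in medium. Flux continuity and
the concentration jump then hold *exactly by construction* — the interface
needs no special-casing, and the jump ratio test recovers K to discretization
accuracy.

**Discretization.** Uniform finite volumes with harmonic-mean face
diffusivities (exact for piecewise-linear multi-layer profiles), default
100 × 50 cells over 49.4 × 5 mm (vertical resolution must keep ≥ 3 cells
across the membrane and ≥ 1 channel row; the builder enforces this).
Dirichlet cells are identity rows, so a gas switch changes only the
right-hand side and transient solves reuse one LU factorization. The
nonlinear sink is resolved by Picard iteration with the saturation factor
taken implicitly, to a relative residual of 10⁻¹⁰.

**Time integration.** Backward Euler (unconditionally stable), default
dt = 10 s with snapshots every 600 s to match the 10-min imaging cadence.
The transient gas-switch scenario starts from the steady state of a device
equilibrated at 19%.

**Medium advection of oxygen** is implemented (upwind, with an inlet at the
air-saturated level) but off by default for the gas-switch scenarios: at
0.5 µL/min its effect on the culture-surface field is below 1% of the
reference level (verified in the tests), and the sensing experiments it
mirrors were dominated by the gas supply. Both modes are tested.

## Glucose transport

Glucose is confined to the medium: upwind finite-volume advection by the
Poiseuille profile plus diffusion (D = 6.16 × 10⁻¹⁰ m²/s), inlet at
5.5 mol/m³, outflow (zero diffusive flux) outlet, no-flux walls, and a
zero-order uptake flux r·N_total/A_culture on the culture surface with
r = 2.4 × 10⁻⁹ mol/min per 10⁶ cells. The inflow carries the inlet value
advectively, so the supplied flux is exactly Q·C_in and the flow-averaged
outlet equals the closed-form mass balance C_out = C_in − r·N/Q by discrete
conservation — the mass balance doubles as an independent oracle at the 2%
level. Where the surface concentration falls below 0.1% of the inlet level
the uptake scales proportionally to the remaining concentration (taken
implicitly), so uptake ceases smoothly where glucose is exhausted and the
field stays non-negative; this matters only in the supply-limited regime
(e.g. far below 0.2 µL/min at default seeding).

Per-row advective fluxes are the exact integrals of the parabolic profile
over each cell, so depth-integrated flux equals Q at machine precision at
any vertical resolution.

## ROI extraction and time metrics

Sensor sections are 1.5-mm disks on the culture surface; the default layout
places ten of them (4/2/4 across zones 1/2/3) well inside each zone so ROI
means report zone levels rather than boundary blends. In the 2-D model a
disk reduces to its x-footprint with chord-length area weights. Oxygen is
reported as %O2 = C_medium·K/C_sat,pdms × 19.

*Stabilization time*: the earliest time on the window grid (600 s windows)
after which every ROI signal changes by less than 1% of full scale in every
subsequent window; "full scale" is the 19% reference span for device
scenarios. The 10-min cadence quantizes the result to 10-min multiples.

*Sensor response time*: t90 — time from step initiation until the signal
completes 90% of the plateau-to-plateau excursion, interpolated linearly
between frames. The 90% criterion is this package's definition (the
literature value it is compared against does not state one). The
calibration-scenario model is 1-D diffusion through the 2-mm gas layer:
channel-side Dirichlet step 19% → 0, far side sealed by the low-permeability
polystyrene sensor film, sensor at the sealed face. The analytic series
gives t90 = ln(4/0.1π)·4L²/(π²D) ≈ 21.2 min, and the numerical slab solver
reproduces the series within 1%.

## Sensing model and calibration

Two-site Stern–Volmer: R/R0 = f1/(1 + Ksv·[O2]) + f2 with f2 = 1 − f1
enforced exactly; strictly decreasing, inverted in closed form on the
physical band f2 < R/R0 ≤ 1. Readings at or below f2 are flagged (possible
bleaching), R/R0 > 1 clamps to 0% with a QC flag. The ratio is
mean(red)/mean(green) per ROI disk — channel means before the ratio — with
no background subtraction by default (an optional constant offset exists).
A 19%/0% two-point calibration cannot identify f1 and Ksv jointly, so
two-point mode fixes f1 (default 0.8, configurable) and solves Ksv exactly;
multi-point mode least-squares fits both from ≥ 3 levels. Replicate frames
per level are averaged. ROIs reading above 21% O2 (19% + 2% margin) for ≥ 3
consecutive frames are excluded as photobleached; single-frame spikes are
kept.

## Quantification

Viability = (total − dead)/total × 100 from thresholded 8-connected
component counts (Otsu threshold by default, fixed override available —
counts are threshold-sensitive, hence the documented choice). Albumin RFU =
mean 8-bit grey of the albumin (red) channel / mean of the nuclei (blue)
channel per image; per-image *mean* intensities are used (integrated
intensities would cancel identically in the ratio only at equal areas).
Zone summaries use the sample SD (n−1); the across-zone comparison is a
one-way ANOVA (scipy), pinned in the tests to the explicit sums-of-squares
formula at 10⁻¹⁰.

## Synthetic data

The generator emulates the study's acquisition: 10-min frame cadence,
1.5-mm sensor disks, zone plateaus at the cell-free measured levels
(19/13/7 %O2) reached exponentially (τ = 600 s) after the gas switch, 36
imaging sites per zone for staining. Noise is multiplicative Gaussian per
channel (photon-like), σ = 1% by default — no noise characterization was
published, so this is a generator choice. Sensor rendering defaults to the
optical scale of the sensing microscope (3.45 µm/px); tests and the
demonstration pipelines render at coarser scales (40–80 µm/px), which
changes only disk pixel counts, not the ratio statistics. Staining images
place non-overlapping nuclei disks with Bernoulli live/dead splits and
per-cell lognormal albumin factors scaled by zone gains (3/2/1), so the
expected RFU ordering is known by construction.

What passing the synthetic round-trips does *not* show: real sensor films
have spatial inhomogeneity, photobleaching drift, and optical cross-talk
between dyes; real staining images have illumination fields, cell clusters
and out-of-focus light. None of these are modelled, so pipeline accuracy on
real data will be bounded by those effects, not by the numerics verified
here.

## Problem sizes and numerical defaults

Device solves use the 100 × 50 default grid (5,000 cells); mesh-doubling
changes outlet glucose and zone means by < 2% (tested). Transients run
7,200 s at dt = 10 s; the slab scenario uses 80 cells at dt = 5 s. Steady
nonlinear solves converge in well under 200 Picard iterations to 10⁻¹⁰
relative residual. All stochastic outputs are driven by explicit
`numpy.random.default_rng` seeds and are bit-reproducible.

## Known limitations

* The cross-section model cannot resolve width-wise effects (the study
  itself notes slightly higher albumin on one longitudinal side).
* Equilibration observed on the bench (~2 h) is slower than the modelled
  ~30–40 min; the study attributes the gap to interface effects and protein
  adsorption on the PDMS, which are not modelled here.
* Zone-3 predictions are the most sensitive to the ambient-exposure
  boundary and the membrane thickness tolerance (±0.3 mm in fabrication);
  the model holds both at nominal values.
* Shear comparisons away from the 0.5 µL/min anchor inherit the
  non-linearity of the reported 3-D values discussed above.
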