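# Methods

`mwablate` models how fatty liver disease changes the outcome of hepatic
microwave ablation (MWA). It couples three pieces: an image-derived
constitutive model that maps liver fat percentage to tissue properties, a
time-harmonic electromagnetic (EM) solver for a 915 MHz single-slot coaxial
antenna, and a transient Pennes bioheat solver with Arrhenius damage
accumulation. This note records the model, the assumptions, the numerical
choices, and what the synthetic data do and do not establish.

## Constitutive material model

Fat fraction `f` is handled in percent throughout (only the dielectric
mixture converts internally to a fraction).

* **Thermal conductivity**: `k(f) = (k_liver − k_fat) e^{τ_k f} + k_fat` with
  `k_liver = 0.521`, `k_fat = 0.21` W/(m·K) and `τ_k = −0.0546` per percent.
  The curve decays from the zero-fat liver value toward (never reaching) the
  pure-fat value.
* **Dielectrics**: volume-fraction mixing of the 915 MHz endpoint values,
  `σ: 0.861 → 0.11` S/m and `ε_r: 46.8 → 10.8` between zero fat and pure
  fat. Published tables of the intermediate states appear to carry one
  rounding step more than the formula; the formula is treated as canonical
  and table values are matched to ±0.003 S/m and ±0.2 permittivity units.
  One entry (`k` at 21.20 % fat) evaluates to 0.3077, which we round to
  0.308 where the source prints a truncated 0.307; agreement is asserted to
  one unit in the last printed digit.
* **Perfusion**: linear decrease from the healthy `ω_0 = 0.018` 1/s to a
  cirrhotic floor `ω_cirr = 0.011` 1/s, saturating at 35 % fat. The floor
  follows from 11 kg/(m³·s) with blood density 1000 kg/m³ — the same
  conversion that makes 18 kg/(m³·s) equal 0.018 1/s.
* **Tumor (HCC)**: fixed `σ = 1.24` S/m, `ε_r = 55.7`, `k = 0.624` W/(m·K);
  density, heat capacity and Arrhenius constants equal the bulk liver values.
  Tumor perfusion defaults to the surrounding parenchyma's rate (no
  independent clinical value is adopted); pure fat is modelled as
  unperfused. Bulk `ρ` and `c_p` do not vary with fat fraction.
* **Disease classes**: index 0 = no infiltrative fat; low/mild/moderate/high
  classes split at 6, 17 and 22 % fat, left-closed/right-open so that the
  partition is exhaustive and non-overlapping.

## Electromagnetic model

The time-harmonic vector wave equation with complex permittivity
`ε̃ = ε_r − jσ/(ωε_0)` is reduced to the axisymmetric TM₀ problem for the
azimuthal magnetic field `H_φ` — the standard formulation for coaxial slot
antennas. We solve for the scaled unknown `w = r·H_φ`: the coax TEM mode
(`H_φ ∝ 1/r`) is then exactly constant and representable by linear elements,
which removes a spurious discrete cutoff that otherwise appears at
sub-millimetre coax radii. Quadrature radii of the `1/r`-weighted forms are
clamped to half the element centroid radius on axis-touching elements; the
O(h) error this introduces is confined to the axis layer where `H_φ`
vanishes by regularity.

Boundary conditions:

* metal surfaces (inner conductor, slotted shield, short-circuit plug) are
  meshed as excluded regions whose boundaries carry the natural
  perfect-electric-conductor condition;
* the coax cross-section at the entry surface is a matched modal port driven
  by the TEM mode. The port reflection coefficient S11 is the power-
  normalized projection of the reflected field on the incident mode (the
  published S-parameter expression is degenerate as printed — identical
  numerator and denominator — so the conventional definition is used);
* the exterior carries a first-order scattering condition with the local
  medium's wavenumber; the `1/r` curvature term is retained on
  radially-facing facets.

**Power normalization.** "60 W continuous power" is interpreted as *net*
power entering the port after reflection (clinical generator semantics): the
linear solution is rescaled so the net port Poynting flux equals the drive
power. An `incident` reference is available behind a flag; with the
benchmark antenna stand-in it would deliver only ~29 W net and was rejected
(see Limitations).

The sparse complex system is factorized directly (SuperLU); no iterative
tolerances are exposed. SAR is the element-wise `½σ|E|²` with `E` recovered
from the P1 gradient of `w`. A power budget (absorbed + radiated through the
scattering boundary vs delivered) closes to well under 2 % on the default
mesh.

## Antenna and domain geometry

The clinical applicator's internal dimensions are proprietary, so the
antenna is the standard published single-slot coaxial benchmark: inner
conductor radius 0.135 mm, dielectric outer radius 0.470 mm (PTFE,
`ε_r = 2.03`), shield thickness 0.125 mm, catheter outer radius 0.895 mm
(`ε_r = 2.6`), 1 mm air slot centred 5.5 mm above a short-circuited tip,
inserted 65 mm through the top surface of a liver cylinder (default radius
40 mm, height 100 mm — far enough that the fixed 37 °C wall is
ablation-inert radially). All dimensions are configurable. A 2 cm spherical
tumor, when present, is centred on the slot. Meshes are graded
tensor-product triangulations with interfaces on grid lines, ≥10 elements
across the slot, and near-field spacing of 0.1–0.25 mm.

## Bioheat and damage model

Pennes' equation `ρc_p ∂T/∂t = ∇·(k∇T) − ρ_b c_{p,b} ω_b (T − T_b) + SAR` is
integrated by backward Euler (default `dt = 0.5` s, unconditionally stable)
with lumped mass; on the structured right-triangle meshes the stiffness
matrix is an M-matrix, so the scheme satisfies a discrete maximum principle.
The perfusion term is a *sink* toward blood temperature (the published form
carries a sign typo that would make perfusion unconditionally heating).
Blood properties: `ρ_b = 1000` kg/m³ (forced by the perfusion unit
conversion) and `c_{p,b} = 3617` J/(kg·K) (standard reference value).
Boundary conditions: 37 °C Dirichlet on the exterior walls, convective
saline cooling `−k∂T/∂n = h(T − T_ext)` with `h = 980` W/(m²·K) and
`T_ext = 20` °C on the antenna–tissue interface, symmetry on the axis. The
EM field is solved once and held constant (properties are
temperature-independent); perfusion does not shut down with coagulation.

Damage accumulates per node as the Arrhenius integral
`α(t) = ∫ A e^{−ΔE/(R T)} dt` (trapezoidal per step; liver/tumor
`A = 7.39×10³⁹` 1/s, `ΔE = 2.58×10⁵` J/mol), and the damaged fraction is
`θ_d = 1 − e^{−α}`. Necrosis is `θ_d > 0.98` (α > ln 50). The necrotic
region is the union of tissue elements whose *vertices* all pass the
threshold (conservative; a centroid rule is available), its volume is the
exact revolution integral `2π∫r dA`, the long-axis diameter is the axial
extent of the passing nodes and the short axis twice their maximal radius.
An optional voxel mode computes the same metrics for 3D damage arrays.
Dose–volume trajectories are sampled every 15 s; the probe temperature is
recorded every step at a point 5 mm radially from the slot centre (nearest
mesh node).

## Synthetic data

Patient imaging is protected, so all inputs are synthetic. Fat-fraction
volumes are Gaussian-filtered white noise (default correlation length 8 mm,
emulating the smooth spatial heterogeneity of chemical-shift fat maps)
inside an ellipsoidal liver mask at mDIXON-like voxel spacing
(2.083×2.083×3 mm), affinely rescaled so the masked sample mean and SD equal
the disease-state targets (3.9±2.3, 14.70±3.6, 21.20±2.9, 29.90±3.7 %)
exactly before clipping to [0, 100]. A three-segment cylindrical "portal"
tree provides the vessel-exclusion mask. The ROI protocol mirrors the
clinical reading: 1 cm diameter in-plane discs, fully inside the liver,
disjoint from vessels, centres at least one diameter apart, placed by seeded
rejection sampling (the manual placement of a radiologist is not
reproducible; the spread policy is ours). What passing tests show: the
sampling and aggregation machinery is unbiased and reproducible on fields
with the clinical first- and second-order statistics. What they do not
show: robustness to water–fat swaps, motion artefacts, focal sparing
patterns, or real vessel anatomy.

Anatomical variability across the four synthetic "patients" of the sweep is
induced by seeded perturbations of liver extents (±10 % radius, ±8 % height)
and insertion depth (±3 mm); the resulting between-geometry SDs are not
expected to match the patient-cohort SDs of the source study.

## Experiment pipeline

The sweep enumerates geometries × disease states × tumor on/off (4×5×2 = 40;
20 without tumors), runs EM → bioheat → damage per configuration at 60 W for
15 min, and reports per-state mean ± SD of volume and diameters, dose–volume
trajectories (dose = power × time), probe-temperature envelopes, paired
two-sided t-tests between states (pairing by geometry, flagged at p < 0.01,
degenerate zero-variance pairs reported without p; no multiple-testing
correction), and a perfusion sensitivity table that reruns the low-fat state
at {0.0116, 0.0228} 1/s and the high-fat state at {0.01, 0.0144} 1/s as
absolute overrides.

## Numerical verification

The suite checks, among others: exact reproduction of the property table;
TEM `1/r` field and ~0 reflection on a matched coax; |S11| ≈ 1 on a short;
TEM decay in a lossy line equal to the plane-wave attenuation constant to
2 %; port Poynting flux equal to the drive power to 0.1 %; EM power budget
closure to 2 %; perfusion-only relaxation at rate `ρ_b c_{p,b} ω_b/(ρc_p)`
to 0.5 %; exact enthalpy conservation on insulated domains; the discrete
maximum principle; revolution volumes equal to Pappus values; and the
damage closed forms (`θ_d(ln 50) = 0.98`, constant-temperature `α = rate·t`
to 1e-10 against quadrature).

Default problem sizes are desk-scale by design: ~19k triangles per domain,
`dt = 0.5` s over 900 s (1800 implicit steps against one factorization),
about 5 s per configuration end-to-end.

## Known limitations

* **Antenna stand-in.** With the benchmark dimensions the antenna reflects
  ~51 % of incident power at 915 MHz (the published benchmark is a 2.45 GHz
  design); net-power normalization makes deposition self-consistent, but
  zone *shape* details differ from the clinical device. In particular a
  backward-heating tail along the shaft — a bound sheath mode of the
  insulated antenna that real applicators suppress by design — grows with
  fat content and inflates the zero-fat→high-fat volume increase to ~+54 %
  against the reported ~+40 % (the main lobe alone reproduces ~+34 %).
  Alternative stand-ins (slot retuned for 915 MHz match, 14-gauge radii,
  bare-metal shaft) move the error elsewhere rather than removing it.
* **Early tumor dynamics.** With equal net power, the tumor's higher
  electrical conductivity always raises near-probe SAR, so with-tumor
  volumes lead at all doses; the reported early-dose ordering (no-tumor
  faster, curves crossing later) is not reproduced and most likely depends
  on per-configuration reflected power of the unpublished antenna.
* No temperature-dependent properties, vaporization/latent heat, tissue
  contraction, or perfusion shutdown (deliberately, matching the modelling
  scope); temperatures near the slot can therefore exceed 100 °C.
* The full-3D patient-geometry pathway (segmentation-derived meshes) is out
  of scope; `build_domain(mode="full_3d")` raises, while voxel-based damage
  metrics support 3D fields.
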