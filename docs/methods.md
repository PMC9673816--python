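# Methods

This note documents the two model families in `glucolux`, their default
parameterization, the numerical schemes, and the judgment calls made where
the physical setup is underdetermined. Units follow the conventions of
each field: optical coefficients in cm⁻¹ over a mm-scale voxel grid
(converted internally), chemistry in SI (mol/m³, m²/s, s).

## Tissue and sensor geometry

The skin block is 17 × 17 × 4 mm of dorsal-wrist tissue discretized into
0.05-mm cubic voxels (340 × 340 × 80), origin at the surface under the
source center, Z downward, half-open voxel intervals with 0-based indices.
Three layers: epidermis 0–0.1 mm, dermis 0.1–1.6 mm, hypodermis 1.6–4 mm.
The layer depths are literature-typical for the dorsal wrist; the 1.6-mm
dermal/subcutaneous junction is the depth marked in the displacement-study
figures. Both are configurable.

Three candidate insertable designs share the constraints: 6.5-mm total
length, alternating repeating units of the two assays, and insertion
through a 17-gauge needle, operationalized as *circumscribed cross-section
diameter ≤ needle bore* (default 1.19 mm, thin-wall 17G; the gauge fixes
the outer diameter but not the wall, so the bore is configurable).

* **Design 1 (current barcode)**: 0.7 × 0.9 mm cuboid, transverse
  alternating slabs (default 2 × 3.25 mm, the coarsest split).
* **Design 2 (stacked cylinder)**: coaxial disks; diameter defaults to the
  needle-inscribed 1.19 mm. This is a deliberate design choice: the
  cylinder's advantage over the cuboid is precisely that it maximizes
  sensing volume under the circular insertion constraint, so the inscribed
  diameter is the natural parameterization. It is the main geometric
  assumption behind the design-comparison ratios.
* **Design 3 (longitudinal rods)**: a 2 × 2 bundle of full-length rods,
  two per assay on opposite diagonals, rod diameter defaulting to the
  needle-inscribed bundle (d = bore/(1+√2) ≈ 0.49 mm). The published
  drawings of this design are not dimensioned in text, and the comparison
  ratio against it is very sensitive to rod diameter (absorption in a rod
  scales roughly with footprint × (1 − e^(−μₐ·chord))); reproducing a
  ratio near 3.2 would require rods roughly half this diameter. We keep
  the maximal-packing default and flag the ratio as geometry-limited.

Rasterization labels a voxel by its center (ties resolve toward the
sensor, keeping thin compartments contiguous); compartments alternate
assay labels along the long (X) axis. Inter-compartment spacer walls are
zero-thickness in the optical model; spacers matter only in the chemical
model.

## Monte Carlo photon transport

MCML-style implicit-capture random walk on the voxel grid, one
splitmix64 RNG stream per photon index (results independent of execution
order; bit-reproducible per seed). Optical depth to the next interaction
is sampled once and consumed across voxel boundaries (memoryless
property); at each interaction the local voxel tallies w·μₐ/μₜ and the
photon deflects by the Henyey–Greenstein inverse CDF. Russian roulette
below weight 10⁻⁴ (survival 0.1) with the net created/destroyed weight
tallied, so the energy ledger `launched = absorbed + escaped + roulette`
closes to round-off; the suite asserts < 10⁻⁶ relative. Refractive index
is 1 everywhere (index matching), so there are no Fresnel events; the top
surface tallies escape (the readout plane), lateral and bottom boundaries
absorb.

Optical properties at 680/800 nm (cm⁻¹): epidermis μₐ 0.78/0.46, μs
294.1/250.0, g 0.9; dermis μₐ 0.48/0.30, μs 195.3/140.8, g 0.9; sensor
hydrogel μₐ 10⁻⁶, μs 5·10⁻⁴, g 0.75; both assays μₐ 5/10⁻⁶, μs 10⁻⁶,
g 0.75, quantum yield 1. The hypodermis has no published row and defaults
to dermis values; we also evaluated literature subcutaneous-fat values
(μₐ ≈ 0.10 cm⁻¹, μs′ ≈ 12 cm⁻¹) and found the headline quantities nearly
unchanged (e.g. the 2-mm beam FWHM moves only ~0.15 mm), so this
assumption is not the dominant uncertainty.

The two-stage luminescence simulation samples a fixed emission-photon
budget from the absorbed-excitation × quantum-yield distribution over
assay voxels (two-pass fluorescence: equivalent in expectation to spawning
per absorption event, with bounded memory), launches isotropically, and
attributes each escaping photon to its source assay. Lateral fluence
profiles use a track-length estimator within the single 0.05-mm voxel
layer at the requested depth, averaged over a ±0.25-mm central strip; FWHM
is linearly interpolated at half peak, with flat and multi-modal profiles
rejected (a noisy low-budget profile can legitimately fragment at the
half-level — raise the photon budget rather than smooth).

A note on what the beam width *can* be: with the dermis values above,
μs′ ≈ 19.5 cm⁻¹ and μ_eff = √(3μₐ(μₐ+μs′)) ≈ 5.4 cm⁻¹, diffusion-theory
spreading of a 1.75-mm source predicts a half-maximum width near 3–3.6 mm
at 2 mm depth. The package's Monte Carlo reproduces exactly this range;
a substantially wider beam is not attainable from these coefficients.

## Design-study drivers

Design comparison runs each design centered at (0, 0, 2 mm) with
replicated two-stage simulations and reports total (both assays summed)
surface-escaping luminescence, with pairwise ratios and propagated
standard errors. Offset sensitivity sweeps X and Y ∈ {−5, −3, 0, 3, 5} mm
and Z ∈ {1.25, 2, 2.75} mm; "relative luminescent intensity" is
normalized per design per axis to its maximum. Unit-size selection fixes
total length and subdivides into 1–15 compartments per assay at ±5-mm X/Y
offsets; the selected thickness is the largest whose per-assay outputs
change by < 5 % (relative) to the next-finer subdivision at every tested
offset. The ideal sensor length equals the excitation FWHM at the target
depth, and the domain count is the rounded length/unit ratio.

Default photon budgets are 10⁵–10⁶ per stage with 3 replicates.
Replicate-mean sampling error at 3·10⁵ photons is ≈ 1 % on the ratio
quantities — far below the geometry-assumption uncertainty discussed
above. The acceptance script runs 3·10⁵ excitation / 2·10⁵ emission
photons × 3 replicates per design/offset, a problem size chosen so the
full recomputation stays in the minutes range on a single core.

## Glucose-oxidase kinetics and lifetime readout

Rate constants (sensing hydrogel): k₁ = 100 m³/(mol·s), k₋₁ = 0.003 s⁻¹,
k₂ = 300 s⁻¹, k₃ = 1000 m³/(mol·s), k₋₃ = 150 s⁻¹, k₄ = 50 s⁻¹, total
enzyme Eₜ = 0.1463 mol/m³. Enzyme species are immobile; only G and O₂
diffuse. The quasi-steady cycle flux used by the steady-state solver is
obtained by setting the four enzyme-species derivatives to zero under
E + E′ + X₁ + X₂ = Eₜ:

    R = k₂ α Eₜ / (1 + α + (k₂α/k₄)(1 + 1/β)),
    α = k₁G/(k₋₁+k₂),  β = k₃O₂/(k₋₃+k₄),

with glucose and O₂ consumed 1:1 (saturation limit Eₜk₂k₄/(k₂+k₄) ≈ 6.27
mol·m⁻³·s⁻¹). Catalase is present in the physical assay but absent from
the printed reaction set; an H₂O₂-recycling term is deliberately not
modeled so the package matches the published equations.

Lifetime: τ = τ₀/(1 + K_sv[O₂]), τ₀ = 201 µs. The published K_sv = 0.023
is unitless in the source; the default convention here is µM⁻¹ (so
capillary O₂, 0.009 mol/m³ = 9 µM, gives τ = 166.5 µs). The convention is
an explicit config enum (`uM`, `mol/m3`, `mmHg`); it rescales absolute τ
but cancels out of time-to-steady-state and crosstalk conclusions. The
sensor-level lifetime is the volume-weighted mean of the local τ over
enzymatic cells (the spatial aggregation rule used by the original
readout is unpublished; intensity weighting is available).

An important emergent property of these constants: the effective
first-order O₂ consumption in the sensor, ~k₃Eₜ·(E′ fraction) ≈ 10² s⁻¹,
gives an O₂ penetration depth √(D/k) of only a few µm. Any glucose above
trace level (stoichiometrically, 0.009 mol/m³ suffices) therefore drives
the sensor interior anoxic, and the sensor-mean lifetime responds to
glucose in a nearly all-or-nothing fashion — see Limitations.

## Finite-volume transport solver

Structured rectilinear cell-centered finite volumes replace the original
unstructured finite elements; mesh-quality metrics of that workflow are
not reproduced. Diffusive face conductances use harmonic means
(concentration and flux continuity at region interfaces; no partition
coefficient, since none is published). Channel advection uses a
face-centered plane-Poiseuille profile: on every vertical face the open
(fluid, contiguous-from-top) height carries a no-slip parabola normalized
to the exact inlet flux, and vertical face velocities follow from
discrete continuity — the field is divergence-free cell by cell, so
upwind advection is exactly conservative and the top-wall normal velocity
closes to zero. Full Navier–Stokes is not solved: at 9 mm/s in a
millimeter channel Re ≪ 1 and entry lengths are negligible.

Time stepping is first-order operator splitting, chosen for robustness at
the stiffness contrast between ms-scale kinetics and minutes-scale
diffusion: (1) backward-Euler transport of G and O₂ through prefactorized
sparse LU (unconditionally stable, M-matrix positivity); (2) zeroth-order
tissue sinks, linearly ramped below 10⁻³ mol/m³ so they cannot drive
concentrations negative; (3) backward-Euler update of the full
six-species network per enzymatic cell by a vectorized Newton iteration
(batched 6 × 6 solves, analytic Jacobian, automatic sub-stepping on
non-convergence). Enzyme conservation holds to Newton tolerance by
construction. Default dt = 0.5–2 s; plateau lifetimes are dt-independent
to < 0.5 % on the implicit path (asserted in the suite).

Steady states (interstitial crosstalk) use a damped Picard solver on the
QSS-reduced system: the cycle flux is linearized implicitly in each
species (R ≈ (R/c)·c), preserving positivity, and iterated to 10⁻¹⁰
relative change. The suite cross-checks it against the time-dependent
path on a small configuration (dual route, agreement < 0.5 %).

## Flow-cell experiment

Channel 7.6 × 2.8 mm with the 4 × 0.5-mm enzymatic sensor centered on the
bottom wall; the sensor's upper corners carry a quarter-disc fillet mask
(default radius 0.1 mm, not dimensioned in the source) mimicking the
cylindrical sensor. Inflow 0.009 m/s on the left edge with Dirichlet
concentrations, outflow right, impermeable walls. Inlet O₂ defaults to
0.009 mol/m³ (the published initial/capillary value; the actual
oxygenation of the bench solution is unstated and configurable). Grid
0.05 mm, within the source's sensor element-size range.

The protocol steps inlet glucose through 0, 2.78, 5.55, 8.34, 11.1 mol/m³
with 45-min holds (long enough for a ~20-min settling time plus plateau);
the sensor-mean τ is sampled every 15 s. TSS of a transition runs from
the first crossing of 1.05·τ_initial (0.95 for falling transitions — the
published definition narrates only rising steps; the mirrored threshold is
the symmetric reading) to the first entry within 5 % of the final
plateau, with linearly interpolated crossing times; a transition whose
total excursion never crosses its thresholds has no defined TSS. Plateaus
are verified by a trailing-slope criterion (|dτ/dt| < 10⁻³ µs/min over
2 min).

## Interstitial experiment

A 1-mm-tall 2-D slice: 12 alternating 0.36-mm enzymatic/nonenzymatic
domains (0.9 mm tall) separated by inert hydrogel spacers, 0.05-mm tissue
stand-offs above and below, 0.05-mm tissue end caps. Total length =
12·0.36 + 11·spacer + 0.1 mm, i.e. 4.53 mm at 0.01-mm spacers to
15.42 mm at 1.0-mm spacers — this arithmetic fixes the spacer sweep to
0.01–1.0 mm and the end caps to 0.05 mm, reconciling the source's
conflicting spacer-range statements with its printed length range.
Capillary Dirichlet boundaries hold G = Pw and O₂ = 0.009 mol/m³;
zeroth-order tissue sinks consume 0.027 (G) and 1.04·10⁻⁵ (O₂) mol/(m³·s).

The capillary condition is applied on **all four** domain edges by
default. The source text names the top and bottom boundaries but also
places capillaries 0.05 mm from the sensor *in each direction*; with
impermeable ends, a no-enzyme control run still produces a several-percent
spurious "crosstalk" signal, because the end-cap tissue column — 1 mm
between capillaries, where the sink could notionally depress glucose by
R·h²/8D ≈ 13 mol/m³ — starves against the sealed wall. That artifact has
nothing to do with assay interaction (the metric's purpose), and real
subcutis is perfused at ~0.05-mm capillary spacing in every direction, so
capillary-fed ends are both the physical and the purposive reading.
Zero-flux ends remain available (`capillary_ends=False`).

Grid 0.01 mm × 0.025 mm (resolves the thinnest spacer and the
stand-offs). The crosstalk metric is the per-nonenzymatic-domain percent
difference of steady-state mean glucose between two spacer widths,
100·(C_wide − C_narrow)/C_narrow, and its maximum absolute value.

The capillary glucose waveform Pw(t) is not tabulated in the source; the
`synthetic` module supplies a constant 2.78 mol/m³ (the crosstalk study
runs at steady state, where the waveform shape is irrelevant) and a
configurable piecewise-linear meal-like excursion (baseline 2.78, peak
11.1, 30-min rise / 60-min fall) for time-dependent runs.

## Synthetic inputs: what they do and do not emulate

All inputs are configuration; nothing is downloaded. The generators
produce: glucose step ladders at the published hold levels; constant and
meal-like capillary waveforms (deterministic given a seed; optional
Gaussian noise clipped at zero); and small voxel scenes with analytically
known optics (uniform slab for Beer–Lambert, transparent block with a
point emitter for solid-angle escape, mirror-symmetric two-compartment
sensor for symmetry checks). They emulate the *temporal structure* of the
experiments — levels, durations, shapes — not physiological glucose
dynamics (no insulin/meal model), sensor fouling, or optical-property
variability between subjects. Passing tests therefore demonstrate model
correctness under the published nominal parameters, not robustness across
a population.

## Known limitations

* **Design-comparison ratios are geometry-limited.** The candidate
  designs' printed drawings are not dimensioned in machine-readable form;
  the defaults reconstruct them from the stated constraints. The
  design-2/design-1 ratio lands near the published value under the
  needle-inscribed cylinder assumption, but the design-3 comparison is
  acutely sensitive to rod diameter and the default 2 × 2 maximal packing
  yields a substantially smaller ratio than published.
* **Beam FWHM.** As derived above, the printed dermis coefficients bound
  the 2-mm beam half-width near 3.2 mm; the package reports what those
  coefficients produce.
* **Lifetime response saturates.** With the published rate constants and
  enzyme loading, the sensor interior goes anoxic at any supra-trace
  glucose, so plateau lifetimes for the four nonzero glucose steps are
  nearly identical and only the first transition has a defined TSS, on
  the scale of a minute — a direct consequence of the µm-scale O₂
  penetration depth, which also means the O₂ boundary layer is
  unresolved at practical grids (the glucose field, which the crosstalk
  metric reads, is grid-converged; the suite asserts < 2 % change under
  refinement). A graded, minutes-scale response would require an
  effective turnover ~10⁴ × slower relative to diffusion.
* The optical model ignores polarization, Fresnel reflection (by the
  index-matching assumption), time-resolved transport, and detector
  optics; the chemical model ignores H₂O₂ effects, enzyme deactivation,
  temperature, fibrosis, and 3-D flow.
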