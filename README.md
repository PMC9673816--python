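# glucolux

In-silico design tools for a fully insertable, multimodal optical
continuous glucose monitor (CGM): a millimeter-scale "barcode" sensor of
alternating repeating units of two glucose-sensing assay chemistries — an
enzymatic phosphorescence-lifetime assay (glucose oxidase + an O₂-quenched
phosphor) and a nonenzymatic competitive-binding FRET assay — injected
through a 17-gauge hypodermic needle and read through the skin by a
wearable. The package is aimed at biosensor and biophotonics modelers who
need to answer two questions before fabricating such a device: *does enough
luminescence get out of the tissue for each candidate geometry?* and *do
the two assay chemistries interfere with each other's glucose supply once
implanted?*

It contains two model families and the experiment drivers that turn them
into design decisions:

**Voxel Monte Carlo tissue optics** (`geometry`, `optics`, `design_study`).
A three-layer skin block (epidermis/dermis/hypodermis, 17 × 17 × 4 mm,
0.05-mm voxels) contains a parametric sensor; 680-nm excitation photons are
launched from a 1.75-mm square LED (top-hat near field, Lambertian far
field) and tracked with an implicit-capture random walk — step length
−ln(u)/μₜ, weight deposit w·μₐ/μₜ per interaction, Henyey–Greenstein
scattering with anisotropy g, Russian roulette below weight 10⁻⁴. A second
pass samples 800-nm emission photons from the absorbed-energy distribution
in the assay voxels (quantum yield 1) and scores the emission weight
escaping the top surface, per source assay. Drivers compare candidate
designs, sweep source–sensor offsets, measure the excitation-beam FWHM at
the 2-mm target depth, and pick the repeating-unit thickness at which both
assays are excited evenly.

**Glucose-oxidase reaction–diffusion chemistry** (`kinetics`, `rd_solver`,
`flowcell`, `interstitial`). The classical ping-pong GOx cycle

    E + G ⇌ X₁ → E′ + gluconate        (k₁, k₋₁; k₂)
    E′ + O₂ ⇌ X₂ → E + H₂O₂           (k₃, k₋₃; k₄)

is coupled to 2-D finite-volume transport of glucose and O₂ (implicit
diffusion/advection via sparse LU, L-stable backward-Euler reaction update
per cell). Local O₂ maps to phosphorescence lifetime through Stern–Volmer,
τ = τ₀/(1 + K_sv·[O₂]) with τ₀ = 201 µs, K_sv = 0.023 µM⁻¹. Drivers
reproduce a bench flow-cell glucose-step protocol (sensor-mean lifetime
trace and its 5 %/5 % time-to-steady-state) and an interstitial implant
model with capillary boundary sources, zeroth-order tissue consumption, and
variable inert spacers between sensing domains, quantifying the glucose
"crosstalk" imposed on the nonenzymatic domains by their enzymatic
neighbors.

## Worked example

Build the optimized stacked-cylinder barcode (4.3 mm long, 0.36-mm
repeating units, needle-inscribed 1.19-mm diameter), implant it 2 mm deep
under the LED, and run both Monte Carlo stages:

```python
from glucolux import geometry, optics
from glucolux.kinetics import SternVolmerParams, lifetime, o2_in_unit

scene = geometry.tissue_scene()
design = geometry.build_design("stacked_cylinder", 4.3, unit_thickness=0.36,
                               cross_section=geometry.Cylinder(1.19))
print(f"{design.n_units_total} sensing domains of "
      f"{design.unit_thickness:.3f} mm in a {design.total_length} mm sensor")

placed = geometry.rasterize(design, geometry.Placement(0, 0, 2.0), scene)
ex = optics.propagate(placed, n_photons=100_000, seed=1)
em = optics.run_luminescence(ex, placed, n_photons=100_000, seed=2)
print(f"excitation weight absorbed in tissue+sensor: {ex.absorbed_total:.0f} / 100000")
print(f"luminescent weight reaching the skin surface: "
      f"assay1 {em.per_assay_luminescence['assay1']:.0f}, "
      f"assay2 {em.per_assay_luminescence['assay2']:.0f}")

sv = SternVolmerParams()
print(f"lifetime at capillary O2 (9 uM): {lifetime(o2_in_unit(0.009, 'uM'), sv):.1f} us "
      f"(tau0 = {sv.tau0} us)")
```

prints

```
12 sensing domains of 0.358 mm in a 4.3 mm sensor
excitation weight absorbed in tissue+sensor: 28039 / 100000
luminescent weight reaching the skin surface: assay1 1206, assay2 1254
lifetime at capillary O2 (9 uM): 166.5 us (tau0 = 201.0 us)
```

Reading: the 4.3-mm sensor carries 12 alternating assay domains (6 per
assay); about 28 % of the launched excitation weight is absorbed somewhere
in the block (most of the rest backscatters out of the skin); the two
assays return nearly equal luminescence at the detector plane, as intended
for a centered sensor; and in air-equilibrated interstitial fluid the
phosphor's lifetime sits at 166.5 µs, rising toward 201 µs as glucose
consumption depletes O₂.

The same experiments are scriptable from the shell:

```bash
glucolux --out results design-study fwhm --photons 300000
glucolux --out results flowcell --protocol default
glucolux --out results interstitial --spacer-sweep 1.0,0.01
glucolux --out results reproduce-all --scale ci
```

Each command writes tidy CSV tables plus a JSON-lines manifest recording
the configuration snapshot, seeds and wall times. All physical parameters
(optical properties per medium, rate constants, diffusivities, protocol
levels) live in a nested YAML configuration; any value can be overridden
with `--config my.yaml`, and defaulted values are flagged in the manifest.

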