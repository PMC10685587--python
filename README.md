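# lamella

Analysis toolkit for lamellar neutron diffraction and mechanics of
stacked lipid bilayers — built around the comparison of phosphate-free
betaine-lipid (DGTS-type) membranes with their phosphatidylcholine
(PC) counterparts, but general to any centrosymmetric multilayer.

Given indexed Bragg-peak intensities from a θ–2θ scan of a supported
multilayer under controlled humidity, the package

1. **reduces** them to structure-factor magnitudes,
   |F_n|² = C_abs·C_Lor·I_n with C_abs = α/(1−e^(−α)), α = 2µt/sinθ and
   C_Lor = sin 2θ, and d-spacings from Bragg's law;
2. **phases** them: centrosymmetry restricts phases to signs
   ν_n ∈ {±1}, chosen by exhaustive search under physical constraints
   at the water-matched (≈8% D2O) contrast;
3. **reconstructs** the scattering-length density profile
   ρ(z) = (2/d)·Σ ν_n|F_n|cos(2πnz/d) and extracts the bilayer
   thickness d_b (headgroup centre-to-centre, mirrored-Gaussian fit)
   and water thickness d_w = d − d_b;
4. **fits forces**: the exponential hydration repulsion
   Π = Π₀·e^(−d_w/λ_w) against osmotic pressures from the Kelvin
   relation Π = −(k_BT/v_w)·ln RH, plus the beam-theory scaling
   κ ∝ d_b³;
5. **fits mechanics**: the Caillé parameter
   η = πk_BT/(2d²√(κB/d)) and de Gennes length Λ = √(κ/(Bd)) from
   off-specular Bragg-sheet maps, via a discrete-smectic Gaussian
   fluctuation simulator with kinematic scattering, inverted in closed
   form to the bending modulus κ and compression modulus B;
6. **analyses MD density profiles**: water polarization, leaflet
   dipole moments, Gibbs–Duhem pressures Π = −(µ−µ₀)/v_w⁰, 3-term
   truncated NSLD profiles and headgroup-orientation medians.

A forward generator (`lamella.synthetic`) produces every input with a
machine-readable ground-truth sidecar, so the entire chain is validated
in closed loop.  See `docs/methods.md` for the model details, defaults
and limitations.

## Worked example

```python
from lamella.datamodel import DiffractionCondition
from lamella.synthetic import BilayerModelParams, make_sld_model, gen_peak_table
from lamella.reduction import structure_factors
from lamella.nsld import assign_phases, synthesize_profile, fit_bilayer_thickness

cond = DiffractionCondition(wavelength=4.47, mu=5.0, t=50.0,
                            temperature=323.15, relative_humidity=0.98,
                            d2o_fraction=0.08)
model = make_sld_model(BilayerModelParams(d=55.0, z_h=18.05))  # d_b = 36.1 Å
dataset, truth = gen_peak_table(model, cond, n_orders=4)

fset = structure_factors(dataset)
signed, ranking = assign_phases(fset)
profile = synthesize_profile(signed, n_points=1201)
geom = fit_bilayer_thickness(profile)
print(tuple(int(s) for s in signed.signs), round(geom.d_b, 2), round(geom.d_w, 2))
```

prints

```
(-1, -1, 1, -1) 35.98 19.02
```

— the canonical fluid-PC sign pattern, and the 36.1 Å generator
headgroup separation recovered to 0.12 Å through a 4-order truncation,
with the complementary water layer making up the 55 Å repeat.

The same pipeline is scriptable from the shell:

```bash
lamella --seed 3 --out run simulate --d 55 --d-b 36.1
lamella --out run reduce run/peaks.tsv
lamella --out run phase run/peaks.tsv
lamella --out run reconstruct run/peaks.tsv   # writes geometry.tsv + NSLD TSVs
```

(subcommands `forces`, `mechanics` and `mdprof` cover stages 4–6; all
tables are '#'-commented TSV).

## Acceptance script

`scripts/acceptance.py` regenerates the package's headline numbers from
scratch — the beam-theory rigidity scaling evaluated at the reference
fluid-phase thicknesses, the two noise-free diffraction closed loops at
the reference PC-fluid and DGTS-gel thicknesses, the Caillé/de Gennes
forward–inverse round trip at the reference PC mechanics, and the
full-scale Bragg-sheet recovery of the DGTS bending modulus — and
writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes a few minutes on one CPU; all randomness derives from
`--seed`.
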