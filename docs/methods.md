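# Methods

`lamella` analyses lamellar (smectic) stacks of lipid bilayers the way
solid-supported multilayer neutron diffraction experiments do: indexed
Bragg-peak intensities are reduced to structure factors, phased under
centrosymmetric constraints, synthesized into a neutron scattering-length
density (NSLD) profile, and converted into bilayer/water thicknesses,
hydration-force decay lengths and smectic mechanical moduli.  A forward
generator produces every input with known ground truth so each stage can
be validated in closed loop.

## Reduction

For a peak of order *n* at scattering angle 2θ with integrated intensity
*I_n*,

    |F_n|² = C_abs · C_Lor · I_n,
    C_abs  = α/(1 − e^(−α)),  α = 2µt/sin θ,
    C_Lor  = sin 2θ,

with µ the linear absorption coefficient (default 5 cm⁻¹) and *t* the dry
deposition thickness (default 50 µm — hydration-dependent thickness is
not modelled; the flag is recorded in output metadata).  The lamellar
period is *d* = nλ/(2 sin θ) per order; the per-dataset *d* is the
weighted mean over orders, with a logged warning when orders disagree by
more than 1% (mis-indexing or phase coexistence).  Counting errors
propagate first order; a missing error defaults to √I.

Relative humidity maps to osmotic pressure through the osmotic-stress
(Kelvin) relation Π = −(k_B T/v_w)·ln RH with v_w = 30 Å³ by default
(configurable).  The identical relation evaluated through the
Gibbs–Duhem route (below) is enforced by a cross-module test.

## Phase assignment

A centrosymmetric bilayer restricts phases to signs ν_n ∈ {±1}; the
profile is ρ(z) = (2/d)·Σ ν_n|F_n|cos(2πnz/d).  All 2^N vectors are
enumerated (N ≤ 8) and survivors must satisfy, at the ≈8% D2O
(water-matched) contrast:

1. global minimum within the central 10% of the period (hydrogen-rich
   terminal methyls; truncation ringing can displace it slightly off
   z = 0, which is why the window is not a point);
2. two symmetric global maxima with |z|/d ∈ [0.20, 0.48] (headgroups);
3. the unit-cell edge — the water-layer centre — well below those
   maxima (edge level ≤ 0.85 of the trough-to-peak range), since
   near-null-contrast water cannot rival the headgroup density.

Survivors are ranked by the contrast score max ρ − max(ρ(0), ρ(d/2)):
headgroup maxima must stand above *both* the methyl trough and the water
level.  Ranking by trough contrast alone turns out to prefer an
unphysical vector whose profile peaks at the cell edge for DPPC-like
4-order data; penalising the edge level fixes this without any tuned
weight.  Ties break toward fewer sign changes and are logged.

Limits worth knowing: the magnitudes of a profile with *no* headgroup
maxima (a bare methyl trough) can always be re-phased into a plausible
two-maximum profile, so headlessness is undetectable from magnitudes
alone; and signs of very weak high orders (|F_n| ≲ 10% of |F₁|) are
near-degenerate — choosing the wrong one moves the fitted thickness by
under 0.3 Å on our fixtures.  Phase search is only meaningful at the
low contrast; 100% D2O data are used for d-spacing only.

## Thickness extraction

The bilayer thickness d_b is the centre-to-centre headgroup distance
from a fit of mirrored Gaussians (shared amplitude and width, centres
±z_H) plus a constant baseline; d_b = 2 z_H and d_w = d − d_b with
δd_w = √(δd² + δd_b²).

Because a profile synthesized from N orders carries no content beyond
order N, fitting raw Gaussians to it inherits the truncation ringing as
a centre bias (measured: +0.7 to +1.7 Å at N = 4 for realistic
profiles).  The fitted model is therefore *band-limited to the same
orders* before comparison — its exact cosine coefficients are damped
Gaussians — which removes the bias (< 0.3 Å across all reference
fixtures at N = 4, 5).  For continuous profiles (``n_orders_used`` = 0)
the raw Gaussian fit is used and is exact on noise-free Gaussian-pair
inputs.

Uncertainty: the RMS residual between fit and profile over the
headgroup neighbourhood (|‖z|−z_H| ≤ 2w) is reported as-is (SLD units)
and also mapped to a length through the fitted peak curvature |ρ''| =
A/w²: a height mismatch δρ displaces a peak centre by δz ≈ √(2δρ/|ρ''|),
so δd_b = 2δz.  This keeps the profile-residual statistic while giving
a propagatable length error.

## Hydration repulsion

Pressure–distance data follow Π = Π₀·e^(−d_w/λ_w).  The fit is linear
least squares in ln Π (the data span decades); δd_w, when present, is
propagated to ln Π through the local slope and the fit reweighted once.
Fewer than three usable points raise an error instructing the caller to
report *no* decay length — an unconstrained two-point "fit" is worse
than none.  Phases are never mixed in one fit.  The beam-theory scaling
κ_new = κ_ref·(d_b,new/d_b,ref)³ treats the bilayer as a homogeneous
plate.

## Smectic mechanics and Bragg sheets

Closed forms: η = π k_B T/(2d²√(κB/d)) (Caillé) and Λ = √(κ/(Bd))
(de Gennes), inverted exactly as B = π k_B T/(2d²Λη), κ = Λ²Bd.
k_B = 1.380649×10⁻²³ J/K; κ is reported in k_B T at the dataset
temperature.

The fluctuation simulator samples the exact Gaussian ensemble of the
discrete smectic Hamiltonian

    H = Σ_n ∫d²r [ B/(2d)·(u_{n+1} − u_n)² + (κ/2)(∇²u_n)² ]

by spectral decomposition: in-plane Fourier modes × eigenmodes of the
inter-layer coupling matrix (periodic across the stack by default;
substrate-pinned Dirichlet walls as an option), each mode drawn with
variance k_B T/eigenvalue.  All q_∥ = 0 modes (uniform layer
translations) are pinned to zero, and the same modes are excluded from
the closed-form variance oracle the sampler is tested against
(equipartition per mode, χ²-style bounds).

Scattering is kinematic: the density Σ_n f(z − nd − u_n) gives, around
sheet ℓ,

    I_ℓ(δ, q_∥) = |f̂(2πℓ/d)|² ⟨|Σ_n e^(iδnd) F₂D[e^(i q_z u_n)]|²⟩,

evaluated at the stack's N discrete q_z offsets δ (one layer-index DFT
yields the whole sheet zone), radially averaged over q_∥.  The map is
therefore 2D, the discrete analogue of an (Ω, 2θ) scan.  This matters:
at the *exact* sheet centre only the conformal (uniform-across-layers)
bending mode scatters at linear order, so a centre-only map is blind to
Λ; the q_z-resolved zone restores the bending/compression crossover at
q* = √(2/(Λd)) that identifies Λ.  A finite lateral cut-off R damps
inter-layer cross terms by e^(−r/R) in real space; it is labelled
empirical, defaults to ∞, and is not fitted by default.

Mechanics recovery uses two observables: the specular/diffuse ratio of
the second sheet's central row (η-dominated through the fluctuation
amplitude) and the q_∥ decay of the q_z-integrated first sheet with the
specular bin excluded (Λ-dominated through the crossover).  A log-spaced
(η, Λ) grid is forward-simulated with common random numbers — one fixed
internal seed makes the least-squares score surface smooth — and a
Nelder–Mead refinement follows; (κ, B) come from the closed-form
inversion.  Default fixture: 16 layers, 64×64 lateral grid of 640 Å,
200 seed averages for data and 192 for the fit — sized so a full
closed-loop recovery runs in a few minutes on one CPU.  At this scale
the recovery of κ = 22 k_BT truth lands within ±1.5 k_BT across seeds;
the Monte-Carlo spread of the data maps, not the optimiser, limits the
precision.

## Density-profile analytics

Operating on tabular z-resolved component densities over one repeat
(trajectory reduction is upstream and out of scope):

* water polarization m_w(z) = ∫ρ_w^(c) dz′ by cumulative trapezoid on
  *water-centered* profiles (m_w closes to zero for neutral water);
* leaflet dipole M_z = A_l·∫m_l dz on *bilayer-centered* profiles, per
  lipid in e·Å (equals −A_l∫zρ dz for a neutral leaflet; gauge-origin
  independent).  Centering is an explicit flag — silent recentering is
  forbidden because both conventions are in routine use;
* Gibbs–Duhem pressure Π = −(µ − µ₀)k_BT/v_w⁰ with µ in k_B T and v_w⁰
  in Å³ (default 30 Å³, configurable — the reference value is not
  printed anywhere authoritative);
* truncated-Fourier NSLD: component mass densities × scattering lengths
  (bundled table of standard coherent b values) → cosine coefficients →
  keep 3 terms (the typical experimental order count) → resynthesize
  and fit d_b, so simulation-derived profiles are band-limited exactly
  the way diffraction band-limits data.  Constant repeat shifts
  Δd = 3 Å (fluid) / 8 Å (gel) are applied only when the comparison
  flag is set, compensating the united-atom underestimate of chain–chain
  repulsion;
* headgroup orientation: median over the pooled vector collection of
  the angle to the membrane normal (90° = in-plane); vectors are
  auto-normalized with a warning.

Neutrality tolerance before polarization integrals: |net charge| <
10⁻⁶ e/Å² — beyond it the code warns and proceeds.

## Synthetic world

The bilayer SLD generator is a water slab (SLD linear in the D2O
fraction between −0.56 and 6.36 ×10⁻⁶ Å⁻², matched near 8%), a chain
plateau at −0.4, two headgroup Gaussians (amplitude 2.0, width 3 Å —
the standard headgroup-peak width of lamellar modelling) at ±z_H, and a
methyl trough at the mid-plane; the water edge sits 7 Å beyond the
headgroup centres with 3 Å Gaussian smoothing, fluid-interface-like.
Its cosine coefficients are closed-form, so Fourier round-trip tests are
exact.  Intensity noise is Gaussian per order (counting-like), pressure
noise log-normal (humidity control is multiplicative); both default to
the values used in the closed-loop tests (0 and 5%).  Every generator
writes a `.truth.tsv` sidecar and all randomness flows from explicit
seeds.

What the generators do **not** emulate: detector geometry and Ω-scan
step artifacts, multiple scattering, absorption dips near Ω ≈ 0 and
Ω ≈ 2θ, asymmetric bilayers, and real-water structural detail.  A green
closed-loop test therefore establishes the *analysis chain's*
correctness on data obeying the stated model, not instrument-level
fidelity.

## Known limitations

* Phase search cannot detect a headgroup-free profile (fundamental
  magnitude/phase ambiguity) and may mis-assign signs of very weak high
  orders; both situations are diagnosable from the returned ranking.
* The 3-order truncation of sharp density features carries ~1 Å
  thickness offsets even with the band-limited fit, because the fit
  model (Gaussian pair + constant) is not the true profile family.
* The kinematic treatment has no specular-region correction; measured
  first-sheet specular data violate it and are excluded from fitting,
  as is standard.
* R is an empirical damping with no claim to the exact meaning it has
  in dynamical treatments; it is off (∞) by default.
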