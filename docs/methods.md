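# Methods

This note records the models implemented in `flashxtal`, their assumptions
and calibrations, the numerical choices, and what the test suite does and
does not demonstrate.

## Units and conventions

Photon and electron energies in eV, atomic lengths in Å, attenuation in
cm⁻¹, cross sections in barn (10⁻²⁴ cm²), dose in Gy (J/kg), time in fs,
fluence in J/cm². Scattering vectors use |q| = 2 sinθ/λ = 1/d, structure
factors the phase convention F(q) = Σ f_i exp(+2πi q·x_i), so every
Debye–Waller exponent reads 4π²q²σ². σ always denotes the **per-axis (1D)**
RMS displacement; the 3D RMS is √3·σ. With this pair of conventions the
displacement low-pass filter exp(−4π²q²σ²) falls to 1/e² at resolution
d ≈ 2πσ·√2, matching the usual "low-pass filter at a resolution of 2πσ"
description. All constants (N_A, r_e, m_e, hc = 12398.4 eV·Å, eV→J,
barn→cm²) live in `flashxtal.constants`.

## Element data and cross sections

`data/elements.csv` bundles, for H, C, N, O, Mg, P, S, Ca, Mn, Fe: atomic
mass, K-edge energy, and the K-hole Auger lifetimes (C 10, N 7.1, O 5.0,
S 1.3, Mn 0.62, Fe 0.55 fs). The carbon K edge is taken at 284.0 eV.

`data/xsections.csv` holds photoabsorption (σ_A) and elastic (σ_S) cross
sections on a ~64-point log grid over 0.2–12 keV, with extra nodes
bracketing each K edge (±0.5%) so interpolation never smooths across an
edge. Interpolation between nodes is log-log linear, which is monotone
between nodes by construction; queries outside the grid raise.

The σ_A energy dependence comes from the Cromer–Liberman f″ tabulation
(via gemmi), converted through σ_A = 2 r_e λ f″. Cromer–Liberman runs a few
to ten per cent below the LBNL/Henke tabulation for light elements in this
range, so each element's curve carries a constant scale factor pinned to
Henke-traceable reference values at 6 keV; Mn and Fe, whose K edges fall
between 6 and 8 keV, get a second factor above the edge pinned at 8 keV. A
final common renormalization fixes the mass attenuation of the reference
protein composition (H₅₀C₃₀N₉O₁₀S₁, 1.35 g/cm³) to the tabulated
32.5 cm⁻¹ at 6 keV, since the individual printed-precision pins accumulate
~2% of rounding. Hydrogen (below the Cromer–Liberman validity range) uses a
hydrogenic Stobbe-like power law; it contributes < 0.1% to any compound
attenuation here. The bundled table is the package's single source of
truth; different standard tabulations disagree at the few-per-cent level
and no attempt is made to arbitrate beyond the pinning above.
`scripts/build_xsection_table.py` regenerates both files.

σ_S integrates r_e²|f₀(q)|² over the full sphere using International Tables
sum-of-Gaussians form factors, with **no polarization factor** — consistent
with the intensity formula below, which likewise omits it.

## Dosimetry

Flat-top pulses only: constant intensity for a duration T, so dose rate
R = D/T exactly. Thin-sample model: D = I₀·μ/ρ with no depth attenuation;
`dose()` warns when a supplied thickness exceeds a tenth of the absorption
length. Fractional stoichiometric counts are allowed (solvent-averaged
compositions). Built-in materials: the average protein above, water, pure
carbon (2.0 g/cm³, a density that no bundled example actually uses), and a
photosystem-I crystal composition
(H₁₄₁₄₀₀O₅₇₃₀₀C₁₆₉₀₀N₃₃₁₀S₈₉Fe₁₂Mg₉₆P₃Ca₁, 1.077 g/cm³). Heat capacity is
a user input with water's 4800 J kg⁻¹K⁻¹ as the only built-in.

## Ionization dynamics

The cascade model has three parameters: ε_ion = 21 eV deposited per
ionization (the empirical large-time limit for light-element organic
matter), a saturating-exponential time constant τ = 10 fs, and a core-shell
fraction of 10/240. The average-ionization trajectory is an energy-budget
model: the supply rate R·m̄/(N_A·ε_ion) convolved with the cascade response
gives

    z(t) = (R m̄ / N_A ε_ion) · [t − τ(1 − e^(−t/τ))],

capped at the mean electron count Z̄ (3.89 for the average protein);
w(t) = 1 − z/Z̄. To this model's accuracy z(t) depends only on dose rate
and composition, not photon energy. This is a deliberate stand-in for full
plasma-kinetics calculations: it reproduces the published anchor points
(one electron per atom at ~300 MGy for a 100 fs pulse; valence-shell
stripping at ~1 GGy; full transparency per the power law below) but not the
detailed curve shapes, which depend on continuum lowering and recombination
that are out of scope.

The transparency time is a separate anchored power law,
t_tr = 3 fs · (R / 60 GGy fs⁻¹)^(−2/3), reproducing the published ~60 fs at
0.6 GGy/fs to within ~8%.

Electron trapping uses a uniformly charged sphere with the electron
launched from the surface (the weaker bound; the geometry is otherwise
unconstrained): trapping at e·Q/(4πε₀R_sphere) = E_kin. For an 8 nm protein
particle and 6 keV electrons this gives a threshold of ~0.56 net charges
per atom — order unity, consistent with the published claim that unit
average ionization traps such electrons, though the published statement
evidently assumes a different charge profile.

Expected photoionization counts are deterministic expectations
(atoms × σ_A × fluence); a seeded Poisson sampler provides stochastic
realizations. The worked 1 μm³/1 MGy example reproduces the published
per-element counts to ~11% when fed the published rounded inputs
(10¹¹ atoms, 4×10⁸ photons/μm²); the published "≈50 000 scattered photons"
is a factor ~2 above what the form-factor-integrated σ_S gives and is not
asserted anywhere.

## Atomic motion

RMS displacement follows σ(t) = C·R^α·t^β. Default exponents α = 1/2,
β = 3/2 (preset `sec3b`, the plasma-simulation scalings); an alternative
preset `sec5` (α = 1/3, β = 4/3, giving turn-off ∝ R^(−1/4)) matches the
exponents used in the wavelength-scaling argument — the literature states
both sets, and they are not mutually consistent, so both ship as named
presets. The amplitude C is calibrated so σ = 1 Å at the end of a 50 fs
pulse at 50 MGy/fs — the toy-crystal explosion scenario — because no
absolute (σ, t, R) triple is published; C is a first-class parameter.

Turn-off time solves σ(t_off) = 1/(2πq):
t_off = [1/(2πq·C·R^α)]^(1/β). The cutoff convention σ_c = 1/(2πq) is
chosen over the dimensionally inconsistent alternative "σ exceeding 2π/q".
Effective dose is R·min(t_off, t_tr): slope 2/3 in log R while motion
gates, bending to 1/3 when transparency binds. A boolean helper implements
the observability criterion for correlated (directed) motion: its
displacement must exceed 2π·σ(t) — about six times the diffusive RMS.

## Diffraction model

I(q) = (photons/area)·r_e²·ΔΩ·|F(q)|², no polarization factor. Toy crystals
are orthorhombic with an explicit motif; patterns are evaluated on explicit
q-grids (planar sections or 3D boxes), with |q| ≤ 2/λ enforced.

Disorder is random and independent per atom: isotropic Gaussian
displacements (per-axis σ) and a binary ionization mixture (fraction x
carries a scattering deficit Δf). The expected intensity splits exactly
into the coherent ("Bragg") term |Σ f̄ᵢ e^(2πiq·x)|²·e^(−4π²q²σ²) and the
incoherent ("diffuse") variance term Σ(⟨f²⟩ − f̄²e^(−4π²q²σ²)). Ionized
atoms scatter in proportion to their remaining bound electrons — a low-q
approximation valid below ~1.7 Å resolution, where the shape change of
core-ionized form factors becomes significant.

Pulse integration uses the midpoint rule over n_steps (default 32) with
σ(t) and w(t) from the trajectories; the binary mixture uses x(t) = 1 − w(t)
against fully stripped atoms so the mean factor is f₀·w(t) and the Bragg
term integrates to g(q,T)·|F₀|². Displacements and ionization states are
drawn independently per time step and per realization (damage correlation
times are short compared with the pulse). Monte-Carlo realizations use one
root seed with deterministically spawned child streams: outputs are
bit-reproducible given the seed.

Peak/background separation integrates counts in a box of half-width 1/(N·a)
around each predicted node and subtracts the median of the surrounding
annulus; it requires ≥5 grid nodes per 1/(N·a) and errors out otherwise.
For small crystals (N ≈ 3–5) shape-transform side lobes outside the peak
boxes put a floor under the "diffuse" map of order 10% of the peak height
near peaks — an honest feature of nanocrystal patterns, not a separation
failure; the background-subtracted **peak** counts still recover
g(q,T)·|F₀|² to within a few per cent.

The explosion fixture is a 5×5×5 crystal of 25 Å cubic cells with 8
carbon pseudo-atoms per cell at fixed seeded fractional positions (1000
atoms; the published simulation does not specify its motif, so this one is
an invention and only qualitative behaviours are comparable), driven by the
50 MGy/fs × 50 fs trajectories so σ(T) = 1 Å exactly.

## Numerical choices

- Energy-conservation checks (Bragg loss rerouted to diffuse) are exact
  only over all reciprocal space; over a finite q-box, motif cross terms
  leave quadrature residuals of several per cent regardless of grid
  fineness. The invariant is therefore verified on a one-atom-per-cell
  crystal over a box commensurate with the reciprocal lattice, where
  cancellation is cell-by-cell and the residual stays below 1%.
- Grid aliasing: discrete q-sampling with spacing δ aliases pair
  separations at 1/δ; sampling always keeps 1/δ larger than the crystal
  extent.
- The step-gate limit g = t_off/T is reproduced by the trapezoid
  integration to ~1/n_steps; tests use fine grids accordingly.
- Problem sizes in the test suite (3×3×3 crystals, a few hundred atoms,
  10²–10³ Monte-Carlo realizations, ≤ 226² planar grids) were chosen to
  keep ensemble standard errors a factor ≳3 below the tolerances being
  checked while the whole suite runs in well under a minute.

## Wavelength scaling

Total-signal exponents at fixed pulse energy: available photons λ¹, merged
photons per reflection λ³, gate time λ^(−3/4) (motion-gated) or λ^(−2)
(ionization-gated) — totals 13/4 and 2. The λ³ dose scaling assumed in the
gate-time derivation fails near absorption edges; compositions with a K
edge within ±200 eV of the working energy are flagged. The regime
boundaries are ~100 MGy/fs (below: motion-gated) and ~1 GGy/fs (above:
ionization-gated); between them both processes matter and results carry a
"transition" flag with motion-gated exponents. The merged (λ³) convention
is reported throughout; per-still scalings differ by one power of λ.

## What the tests show — and don't

Dosimetry values are checked against published worked examples at their
printed precision (the per-element dose table to within 5%, limited by the
printed rounding of the pins). The dynamics models are checked against
their calibration anchors and scaling exponents — by construction they
cannot validate the underlying plasma physics. Monte-Carlo/analytic
agreement (3 standard errors) validates the disorder algebra, not the
realism of the independence assumptions. The synthetic toy crystals lack
solvent, inherent static disorder, mosaicity and shape variety; passing
pattern tests therefore demonstrates the gating model's internal
consistency, not agreement with measured SFX data.

## Known limitations

No depth-resolved attenuation or beam profiles; no electron
capture/recombination, continuum lowering, or fluorescence competition; no
spatially resolved cascades; no ionized-atom form-factor shapes (quantum
calculations out of scope); no Ewald-sphere partiality, detector noise, or
merging; heavy-atom bleaching curves are not modelled (the
bound-electron-count scaling is the hook where such a model would attach).
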