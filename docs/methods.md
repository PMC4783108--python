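# Methods

## Physical model

The system is a single-component suspension of γ-crystallins treated as a
hard-sphere crowder fluid in which a tagged dimerization 2 R ⇌ P occurs.
All lengths are **diameters**: reactant σ = 3.6 nm, crowder σ₀ = σ/ς,
product cap σp. The product is a spherocylinder whose volume equals that
of its two parent spheres, πσ³/3, which fixes σp = σ(4/(3λ+2))^{1/3} and
L = λσp; λ = 0 gives the volume-conserving sphere of diameter 2^{1/3}σ.

The steric part of every activity coefficient is the SPT insertion work

    ln γˢᵗ(φ; ς, λ) = −ln(1−φ) + A₁x + A₂x² + A₃x³,  x = φ/(1−φ),

with A₁ = ς³+3ς²+3ς+1.5λ(ς²+2ς+1), A₂ = 3ς³+4.5ς²+4.5λ(ς²+ς),
A₃ = 3ς³+4.5λς². Two consistency anchors pin this form: for ς = 1, λ = 0
the coefficients are (7, 7.5, 3), and the dilute slope 1+A₁ equals the
sphere excluded volume factor (1+ς)³. (Note A₁ itself does *not* contain
the constant term of (1+ς)³; that unit is carried by −ln(1−φ).)

Attraction enters through one of two chemical terms:

* **TPM.** First-order perturbation with an orientational average:
  ln γᶜʰ = −ρεS[δr + (g₀ᵐᵃˣ−1)θ]. The bracket groups the bare
  attraction-range term δr with the contact-correlation correction
  (g₀ᵐᵃˣ−1)θ; this grouping is asserted by a dedicated unit test because
  it determines every downstream number (with the alternative grouping
  −ρεS·δr·g₀ᵐᵃˣ·θ the dimensions would not even close). Species
  surface areas are S_r = πσ² and S_p = πσp²(1+λ).
* **CBM.** Langmuir-like binding of crowders at n_s nonspecific sites:
  ln γᶜʰ = −n_s ln(1 + K(γˢᵖγ_bˢᵗ/γ_complexˢᵗ)φ). Because reactants and
  crowders are the same protein, γ_bˢᵗ = γ_rˢᵗ and the reactant–crowder
  complex has the steric coefficient of the 2^{1/3}σ volume-conserving
  sphere (identical to γ_pˢᵗ at λ = 0). The product's chemical term is
  not uniquely determined by the modelling framework; we extend it
  area-proportionally — the product carries n_p = αS_p sites with
  α = n_s/S_r constant, and its crowder complex is the volume-conserving
  sphere of volume v_p + v_b (3^{1/3}σ at ς = 1). A 'conserved' switch
  (n_p = 2n_s − 2, two sites consumed by the bond) is exposed for
  sensitivity analysis. Complex geometries for ς ≠ 1 generalize to
  volume-conserving spheres of the actual combined volume.

The crowding factor ln Γ = 2 ln γ_r − ln γ_p needs no absolute association
constants: K and K₀ enter only through this ratio.

Osmotic pressure comes from the **reactant** (monomer) activity
coefficient — the measured suspension is monomeric — via
Π = RT[ρ + ∫₀^ρ ρ′(d ln γ/dρ′)dρ′]. With no attraction this reproduces the
SPT hard-sphere equation of state Z = (1+φ+φ²)/(1−φ)³ to machine
precision, which the tests use as an independent oracle, along with the
exact dilute virial B₂ = 4v.

## Parameters, units, defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| σ | monomer diameter | 3.6 | nm |
| ς | σ/σ₀ | 1.0 | – |
| λ | product asphericity | 0.0 | – |
| M | molar mass (c ↔ φ conversion) | 21 000 | g/mol |
| T | temperature | 298.15 | K |
| δr | TPM attraction range | 0.2 σ | nm |
| θ | contact-peak decay range | (2^{1/6}−1)σ/2 | nm |
| ε | TPM well depth | fitted | k_BT |
| n_s, K | CBM sites / binding constant | fitted | –, – |

λ defaults to 0 (spherical dimer); NMR-derived estimates for crystallin
dimers are near λ = 0.3, and λ is configurable everywhere. M = 21 kDa is a
typical γ-crystallin mass, used only to map mg/mL onto packing fraction
(400 mg/mL ↦ φ ≈ 0.28); it is a config field, not a fitted quantity.
Internally pressures are kept as number density × k_BT and exported in
kPa; the CSV interface is `c_mg_per_mL, Pi_kPa` with `#` comments.

Constructing a state with φ > 0.4 emits a warning: the theory is
pairwise-additive and unreliable where many-body packing matters.

## Numerical choices

* **Quadrature.** Single-point pressures use adaptive quadrature
  (`scipy.integrate.quad`, relative tolerance 1e-11) of the *analytic*
  d ln γ/dρ (chain rule through φ = ρπσ₀³/6); finite differences exist
  only as a test oracle. Curve evaluations for fitting use 64-node
  Gauss–Legendre per target density, vectorized; the integrand is smooth,
  and the two routes agree to 1e-10 relative in the tests.
* **Optimization.** All fits are 1-D bounded scalar minimizations (Brent,
  `xatol = 1e-10`), ε ∈ [0, 30], K ∈ [0, 10³]; deterministic, no
  restarts. An argmin within 1e-6 of the interval edge is flagged
  `at_bound` (degenerate fit) rather than silently returned. The loss is
  the unweighted sum of squared pressure residuals.
* **Root solving.** Compensation crossovers use Brent with a mandatory
  sign-change bracket and tolerance ~1e-12; a missing sign change raises
  with the bracket-end values of ln Γ. For the TPM, ln Γ is *exactly*
  linear in ε, so a closed form
  ε_c = [2lnγ_rˢᵗ − lnγ_pˢᵗ]/(ρ(2S_r − S_p)[δr + (g₀ᵐᵃˣ−1)θ])
  exists and is cross-checked against the root finder; the degenerate
  case 2S_r = S_p (reached near λ ≈ 2.78) raises rather than divides by
  zero.
* **Model equivalence.** The K(ε) map (equal reactant chemical activity in
  both models) is solved by Brent; the CBM side is strictly monotone in
  K, so the root is unique, and it is linear in ε at low density.
* **Seeds.** Every stochastic study takes an explicit integer seed
  (`numpy.random.default_rng`); the documented default for Monte-Carlo
  studies is 20160308.

## Synthetic data

The generator emulates membrane-osmometry isotherms: 16 concentrations on
[25, 400] mg/mL (the dilute limb through the physiological 200–400 mg/mL
regime) evaluated through the chosen model, with multiplicative Gaussian
noise of 5 % relative standard deviation by default (osmometry error
scales with signal; an additive option exists). With attraction at the
strengths relevant to crystallins the curves lie below the ideal law ρRT,
as real crystallin osmometry does. What the generator does **not**
emulate: instrument-specific heteroscedasticity beyond the multiplicative
form, concentration-measurement error (the x-axis is exact), membrane
artifacts, and any real digitized data. Passing recovery tests therefore
demonstrates the estimators' correctness and stability under the stated
noise model, not agreement with experiment.

With zero noise the generator returns the exact model curve, making it the
inverse fixture of the fitting layer: noiseless recovery is exact to 1e-6
relative, and over 200 seeded 5 %-noise replicates the mean recovered ε
and K are biased by less than 2 %.

## Design choices on genuinely open points

* The activity coefficient entering the pressure integral is the
  monomer's; the alternative (a reacting mixture) would require an
  association-equilibrium closure the framework deliberately avoids.
* The product's CBM chemical term (see above) is the largest modelling
  freedom; it shifts the CBM compensation packing fraction φ\* within
  roughly ±0.1, which is why that quantity should be read as "φ\* ≈ 0.2"
  rather than a third decimal.
* λ-sweeps and ς-sweeps change the *product* geometry while keeping
  volume conservation; the steric ln Γ is nearly λ-independent (the cap
  shrinks as the rod grows, and the two effects almost cancel — the
  steric insertion work along this family is not even monotone in λ),
  whereas with attraction ln Γ grows with λ because the product's surface
  area, hence its chemical stabilization, grows.
* Fit sizes: the ideal-matching fit uses an 80-point uniform grid on
  (0, 400] mg/mL; Monte-Carlo recovery uses 200 replicates of 16-point
  isotherms. These sizes make all analyses run in seconds while leaving
  quadrature and optimizer error far below the noise scale.

## Known limitations

* Two-body SPT: no many-body depletion, no phase separation or
  crystallization; quantitatively doubtful above φ ≈ 0.4.
* Monodisperse crowders only (a single ς at a time); no charge effects,
  Donnan equilibria or solvent structure.
* The TPM's orientational averaging washes out patchiness; the CBM's
  sites are structureless. Neither resolves real binding geometry.
* ε, K and n_s are effective parameters of the coarse-grained models;
  they are not transferable to other proteins without refitting.
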