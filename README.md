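# crowdspt

Scaled-particle-theory (SPT) analysis of protein association equilibria in
crowded media, built around the dimerization of eye-lens γ-crystallins.

Uncontrolled crystallin aggregation scatters light and causes cataract, and
whether the crowded cytoplasm of a lens fiber cell pushes crystallins toward
or away from association depends on a competition: excluded-volume
(depletion) effects promote association, while protein–protein attraction to
the surrounding crowders suppresses it. `crowdspt` quantifies this balance
for coarse-grained colloidal models of a dense protein solution, for
theorists and modellers who want activity coefficients, osmotic-pressure
isotherms and association-equilibrium shifts from analytic statistical
mechanics rather than simulation.

## The model

A dimerization 2 R ⇌ P takes place in a fluid of hard-sphere crowders of
diameter σ₀ at packing fraction φ. Reactants are spheres of diameter
σ = 3.6 nm (size ratio ς = σ/σ₀); the product is a volume-conserving
spherocylinder with asphericity λ = L/σp and cap diameter
σp = σ(4/(3λ+2))^{1/3}. The crowding factor

    ln Γ = ln(K/K₀) = 2 ln γ_r − ln γ_p

compares the association constant in the crowd (K) and at infinite dilution
(K₀) through the species' activity coefficients, each split as
ln γ = ln γˢᵗ + ln γᶜʰ:

* **Steric (SPT):** ln γˢᵗ = −ln(1−φ) + A₁x + A₂x² + A₃x³ with
  x = φ/(1−φ) and shape coefficients A₁..A₃(ς, λ); for ς = 1, λ = 0 they
  are (7, 7.5, 3).
* **TPM** (thermodynamic perturbation model): orientationally averaged
  attraction of depth ε (k_BT) over range δr = 0.2σ,
  ln γᶜʰ = −ρεS[δr + (g₀ᵐᵃˣ−1)θ], with the Carnahan–Starling contact
  value g₀ᵐᵃˣ = (1−φ/2)/(1−φ)³ and decay range θ = (2^{1/6}−1)σ/2.
* **CBM** (chemical binding model): reversible binding of crowders at n_s
  surface sites with constant K,
  ln γᶜʰ = −n_s ln(1 + K (γ_rˢᵗγ_bˢᵗ/γ_{r,b}ˢᵗ) φ).

The osmotic pressure follows by thermodynamic integration,
Π = RT[ρ + ∫₀^ρ ρ′ (d ln γ/dρ′) dρ′], which the package evaluates with
analytic derivatives. On top sit least-squares fitters (ε, or K on a grid
of n_s), entropy–enthalpy compensation solvers (the ε_c or φ\* at which
ln Γ = 0), sweep tables for curve families, and a seeded synthetic-isotherm
generator that stands in for osmometry data.

## Worked example

Generate a noisy synthetic isotherm from the TPM at ε = 13.9 k_BT (16
points, 25–400 mg/mL, 5 % multiplicative noise), refit ε, and locate both
compensation points:

```python
import crowdspt as cs

cfg = cs.ModelConfig()          # sigma = 3.6 nm, M = 21 kDa, T = 298.15 K

iso = cs.generate_isotherm(cs.GeneratorSpec(
    model="tpm", parameters={"epsilon": 13.9}, noise_sd=0.05, seed=42,
    config=cfg))
fit = cs.fit_tpm_epsilon(iso, cfg)
print(fit.parameters)                     # {'epsilon': 13.894956390612897}

print(cs.crossover_epsilon(0.2, cfg))     # 9.866512326332009
print(cs.crossover_phi_cbm(cs.CBMParams.for_crystallin(2.0, 10.6), cfg))
                                          # 0.22791849129083183
```

The refitted ε = 13.89 recovers the generating 13.9 to 0.04 % despite the
noise. The second number is the critical TPM well depth at φ = 0.2: below
≈ 9.87 k_BT depletion wins (ln Γ > 0, crowding promotes dimerization), above
it attraction wins. The third is the packing fraction at which the CBM with
two binding sites and K = 10.6 crosses ln Γ = 0 (φ\* ≈ 0.23): more dilute
lens tissue disfavors association, denser tissue favors it. For scale,
Π(200 mg/mL; ε = 13.9) = 10.08 kPa versus the ideal-law 23.61 kPa — the
attraction roughly halves the osmotic pressure in the physiological range.

The same analyses are available from the shell:

```bash
crowdspt simulate --model tpm --epsilon 13.9 --noise-sd 0 -o iso.csv
crowdspt fit --model tpm iso.csv
crowdspt crossover --model tpm --phi 0.2
crowdspt curves --parameter asphericity --grid 0 0.2 0.4 --model tpm -o curves.csv
```

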