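"""Attractive ("chemical") activity contributions and the crowding factor.

Two coarse-grained treatments of protein–protein attraction sit on top of
the hard-body SPT reference:

* **TPM** (thermodynamic perturbation model): an orientationally averaged
  square-well-like attraction of depth ε (k_B T) acting over a range δr
  from the surface, first-order perturbation on the hard-sphere fluid:

      ln γ^ch = -ρ ε S [δr + (g0max - 1) θ],

  with S the species surface area, g0max the Carnahan–Starling contact
  value and θ the decay range of the contact peak.

* **CBM** (chemical binding model): attraction as reversible binding of
  crowders at n_s nonspecific surface sites with binding constant K:

      ln γ^ch = -n_s ln(1 + K (γ^st γ_b^st / γ_{complex}^st) φ),

  where γ_b^st is the crowder's steric activity and γ_{complex}^st that of
  the species–crowder complex.

The crowding factor Γ = K_assoc/K_assoc,0 measures how the crowded medium
shifts the dimerization equilibrium 2 R ⇌ P:

      ln Γ = 2 ln γ_r - ln γ_p.

Positive ln Γ means crowding promotes association (depletion dominates);
negative means the attraction-mediated suppression wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .constants import SIGMA_CRYSTALLIN
from .geometry import (
    SolutionState,
    SpeciesGeometry,
    contact_value_g0max,
    equivalent_sphere,
    sphere_geometry,
    steric_log_activity,
)

__all__ = [
    "TPMParams",
    "CBMParams",
    "CrowdingResult",
    "tpm_chem_log_activity",
    "cbm_chem_log_activity",
    "total_log_activity",
    "crowding_factor",
    "model_equivalence_K_of_epsilon",
]

#: Decay-range prefactor of the contact peak, (2^(1/6) - 1)/2.
_THETA_FACTOR = (2.0 ** (1.0 / 6.0) - 1.0) / 2.0


@dataclass(frozen=True)
class TPMParams:
    """Thermodynamic-perturbation-model parameters.

    Attributes
    ----------
    epsilon
        Orientationally averaged well depth ε ≥ 0, in k_B T.
    attraction_range
        δr, nm; default convention δr = 0.2 σ.
    decay_range
        θ = (2^(1/6) - 1) σ/2, nm.
    surface_area
        S of the species the chemical term applies to, nm²
        (πσ² for the spherical monomer).
    """

    epsilon: float
    attraction_range: float
    decay_range: float
    surface_area: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if min(self.attraction_range, self.decay_range, self.surface_area) <= 0:
            raise ValueError("ranges and surface area must be positive")

    @classmethod
    def for_crystallin(cls, epsilon: float, sigma: float = SIGMA_CRYSTALLIN) -> "TPMParams":
        """Defaults for a spherical monomer of diameter σ: δr = 0.2σ,
        θ = (2^(1/6)-1)σ/2, S = πσ²."""
        return cls(
            epsilon=epsilon,
            attraction_range=0.2 * sigma,
            decay_range=_THETA_FACTOR * sigma,
            surface_area=math.pi * sigma**2,
        )


@dataclass(frozen=True)
class CBMParams:
    """Chemical-binding-model parameters.

    Attributes
    ----------
    n_sites
        Number of binding sites n_s on the reactant monomer.
    binding_constant
        Dimensionless, temperature-dependent K ≥ 0.
    reference_surface_area
        Surface area of the monomer, nm²; the temperature-independent site
        density is α = n_s / S_monomer, and other species carry n = α·S
        sites under the default area-proportional rule.
    product_site_rule
        'area' (n_p = α S_p, default) or 'conserved' (n_p = 2 n_s - 2,
        two sites lost to the bond).
    """

    n_sites: float
    binding_constant: float
    reference_surface_area: float
    product_site_rule: str = "area"

    def __post_init__(self) -> None:
        if self.n_sites < 0 or self.binding_constant < 0:
            raise ValueError("n_sites and binding_constant must be non-negative")
        if self.reference_surface_area <= 0:
            raise ValueError("reference_surface_area must be positive")
        if self.product_site_rule not in ("area", "conserved"):
            raise ValueError("product_site_rule must be 'area' or 'conserved'")

    @classmethod
    def for_crystallin(
        cls,
        n_sites: float,
        binding_constant: float,
        sigma: float = SIGMA_CRYSTALLIN,
        product_site_rule: str = "area",
    ) -> "CBMParams":
        return cls(n_sites, binding_constant, math.pi * sigma**2, product_site_rule)

    @property
    def site_density(self) -> float:
        """α = n_s / S_monomer, nm⁻²."""
        return self.n_sites / self.reference_surface_area

    def sites_for(self, geom: SpeciesGeometry) -> float:
        """Number of binding sites on a species of the given geometry."""
        n = self.site_density * geom.surface_area
        if self.product_site_rule == "conserved" and not math.isclose(
            geom.surface_area, self.reference_surface_area, rel_tol=1e-9
        ):
            return max(2.0 * self.n_sites - 2.0, 0.0)
        return n


@dataclass(frozen=True)
class CrowdingResult:
    """Log activities of reactant and product and the log crowding factor,
    ln Γ = 2 ln γ_r - ln γ_p."""

    log_activity_reactant: float
    log_activity_product: float

    @property
    def log_crowding_factor(self) -> float:
        return 2.0 * self.log_activity_reactant - self.log_activity_product


def tpm_chem_log_activity(params: TPMParams, state: SolutionState) -> float:
    """TPM chemical log activity, -ρ ε S [δr + (g0max - 1) θ]; always ≤ 0."""
    phi = state.packing_fraction
    rho = state.number_density
    bracket = params.attraction_range + (contact_value_g0max(phi) - 1.0) * params.decay_range
    return -rho * params.epsilon * params.surface_area * bracket


def cbm_chem_log_activity(
    params: CBMParams,
    species_n_sites: float,
    state: SolutionState,
    steric_triplet: tuple[float, float, float],
) -> float:
    """CBM chemical log activity of one species.

    ``steric_triplet`` = (ln γ_species^st, ln γ_crowder^st, ln γ_complex^st);
    the term is -n ln(1 + K exp(lnγ_sp + lnγ_b - lnγ_complex) φ) ≤ 0 and
    vanishes when K = 0 or φ = 0.
    """
    if species_n_sites < 0:
        raise ValueError("species_n_sites must be non-negative")
    ln_sp, ln_b, ln_complex = steric_triplet
    phi = state.packing_fraction
    arg = params.binding_constant * math.exp(ln_sp + ln_b - ln_complex) * phi
    return -species_n_sites * math.log1p(arg)


def _cbm_companions(
    geom: SpeciesGeometry, state: SolutionState
) -> tuple[SpeciesGeometry, SpeciesGeometry]:
    """Crowder sphere and volume-conserving species–crowder complex."""
    crowder = sphere_geometry(state.crowder_diameter, state.crowder_diameter)
    complex_geom = equivalent_sphere(geom.volume + crowder.volume, state.crowder_diameter)
    return crowder, complex_geom


def total_log_activity(
    geom: SpeciesGeometry,
    state: SolutionState,
    model: TPMParams | CBMParams | None = None,
) -> float:
    """Total ln γ = ln γ^st + ln γ^ch of a species.

    ``model=None`` (or zero attraction) gives the pure hard-body result.
    For the TPM the species' own surface area replaces the one stored in
    the parameter set; for the CBM the crowder is a σ0 sphere and the bound
    complex a volume-conserving sphere.
    """
    ln_st = steric_log_activity(geom, state)
    if model is None:
        return ln_st
    if isinstance(model, TPMParams):
        species = replace(model, surface_area=geom.surface_area)
        return ln_st + tpm_chem_log_activity(species, state)
    if isinstance(model, CBMParams):
        crowder, complex_geom = _cbm_companions(geom, state)
        triplet = (
            ln_st,
            steric_log_activity(crowder, state),
            steric_log_activity(complex_geom, state),
        )
        return ln_st + cbm_chem_log_activity(model, model.sites_for(geom), state, triplet)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def crowding_factor(
    reactant_geom: SpeciesGeometry,
    product_geom: SpeciesGeometry,
    state: SolutionState,
    model: TPMParams | CBMParams | None = None,
) -> CrowdingResult:
    """Crowding factor for the dimerization 2 R ⇌ P.

    Returns the two total log activities and ln Γ = 2 ln γ_r - ln γ_p.
    With no attraction and equal-sized reactants/crowders ln Γ > 0 at any
    φ > 0: depletion always promotes association of hard particles.
    """
    ln_r = total_log_activity(reactant_geom, state, model)
    ln_p = total_log_activity(product_geom, state, model)
    return CrowdingResult(ln_r, ln_p)


def model_equivalence_K_of_epsilon(
    epsilon: float,
    state: SolutionState,
    n_sites: float = 2.0,
    reactant_geom: SpeciesGeometry | None = None,
    k_max: float = 1.0e9,
) -> float:
    """Binding constant K whose CBM chemical activity matches the TPM one.

    Solves, for the reactant monomer at the given state,

        ln γ^ch_TPM(ε) = ln γ^ch_CBM(K; n_s),

    for K.  The CBM side is strictly decreasing in K, so the root is
    unique.  ε = 0 maps to K = 0, and at low density K grows linearly
    with ε.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    sigma0 = state.crowder_diameter
    geom = reactant_geom if reactant_geom is not None else sphere_geometry(sigma0, sigma0)
    if epsilon == 0.0 or state.packing_fraction == 0.0:
        return 0.0

    sigma_eq = geom.cap_diameter
    target = tpm_chem_log_activity(TPMParams.for_crystallin(epsilon, sigma_eq), state)
    crowder, complex_geom = _cbm_companions(geom, state)
    triplet = (
        steric_log_activity(geom, state),
        steric_log_activity(crowder, state),
        steric_log_activity(complex_geom, state),
    )

    def mismatch(k: float) -> float:
        p = CBMParams(n_sites, k, geom.surface_area)
        return cbm_chem_log_activity(p, n_sites, state, triplet) - target

    if mismatch(k_max) > 0:
        raise RuntimeError(
            f"no CBM binding constant in [0, {k_max:g}] reaches the TPM activity "
            f"{target:.6g}; increase k_max"
        )
    return brentq(mismatch, 0.0, k_max, xtol=1e-12, rtol=8.9e-16)
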