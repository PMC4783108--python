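"""Hard-body geometry and scaled-particle-theory (SPT) steric activity.

The crowded medium is a fluid of hard spheres (crowders) of diameter
``sigma0``.  Solute species — reactant monomers, dimer products, and the
bound complexes of the chemical-binding model — are hard convex bodies
characterized by the size ratio ``ς = d/sigma0`` and, for spherocylinders,
the asphericity ``λ = L/σp`` (cylinder length over cap diameter).

SPT gives the reversible work of inserting one such body into the crowder
fluid, i.e. the steric part of its log activity coefficient, as a cubic
polynomial in ``x = φ/(1-φ)`` whose coefficients A1..A3 depend only on
(ς, λ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PHI_VALIDITY_CEILING, SIGMA_CRYSTALLIN, T_REFERENCE

__all__ = [
    "SpeciesGeometry",
    "SolutionState",
    "shape_coefficients",
    "sphere_geometry",
    "product_geometry",
    "equivalent_sphere",
    "steric_log_activity",
    "steric_log_activity_dphi",
    "contact_value_g0max",
    "contact_value_g0max_dphi",
    "concentration_to_number_density",
    "number_density_to_concentration",
    "packing_to_number_density",
    "number_density_to_packing",
    "concentration_to_packing",
    "packing_to_concentration",
]


def shape_coefficients(sigma_ratio: float, asphericity: float = 0.0) -> tuple[float, float, float]:
    """SPT insertion-work coefficients (A1, A2, A3) for a spherocylinder.

    For a spherocylinder with cap diameter ``σp = ς·σ0`` and cylinder length
    ``L = λ·σp`` inserted into hard spheres of diameter σ0:

        A1 = ς³ + 3ς² + 3ς + 1.5λ(ς² + 2ς + 1)
        A2 = 3ς³ + 4.5ς² + 4.5λ(ς² + ς)
        A3 = 3ς³ + 4.5λς²

    A sphere equal in size to the crowder (ς = 1, λ = 0) gives (7, 7.5, 3).
    Together with the -ln(1-φ) term the low-density slope of the insertion
    work is 1 + A1 = (1+ς)³ for spheres, the familiar excluded-volume limit.

    Parameters
    ----------
    sigma_ratio
        ς > 0, cap diameter over crowder diameter.
    asphericity
        λ ≥ 0, cylinder length over cap diameter; 0 for a sphere.
    """
    s, lam = float(sigma_ratio), float(asphericity)
    if s <= 0:
        raise ValueError(f"sigma_ratio must be positive, got {s}")
    if lam < 0:
        raise ValueError(f"asphericity must be non-negative, got {lam}")
    a1 = s**3 + 3 * s**2 + 3 * s + 1.5 * lam * (s**2 + 2 * s + 1)
    a2 = 3 * s**3 + 4.5 * s**2 + 4.5 * lam * (s**2 + s)
    a3 = 3 * s**3 + 4.5 * lam * s**2
    return a1, a2, a3


@dataclass(frozen=True)
class SpeciesGeometry:
    """Hard-body shape of one solute species in a crowder fluid.

    Attributes
    ----------
    sigma_ratio
        ς = cap_diameter / crowder diameter σ0.
    asphericity
        λ = cylinder_length / cap_diameter (0 for spheres).
    cap_diameter
        Diameter σp of the hemispherical caps (equals the sphere diameter
        when λ = 0), nm.
    cylinder_length
        L = λ·σp, nm.
    A1, A2, A3
        SPT shape coefficients for insertion into the crowder fluid.
    """

    sigma_ratio: float
    asphericity: float
    cap_diameter: float
    cylinder_length: float
    A1: float
    A2: float
    A3: float

    def __post_init__(self) -> None:
        if self.cap_diameter <= 0:
            raise ValueError("cap_diameter must be positive")
        if not math.isclose(
            self.cylinder_length, self.asphericity * self.cap_diameter, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("cylinder_length must equal asphericity * cap_diameter")

    @property
    def volume(self) -> float:
        """Spherocylinder volume π σp³/6 + π σp² L/4, nm³."""
        return (
            math.pi * self.cap_diameter**3 / 6
            + math.pi * self.cap_diameter**2 * self.cylinder_length / 4
        )

    @property
    def surface_area(self) -> float:
        """Surface area π σp² (caps) + π σp L (cylinder) = π σp²(1+λ), nm²."""
        return math.pi * self.cap_diameter**2 * (1.0 + self.asphericity)


def sphere_geometry(diameter: float, crowder_diameter: float) -> SpeciesGeometry:
    """Spherical species of the given diameter in a crowder fluid."""
    if diameter <= 0 or crowder_diameter <= 0:
        raise ValueError("diameters must be positive")
    s = diameter / crowder_diameter
    a1, a2, a3 = shape_coefficients(s, 0.0)
    return SpeciesGeometry(s, 0.0, diameter, 0.0, a1, a2, a3)


def product_geometry(
    asphericity: float, sigma: float, crowder_diameter: float | None = None
) -> SpeciesGeometry:
    """Spherocylindrical dimer formed by two spheres of diameter ``sigma``.

    Volume conservation fixes the cap diameter:

        σp = σ (4 / (3λ + 2))^(1/3),   L = λ σp,

    so that the spherocylinder volume equals πσ³/3 (twice the monomer
    volume) for every λ.  At λ = 0 this is the volume-conserving sphere of
    diameter 2^(1/3) σ.

    Parameters
    ----------
    asphericity
        λ ≥ 0 of the dimer.
    sigma
        Monomer diameter, nm.
    crowder_diameter
        σ0 of the background fluid; defaults to ``sigma`` (crowders are the
        same protein as the reactants).
    """
    lam = float(asphericity)
    if lam < 0:
        raise ValueError(f"asphericity must be non-negative, got {lam}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    sigma0 = sigma if crowder_diameter is None else float(crowder_diameter)
    if sigma0 <= 0:
        raise ValueError("crowder_diameter must be positive")
    cap = sigma * (4.0 / (3.0 * lam + 2.0)) ** (1.0 / 3.0)
    s = cap / sigma0
    a1, a2, a3 = shape_coefficients(s, lam)
    return SpeciesGeometry(s, lam, cap, lam * cap, a1, a2, a3)


def equivalent_sphere(volume: float, crowder_diameter: float) -> SpeciesGeometry:
    """Volume-conserving sphere of the given volume (used for bound complexes)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    d = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    return sphere_geometry(d, crowder_diameter)


@dataclass(frozen=True)
class SolutionState:
    """Thermodynamic state of the crowder fluid.

    Attributes
    ----------
    packing_fraction
        φ ∈ [0, 1), fraction of volume occupied by crowders.
    temperature
        Absolute temperature, K.
    crowder_diameter
        σ0, nm.
    """

    packing_fraction: float
    temperature: float = T_REFERENCE
    crowder_diameter: float = SIGMA_CRYSTALLIN

    def __post_init__(self) -> None:
        phi = self.packing_fraction
        if not 0.0 <= phi < 1.0:
            raise ValueError(f"packing fraction must lie in [0, 1), got {phi}")
        if self.temperature <= 0 or self.crowder_diameter <= 0:
            raise ValueError("temperature and crowder_diameter must be positive")
        if phi > PHI_VALIDITY_CEILING:
            warnings.warn(
                f"packing fraction {phi:.3g} exceeds {PHI_VALIDITY_CEILING}; the two-body "
                "theory neglects many-body effects and becomes unreliable here",
                UserWarning,
                stacklevel=2,
            )

    @property
    def number_density(self) -> float:
        """Crowder number density ρ = 6φ/(π σ0³), nm⁻³."""
        return 6.0 * self.packing_fraction / (math.pi * self.crowder_diameter**3)


def _check_phi(phi):
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= 1):
        raise ValueError("packing fraction must lie in [0, 1)")
    return phi


def steric_log_activity(geom: SpeciesGeometry, state: SolutionState | float):
    """Steric log activity coefficient ln γ^st of a species.

    SPT insertion work in units of k_B T:

        ln γ^st = -ln(1-φ) + A1 x + A2 x² + A3 x³,   x = φ/(1-φ).

    ``state`` may be a :class:`SolutionState` or a bare packing fraction
    (scalar or array); only φ enters.
    """
    phi = state.packing_fraction if isinstance(state, SolutionState) else state
    phi = _check_phi(phi)
    x = phi / (1.0 - phi)
    out = -np.log1p(-phi) + geom.A1 * x + geom.A2 * x**2 + geom.A3 * x**3
    return float(out) if out.ndim == 0 else out


def steric_log_activity_dphi(geom: SpeciesGeometry, phi):
    """Analytic d(ln γ^st)/dφ; the φ→0 limit is 1 + A1."""
    phi = _check_phi(phi)
    x = phi / (1.0 - phi)
    out = 1.0 / (1.0 - phi) + (geom.A1 + 2 * geom.A2 * x + 3 * geom.A3 * x**2) / (1.0 - phi) ** 2
    return float(out) if out.ndim == 0 else out


def contact_value_g0max(phi):
    """Carnahan–Starling contact value of the radial distribution function.

    g0max = (1 - φ/2)/(1 - φ)³; equals 1 in the ideal-gas limit and grows
    monotonically with crowding.
    """
    phi = _check_phi(phi)
    out = (1.0 - phi / 2.0) / (1.0 - phi) ** 3
    return float(out) if out.ndim == 0 else out


def contact_value_g0max_dphi(phi):
    """Analytic derivative of the contact value, (5/2 - φ)/(1 - φ)⁴."""
    phi = _check_phi(phi)
    out = (2.5 - phi) / (1.0 - phi) ** 4
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# concentration <-> number density <-> packing fraction
# ---------------------------------------------------------------------------

from .constants import N_AVOGADRO  # noqa: E402

#: (mg/mL) * (mol/g) * N_A -> nm^-3:  1 mg/mL = 1 g/L, 1 L = 1e24 nm^3.
_CONC_TO_RHO = N_AVOGADRO / 1.0e24


def concentration_to_number_density(c, molar_mass: float):
    """Mass concentration (mg/mL) to number density (nm⁻³), ρ = c N_A / M."""
    c = np.asarray(c, dtype=float)
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c / molar_mass * _CONC_TO_RHO
    return float(out) if out.ndim == 0 else out


def number_density_to_concentration(rho, molar_mass: float):
    """Inverse of :func:`concentration_to_number_density`."""
    rho = np.asarray(rho, dtype=float)
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if np.any(rho < 0):
        raise ValueError("number density must be non-negative")
    out = rho * molar_mass / _CONC_TO_RHO
    return float(out) if out.ndim == 0 else out


def packing_to_number_density(phi, diameter: float):
    """ρ = 6φ/(π d³) for spheres of the given diameter (nm⁻³)."""
    phi = np.asarray(phi, dtype=float)
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if np.any(phi < 0):
        raise ValueError("packing fraction must be non-negative")
    out = 6.0 * phi / (math.pi * diameter**3)
    return float(out) if out.ndim == 0 else out


def number_density_to_packing(rho, diameter: float):
    """φ = ρ π d³ / 6."""
    rho = np.asarray(rho, dtype=float)
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if np.any(rho < 0):
        raise ValueError("number density must be non-negative")
    out = rho * math.pi * diameter**3 / 6.0
    return float(out) if out.ndim == 0 else out


def concentration_to_packing(c, molar_mass: float, diameter: float):
    """Mass concentration (mg/mL) to packing fraction."""
    return number_density_to_packing(concentration_to_number_density(c, molar_mass), diameter)


def packing_to_concentration(phi, molar_mass: float, diameter: float):
    """Packing fraction to mass concentration (mg/mL)."""
    return number_density_to_concentration(packing_to_number_density(phi, diameter), molar_mass)
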