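"""Osmotic pressure of the crystallin suspension.

The pressure follows from the density-dependent activity coefficient of
the monomer by the standard thermodynamic integration

    Π = RT [ ρ + ∫₀^ρ ρ' (d ln γ / dρ') dρ' ],

with γ the *total* (steric + chemical) activity coefficient of the
monomeric crystallin — the species actually present in the measured
suspension.  With ln γ ≡ 0 this reduces to the ideal law Π_i = ρRT; with
no attraction it is the SPT hard-sphere equation of state (low-density
expansion Π/(ρRT) = 1 + 4vρ + …, the exact second virial of hard
spheres).

The integrand is assembled from analytic derivatives (chain rule through
φ = ρπσ0³/6), not numeric differentiation; a finite-difference version is
kept only as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from .config import ModelConfig
from .constants import K_BOLTZMANN, PA_PER_KPA, PER_NM3_TO_PER_M3, T_REFERENCE
from .geometry import (
    SpeciesGeometry,
    concentration_to_number_density,
    contact_value_g0max,
    contact_value_g0max_dphi,
    steric_log_activity,
    steric_log_activity_dphi,
)
from .interactions import CBMParams, TPMParams, _cbm_companions
from .geometry import SolutionState

__all__ = [
    "Isotherm",
    "ideal_pressure",
    "log_activity_drho",
    "osmotic_pressure",
    "osmotic_pressure_curve",
    "pressure_isotherm",
    "read_isotherm",
    "write_isotherm",
]


@dataclass
class Isotherm:
    """Ordered osmotic-pressure isotherm Π(c).

    Attributes
    ----------
    concentrations
        mg/mL, strictly increasing, ≥ 0.
    pressures
        kPa, finite.
    temperature
        K.
    """

    concentrations: np.ndarray
    pressures: np.ndarray
    temperature: float = T_REFERENCE
    concentration_unit: str = "mg/mL"
    pressure_unit: str = "kPa"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.concentrations.shape != self.pressures.shape:
            raise ValueError("concentrations and pressures must have equal length")
        if self.concentrations.ndim != 1 or self.concentrations.size == 0:
            raise ValueError("isotherm must be a non-empty 1-D table")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.pressures)):
            raise ValueError("pressures must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __len__(self) -> int:
        return self.concentrations.size


def _pressure_kpa(rho_plus_integral, temperature: float):
    """(nm⁻³) → kPa via Π = n k_B T."""
    return rho_plus_integral * PER_NM3_TO_PER_M3 * K_BOLTZMANN * temperature / PA_PER_KPA


def ideal_pressure(rho, temperature: float = T_REFERENCE):
    """Ideal (van 't Hoff) osmotic pressure Π_i = ρRT, in kPa, ρ in nm⁻³."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("number density must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    out = _pressure_kpa(rho, temperature)
    return float(out) if out.ndim == 0 else out


def log_activity_drho(
    model: TPMParams | CBMParams | None,
    geom: SpeciesGeometry,
    rho,
    crowder_diameter: float,
):
    """Analytic d(ln γ)/dρ of a species at number densities ``rho`` (nm⁻³).

    Vectorized over ``rho``; raises if any density maps to φ ≥ 1.
    """
    rho = np.asarray(rho, dtype=float)
    v0 = math.pi * crowder_diameter**3 / 6.0
    phi = rho * v0
    if np.any(phi >= 1.0) or np.any(phi < 0.0):
        raise ValueError("density path leaves the physical range 0 <= phi < 1")

    out = steric_log_activity_dphi(geom, phi) * v0
    if model is None:
        pass
    elif isinstance(model, TPMParams):
        bracket = model.attraction_range + (contact_value_g0max(phi) - 1.0) * model.decay_range
        out = out - model.epsilon * geom.surface_area * (
            bracket + rho * model.decay_range * contact_value_g0max_dphi(phi) * v0
        )
    elif isinstance(model, CBMParams):
        # companion geometries do not depend on phi
        state0 = SolutionState(0.0, crowder_diameter=crowder_diameter)
        crowder, complex_geom = _cbm_companions(geom, state0)
        delta = (
            steric_log_activity(geom, phi)
            + steric_log_activity(crowder, phi)
            - steric_log_activity(complex_geom, phi)
        )
        ddelta = (
            steric_log_activity_dphi(geom, phi)
            + steric_log_activity_dphi(crowder, phi)
            - steric_log_activity_dphi(complex_geom, phi)
        )
        a = model.binding_constant * np.exp(delta)
        n = model.sites_for(geom)
        out = out - n * a * (1.0 + phi * ddelta) / (1.0 + a * phi) * v0
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    return float(out) if np.ndim(out) == 0 else out


def osmotic_pressure(
    model: TPMParams | CBMParams | None,
    geom: SpeciesGeometry,
    rho: float,
    temperature: float = T_REFERENCE,
    crowder_diameter: float | None = None,
) -> float:
    """Osmotic pressure (kPa) at a single number density, adaptive quadrature.

    ``crowder_diameter`` defaults to the species cap diameter (monomer
    suspension, ς = 1).
    """
    if rho < 0:
        raise ValueError("number density must be non-negative")
    sigma0 = geom.cap_diameter if crowder_diameter is None else crowder_diameter
    if rho == 0.0:
        return 0.0
    integral, err = quad(
        lambda r: r * log_activity_drho(model, geom, r, sigma0),
        0.0,
        rho,
        epsabs=1e-13,
        epsrel=1e-11,
        limit=200,
    )
    return float(_pressure_kpa(rho + integral, temperature))


def osmotic_pressure_curve(
    model: TPMParams | CBMParams | None,
    geom: SpeciesGeometry,
    rho,
    temperature: float = T_REFERENCE,
    crowder_diameter: float | None = None,
    n_nodes: int = 64,
):
    """Osmotic pressure (kPa) on an array of densities.

    Fixed-order Gauss–Legendre quadrature per point (the integrand is
    smooth and polynomial-like, so 64 nodes reach near machine precision);
    used by the fitting layer, where thousands of curve evaluations occur.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho < 0):
        raise ValueError("number density must be non-negative")
    sigma0 = geom.cap_diameter if crowder_diameter is None else crowder_diameter
    t, w = np.polynomial.legendre.leggauss(n_nodes)
    # map [-1, 1] to [0, rho_i] for every target density
    nodes = 0.5 * np.outer(rho, t + 1.0)              # (m, n_nodes)
    weights = 0.5 * np.outer(rho, w)
    integrand = nodes * log_activity_drho(model, geom, nodes, sigma0)
    integral = np.sum(weights * integrand, axis=1)
    return _pressure_kpa(rho + integral, temperature)


def pressure_isotherm(
    model: TPMParams | CBMParams | None,
    concentrations,
    config: ModelConfig | None = None,
) -> Isotherm:
    """Model isotherm Π(c) on a concentration grid (mg/mL)."""
    config = config or ModelConfig()
    c = np.asarray(concentrations, dtype=float)
    rho = concentration_to_number_density(c, config.molar_mass)
    geom = config.reactant_geometry()
    pi = osmotic_pressure_curve(
        model, geom, rho, config.temperature, config.crowder_diameter
    )
    return Isotherm(c, pi, config.temperature)


# ---------------------------------------------------------------------------
# CSV interface: columns c_mg_per_mL, Pi_kPa; '#' comment lines allowed
# ---------------------------------------------------------------------------

_HEADER = "c_mg_per_mL,Pi_kPa"


def write_isotherm(path: str | Path, iso: Isotherm) -> None:
    """Write an isotherm as CSV (12 significant digits, deterministic)."""
    lines = [f"# temperature_K = {iso.temperature:.12g}", _HEADER]
    for c, p in zip(iso.concentrations, iso.pressures):
        lines.append(f"{c:.12g},{p:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_isotherm(path: str | Path) -> Isotherm:
    """Read an isotherm CSV; validates header and monotone concentrations.

    Malformed rows raise with the offending line number.
    """
    temperature = T_REFERENCE
    cs: list[float] = []
    ps: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("temperature_K"):
                temperature = float(body.split("=", 1)[1])
            continue
        if not header_seen:
            if line.replace(" ", "") != _HEADER:
                raise ValueError(
                    f"{path}:{lineno}: expected header '{_HEADER}', got '{line}'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two comma-separated values")
        try:
            c, p = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
        if cs and c <= cs[-1]:
            raise ValueError(
                f"{path}:{lineno}: concentrations must be strictly increasing"
            )
        cs.append(c)
        ps.append(p)
    if not header_seen:
        raise ValueError(f"{path}: missing header '{_HEADER}'")
    if not cs:
        raise ValueError(f"{path}: no data rows")
    return Isotherm(np.array(cs), np.array(ps), temperature)
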