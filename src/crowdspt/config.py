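"""Run configuration shared by the fitting, sweep, generator and CLI layers."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .constants import M_CRYSTALLIN, SIGMA_CRYSTALLIN, T_REFERENCE
from .geometry import SolutionState, SpeciesGeometry, product_geometry, sphere_geometry
from .interactions import CBMParams, TPMParams

__all__ = ["ModelConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    """Physical configuration of the crystallin system.

    Attributes
    ----------
    sigma
        Reactant monomer diameter, nm.
    sigma_ratio
        ς = σ/σ0, reactant over crowder diameter (1: crowders are the same
        protein).
    asphericity
        λ of the dimer product (0: spherical).
    molar_mass
        g/mol, used for the concentration ↔ packing conversion.
    temperature
        K.
    product_site_rule
        Binding-site rule for the product in the CBM ('area' or
        'conserved').
    """

    sigma: float = SIGMA_CRYSTALLIN
    sigma_ratio: float = 1.0
    asphericity: float = 0.0
    molar_mass: float = M_CRYSTALLIN
    temperature: float = T_REFERENCE
    product_site_rule: str = "area"

    def __post_init__(self) -> None:
        if min(self.sigma, self.sigma_ratio, self.molar_mass, self.temperature) <= 0:
            raise ValueError("sigma, sigma_ratio, molar_mass, temperature must be positive")
        if self.asphericity < 0:
            raise ValueError("asphericity must be non-negative")

    @property
    def crowder_diameter(self) -> float:
        return self.sigma / self.sigma_ratio

    def reactant_geometry(self) -> SpeciesGeometry:
        return sphere_geometry(self.sigma, self.crowder_diameter)

    def product_geom(self) -> SpeciesGeometry:
        return product_geometry(self.asphericity, self.sigma, self.crowder_diameter)

    def state(self, phi: float) -> SolutionState:
        return SolutionState(phi, self.temperature, self.crowder_diameter)

    def tpm(self, epsilon: float) -> TPMParams:
        return TPMParams.for_crystallin(epsilon, self.sigma)

    def cbm(self, n_sites: float, binding_constant: float) -> CBMParams:
        return CBMParams.for_crystallin(
            n_sites, binding_constant, self.sigma, self.product_site_rule
        )

    def replace(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from a YAML key-value file; unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(ModelConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
    return ModelConfig(**raw)
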