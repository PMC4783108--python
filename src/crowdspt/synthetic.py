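"""Synthetic osmotic-pressure isotherms.

Stands in for membrane-osmometry measurements on crystallin solutions:
monotone-to-saturating Π(c) curves over the dilute-to-physiological range
(up to ~400 mg/mL at 298.15 K) that lie below the ideal law ρRT whenever
the model carries attraction.  Noise is multiplicative Gaussian by
default (osmometry error scales with signal); the generator is exactly
reproducible per seed and, at zero noise, returns the model curve itself
— the inverse fixture of the parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .thermo import Isotherm, ideal_pressure, pressure_isotherm, read_isotherm, write_isotherm
from .geometry import concentration_to_number_density

__all__ = ["GeneratorSpec", "generate_isotherm", "default_c_grid", "read_isotherm", "write_isotherm"]

_MODELS = ("ideal", "hard-sphere", "tpm", "cbm")


def default_c_grid() -> np.ndarray:
    """16 concentrations spanning 25–400 mg/mL (dilute limb through the
    physiological 200–400 mg/mL regime)."""
    return np.linspace(25.0, 400.0, 16)


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic isotherm.

    Attributes
    ----------
    model
        'ideal', 'hard-sphere', 'tpm' or 'cbm'.
    parameters
        {'epsilon': ...} for the TPM, {'n_sites': ..., 'binding_constant':
        ...} for the CBM; empty otherwise.
    c_grid
        Strictly increasing concentrations, mg/mL.
    noise_sd
        Relative standard deviation of multiplicative Gaussian noise
        (absolute, in kPa, when ``noise_kind='additive'``).  Default 5%.
    noise_kind
        'multiplicative' or 'additive'.
    seed
        Mandatory whenever noise_sd > 0.
    config
        Physical configuration (geometry, molar mass, temperature).
    """

    model: str
    parameters: dict = field(default_factory=dict)
    c_grid: np.ndarray = field(default_factory=default_c_grid)
    noise_sd: float = 0.05
    noise_kind: str = "multiplicative"
    seed: int | None = None
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_kind not in ("multiplicative", "additive"):
            raise ValueError("noise_kind must be 'multiplicative' or 'additive'")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sd > 0")
        self.c_grid = np.asarray(self.c_grid, dtype=float)
        if self.c_grid.ndim != 1 or self.c_grid.size == 0:
            raise ValueError("c_grid must be a non-empty 1-D array")
        if np.any(np.diff(self.c_grid) <= 0):
            raise ValueError("c_grid must be strictly increasing")


def _interaction_model(spec: GeneratorSpec):
    if spec.model == "tpm":
        return spec.config.tpm(spec.parameters["epsilon"])
    if spec.model == "cbm":
        return spec.config.cbm(
            spec.parameters["n_sites"], spec.parameters["binding_constant"]
        )
    return None


def generate_isotherm(spec: GeneratorSpec) -> Isotherm:
    """Generate one isotherm, Π_i = Π_model(c_i)(1 + η_i), η ~ N(0, sd²)."""
    cfg = spec.config
    if spec.model == "ideal":
        rho = concentration_to_number_density(spec.c_grid, cfg.molar_mass)
        clean = ideal_pressure(rho, cfg.temperature)
        iso = Isotherm(spec.c_grid, np.atleast_1d(clean), cfg.temperature)
    else:
        iso = pressure_isotherm(_interaction_model(spec), spec.c_grid, cfg)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        eta = rng.normal(0.0, spec.noise_sd, size=len(iso))
        if spec.noise_kind == "multiplicative":
            pressures = iso.pressures * (1.0 + eta)
        else:
            pressures = iso.pressures + eta
        iso = Isotherm(iso.concentrations, pressures, iso.temperature)
    return iso
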