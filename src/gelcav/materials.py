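"""Material property records and gel concentration calibrations.

A :class:`MaterialProperties` record collects everything the bubble-dynamics
model needs to know about one medium: density, shear modulus of the
neo-Hookean network, kinematic viscosity of the Kelvin–Voigt dashpot,
surface tension, vapor and ambient pressure, and the polytropic index of
the trapped gas.  Concentration-to-modulus calibrations for agarose and
gelatin are provided, along with a small registry of nominal parameter
sets shipped as packaged YAML data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Dict

import yaml

__all__ = [
    "MaterialProperties",
    "GelCalibration",
    "UnknownGelError",
    "UnknownMaterialError",
    "elastic_modulus_from_concentration",
    "shear_from_elastic",
    "nominal_properties",
    "available_materials",
    "load_material_yaml",
    "dump_material_yaml",
]


class UnknownGelError(ValueError):
    """Raised for a gel type with no concentration calibration."""


class UnknownMaterialError(KeyError):
    """Raised when a material name is not in the registry."""


@dataclass(frozen=True)
class MaterialProperties:
    """One medium's physical parameters (SI units, absolute pressures)."""

    density: float                 # rho, kg/m^3
    shear_modulus: float           # mu, Pa
    kinematic_viscosity: float     # nu, m^2/s
    surface_tension: float         # gamma, N/m
    vapor_pressure: float          # p_v, Pa absolute
    ambient_pressure: float        # p_inf, Pa absolute
    polytropic_index: float = 1.0  # k; 1 = isothermal
    label: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.shear_modulus < 0:
            raise ValueError("shear_modulus must be non-negative")
        if self.kinematic_viscosity < 0:
            raise ValueError("kinematic_viscosity must be non-negative")
        if self.surface_tension < 0:
            raise ValueError("surface_tension must be non-negative")
        if not 0.0 <= self.vapor_pressure <= self.ambient_pressure:
            raise ValueError(
                "vapor_pressure must satisfy 0 <= p_v <= p_inf, got "
                f"p_v={self.vapor_pressure}, p_inf={self.ambient_pressure}"
            )
        if self.polytropic_index < 1:
            raise ValueError("polytropic_index must be >= 1")

    @property
    def dynamic_viscosity(self) -> float:
        """eta = rho * nu, Pa s (the Deborah-group product)."""
        return self.density * self.kinematic_viscosity

    def with_(self, **changes) -> "MaterialProperties":
        """Return a copy with selected fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


#: Power-law calibrations E(c) in kPa with c in % g/ml.
_GEL_LAWS = {
    "agarose": (85.0, 1.8),
    "gelatin": (8.0, 1.0),
}


def elastic_modulus_from_concentration(concentration: float, gel_type: str) -> float:
    """Convert gel concentration (% g/ml) to elastic modulus in Pa.

    Agarose follows E_a = 85 c^1.8 kPa; gelatin follows E_g = 8 c kPa.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    try:
        prefactor_kpa, exponent = _GEL_LAWS[gel_type.lower()]
    except KeyError:
        raise UnknownGelError(
            f"unknown gel_type {gel_type!r}; known: {sorted(_GEL_LAWS)}"
        ) from None
    return 1e3 * prefactor_kpa * concentration ** exponent


def shear_from_elastic(elastic_modulus: float, poisson_ratio: float = 0.5) -> float:
    """Shear modulus mu from elastic modulus E.

    Uses mu = E / (2 (1 + nu_p)); the default Poisson ratio 0.5
    (incompressible isotropic solid) gives mu = E / 3.  Override
    ``poisson_ratio`` for compressible media.
    """
    if elastic_modulus < 0:
        raise ValueError(f"elastic modulus must be non-negative, got {elastic_modulus}")
    if not -1.0 < poisson_ratio <= 0.5:
        raise ValueError("poisson_ratio must lie in (-1, 0.5]")
    return elastic_modulus / (2.0 * (1.0 + poisson_ratio))


@dataclass(frozen=True)
class GelCalibration:
    """A (gel type, concentration, elastic modulus) calibration point."""

    gel_type: str
    concentration: float  # % g/ml
    elastic_modulus: float = field(default=0.0)  # Pa

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        modulus = self.elastic_modulus
        if modulus <= 0:
            modulus = elastic_modulus_from_concentration(self.concentration, self.gel_type)
            object.__setattr__(self, "elastic_modulus", modulus)

    @property
    def shear_modulus(self) -> float:
        return shear_from_elastic(self.elastic_modulus)


def _load_registry() -> Dict[str, MaterialProperties]:
    text = resources.files("gelcav").joinpath("data/materials.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: MaterialProperties(label=name, **fields) for name, fields in raw.items()
    }


_REGISTRY: Dict[str, MaterialProperties] | None = None


def _registry() -> Dict[str, MaterialProperties]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def available_materials() -> list[str]:
    """Names of the registered nominal parameter sets."""
    return sorted(_registry())


def nominal_properties(name: str) -> MaterialProperties:
    """Look up a nominal material by name."""
    try:
        return _registry()[name]
    except KeyError:
        raise UnknownMaterialError(
            f"unknown material {name!r}; registry contains {available_materials()}"
        ) from None


def load_material_yaml(path) -> MaterialProperties:
    """Read a single material from a YAML file with MaterialProperties fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    label = raw.pop("label", str(path))
    return MaterialProperties(label=label, **raw)


def dump_material_yaml(props: MaterialProperties, path) -> None:
    """Write a material record to YAML (round-trip stable)."""
    data = props.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
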