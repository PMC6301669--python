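"""Predicting potency and HU for phantom materials from composition.

A calibration phantom insert is specified by either a chemical formula or
a map of elemental mass fractions, plus its bulk density.  Mass potency is
intensive (density-free); the CT number follows from it and the density:

    HU = 1000 (mu* - 1),   mu* = eta_rho * rho / rho_water.

Air in the HU denominator is treated as zero attenuation by default (its
contribution at 1.2 kg/m^3 is ~1e-3 of water's); an explicit air density
can be supplied to use the true air reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .materials import Composition, molar_mass, parse_formula
from .spectral import AcquisitionModel, mass_potency

__all__ = ["PhantomMaterial", "predict_mass_potency", "predict_hu", "catphan_materials"]

#: Dry-air mass fractions (N/O/Ar by mass; CO2 folded into O).
AIR_MASS_FRACTIONS = {"N": 0.755, "O": 0.232, "Ar": 0.013}
AIR_DENSITY = 1.2  # kg/m^3 at room conditions


@dataclass(frozen=True)
class PhantomMaterial:
    """A named material: formula or mass fractions, plus bulk density."""

    name: str
    density: float
    composition: Composition | None = None
    mass_fractions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if (self.composition is None) == (self.mass_fractions is None):
            raise ValueError("give exactly one of composition or mass_fractions")
        if self.mass_fractions is not None:
            total = sum(self.mass_fractions.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"mass fractions sum to {total}, not 1")
            object.__setattr__(self, "mass_fractions", dict(self.mass_fractions))

    @classmethod
    def from_formula(cls, name: str, formula: str, density: float) -> "PhantomMaterial":
        return cls(name=name, density=density, composition=parse_formula(formula))

    def as_composition(self) -> Composition:
        """Element amounts per formula unit, or per kilogram for fractions.

        Mass potency is invariant to the overall scale of the composition,
        so moles-per-kilogram entries (w_e / M_e) serve directly.
        """
        if self.composition is not None:
            return self.composition
        entries = {
            symbol: fraction / molar_mass(Composition({symbol: 1}))
            for symbol, fraction in self.mass_fractions.items()
            if fraction > 0
        }
        return Composition(entries)


def predict_mass_potency(
    material: PhantomMaterial,
    model: AcquisitionModel,
    voltage: float,
) -> float:
    """Dimensionless mass HU potency of the material; density-independent."""
    return mass_potency(material.as_composition(), voltage, model)


def predict_hu(
    material: PhantomMaterial,
    model: AcquisitionModel,
    voltage: float,
    air_density: float | None = None,
) -> float:
    """Predicted CT number of the material at its bulk density.

    With the default zero-attenuation air reference,
    HU = 1000 (eta_rho rho / rho_water - 1); vacuum maps to -1000.  Pass
    ``air_density`` to divide by (mu_water - mu_air) instead.
    """
    eta = predict_mass_potency(material, model, voltage)
    mu_star_material = eta * material.density / model.water_density
    if air_density is None:
        return 1000.0 * (mu_star_material - 1.0)
    air = PhantomMaterial(
        name="air", density=air_density, mass_fractions=AIR_MASS_FRACTIONS
    )
    eta_air = predict_mass_potency(air, model, voltage)
    mu_star_air = eta_air * air_density / model.water_density
    return 1000.0 * (mu_star_material - 1.0) / (1.0 - mu_star_air)


def catphan_materials() -> tuple[PhantomMaterial, ...]:
    """The six polymer inserts of a Catphan-style sensitometry module."""
    specs = [
        ("teflon", "C2F4", 2160.0),
        ("delrin", "CH2O", 1415.0),
        ("acrylic", "C5H8O2", 1180.0),
        ("polystyrene", "C8H8", 1040.0),
        ("low-density polyethylene", "C2H4", 925.0),
        ("polymethylpentene", "C6H12", 833.0),
    ]
    return tuple(
        PhantomMaterial.from_formula(name, formula, density)
        for name, formula, density in specs
    )
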