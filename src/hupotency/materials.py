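"""Chemical formulas, molar masses, and the packaged powder-potency dataset.

X-ray attenuation in the diagnostic range is insensitive to chemical
bonding (independent-atom approximation), so a material is fully described
here by its stoichiometry.  This module provides the bridge from a chemical
formula to molar quantities, plus the packaged table of measured mass HU
potencies for 30 powders and water at four tube voltages.

Units are SI throughout: molar masses in kg/mol, densities in kg/m^3.
Potencies use the AHU convention (AHU = HU + 1000, so water reads 1000 AHU
and vacuum 0): mass potency eta_rho is dimensionless (water = 1 by
construction at the reference density) and molar potency is expressed in
AHU m^3 mol^-1, i.e. the AHU added per mole-per-cubic-meter of substance.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_MASS",
    "ATOMIC_NUMBER",
    "STUDY_ELEMENTS",
    "WATER_DENSITY",
    "WATER_MOLAR_MASS",
    "Composition",
    "CompoundRecord",
    "CompoundPotencyTable",
    "parse_formula",
    "format_formula",
    "molar_mass",
    "load_powder_table",
    "compound_molar_potency",
]

#: IUPAC conventional atomic weights (2021), natural isotopic abundance,
#: for the first 20 elements, converted to kg/mol.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008e-3,
    "He": 4.0026e-3,
    "Li": 6.94e-3,
    "Be": 9.0122e-3,
    "B": 10.81e-3,
    "C": 12.011e-3,
    "N": 14.007e-3,
    "O": 15.999e-3,
    "F": 18.998e-3,
    "Ne": 20.180e-3,
    "Na": 22.990e-3,
    "Mg": 24.305e-3,
    "Al": 26.982e-3,
    "Si": 28.085e-3,
    "P": 30.974e-3,
    "S": 32.06e-3,
    "Cl": 35.45e-3,
    "Ar": 39.95e-3,
    "K": 39.098e-3,
    "Ca": 40.078e-3,
}

ATOMIC_NUMBER: dict[str, int] = {
    symbol: z for z, symbol in enumerate(ATOMIC_MASS, start=1)
}

#: The 13 elements covered by the powder experiment
#: (Z = 1, 6-8, 11-17, 19, 20), in order of atomic number.
STUDY_ELEMENTS: tuple[str, ...] = (
    "H", "C", "N", "O", "Na", "Mg", "Al", "Si", "P", "S", "Cl", "K", "Ca",
)

#: Reference density of liquid water, kg/m^3 (room temperature).
WATER_DENSITY: float = 998.0

#: Molar mass of water, kg/mol.
WATER_MOLAR_MASS: float = 18.015e-3

#: AHU value of water at the reference density; sets the potency scale.
AHU_WATER: float = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)_?(\d*)_?")

_DATA_SHA256 = "9549334aa80c83de6408d66d170696df7a3a6c7144b64a37f763e5360652adf8"


@dataclass(frozen=True)
class Composition:
    """Stoichiometry of a formula unit: element symbol -> atom count."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("composition must contain at least one element")
        for symbol, count in self.entries.items():
            if symbol not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {symbol!r}")
            if not count > 0:
                raise ValueError(f"count for {symbol} must be > 0, got {count}")
        object.__setattr__(self, "entries", dict(self.entries))

    def __getitem__(self, symbol: str) -> float:
        return self.entries.get(symbol, 0.0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self):
        return self.entries.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Composition):
            return NotImplemented
        return dict(self.entries) == dict(other.entries)

    def __hash__(self) -> int:
        return hash(frozenset(self.entries.items()))


def parse_formula(formula: str) -> Composition:
    """Parse a chemical formula such as ``"CaSO6H4"`` or ``"C_14H_24O_9"``.

    Both plain and underscore-subscripted dialects are accepted; an
    unsubscripted symbol counts one atom.  Charges, hydration dots and
    parentheses are rejected.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    text = formula.strip()
    pos = 0
    counts: dict[str, float] = {}
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.end() == pos:
            raise ValueError(f"cannot parse formula {formula!r} at {text[pos:]!r}")
        symbol, digits = match.groups()
        if symbol not in ATOMIC_MASS:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        count = int(digits) if digits else 1
        if count <= 0:
            raise ValueError(f"subscript for {symbol} must be positive in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + count
        pos = match.end()
    return Composition(counts)


def format_formula(c: Composition) -> str:
    """Render a composition back to the plain dialect (``H2O`` -> ``"H2O"``)."""
    parts = []
    for symbol, count in c.items():
        n = int(count)
        if n != count:
            raise ValueError("cannot format non-integer stoichiometry")
        parts.append(symbol if n == 1 else f"{symbol}{n}")
    return "".join(parts)


def molar_mass(c: Composition, masses: Mapping[str, float] | None = None) -> float:
    """Molar mass of a formula unit in kg/mol."""
    table = ATOMIC_MASS if masses is None else masses
    total = 0.0
    for symbol, count in c.items():
        if symbol not in table:
            raise KeyError(f"element {symbol} missing from atomic-mass table")
        total += count * table[symbol]
    return total


@dataclass(frozen=True)
class CompoundRecord:
    """One measured compound: formula plus mass potency per tube voltage."""

    name: str
    formula: str
    composition: Composition
    supplier: str
    mass_potency: Mapping[float, float]

    def __post_init__(self) -> None:
        for kv, eta in self.mass_potency.items():
            if eta <= 0:
                raise ValueError(f"{self.name}: mass potency at {kv} kV must be > 0")
        object.__setattr__(self, "mass_potency", dict(self.mass_potency))


@dataclass(frozen=True)
class CompoundPotencyTable:
    """The measured powder table: records x strictly increasing voltages."""

    records: tuple[CompoundRecord, ...]
    voltages: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.voltages, self.voltages[1:])):
            raise ValueError("voltages must be strictly increasing")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names")
        for r in self.records:
            missing = [kv for kv in self.voltages if kv not in r.mass_potency]
            if missing:
                raise ValueError(f"{r.name}: missing voltages {missing}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            r.name: {kv: r.mass_potency[kv] for kv in self.voltages}
            for r in self.records
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "compound"
        return frame


def load_powder_table(verify_checksum: bool = True) -> CompoundPotencyTable:
    """Load the packaged powder measurement table (31 records, 4 voltages).

    The dataset holds the observed dimensionless mass HU potency of 30
    powders plus water at 80/100/120/140 kV.  Two formulas are stored in
    their charge-balanced form (K2CO3, Na2CO3) matching the compound names.
    """
    ref = resources.files("hupotency").joinpath("data/powder_potency.csv")
    raw = ref.read_bytes()
    if verify_checksum and hashlib.sha256(raw).hexdigest() != _DATA_SHA256:
        raise ValueError("packaged powder table is corrupted (checksum mismatch)")
    frame = pd.read_csv(ref)
    voltages = (80.0, 100.0, 120.0, 140.0)
    records = tuple(
        CompoundRecord(
            name=row["name"],
            formula=row["formula"],
            composition=parse_formula(row["formula"]),
            supplier=row["supplier"],
            mass_potency={
                kv: float(row[f"eta_{int(kv)}"]) for kv in voltages
            },
        )
        for _, row in frame.iterrows()
    )
    return CompoundPotencyTable(records=records, voltages=voltages)


def compound_molar_potency(
    record: CompoundRecord,
    water_density: float = WATER_DENSITY,
    masses: Mapping[str, float] | None = None,
) -> dict[float, float]:
    """Convert a compound's mass potencies to molar potencies.

    The dimensionless mass potency eta_rho is the AHU contribution per unit
    mass density relative to water; one AHU per kg/m^3 of water corresponds
    to 1000/rho_water AHU m^3 kg^-1, so

        p(V) = eta_rho(V) * (1000 / water_density) * molar_mass

    in AHU m^3 mol^-1.
    """
    if water_density <= 0:
        raise ValueError("water density must be positive")
    mm = molar_mass(record.composition, masses)
    scale = AHU_WATER / water_density * mm
    return {kv: eta * scale for kv, eta in record.mass_potency.items()}
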