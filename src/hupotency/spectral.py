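"""Spectral attenuation model: cross sections, tube spectra, and potencies.

The measurable CT number of a material under a polychromatic beam is
governed by the effective attenuation ratio

    mu* = Int S(E) mu(E) dE / Int S(E) mu_water(E) dE,

where S(E) is the detected weight: tube fluence, times filter
transmission exp(-mu_filter(E) t), times detector response D(E).  With
mu(E) = n sigma(E) (n the molar density of formula units, sigma the molar
attenuation cross section) the intensive molar HU potency of a substance is

    p = 1000 * <sigma>_S / (n0 * <sigma_water>_S)   [AHU m^3 mol^-1]

and the dimensionless mass potency is eta_rho = p * rho0 / (1000 * M).
Both are density-free and invariant to rescaling of fluence or detector
response.  Quadrature is trapezoidal on the working grid (1 keV steps by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .materials import (
    ATOMIC_MASS,
    WATER_DENSITY,
    WATER_MOLAR_MASS,
    Composition,
    molar_mass,
    parse_formula,
)
from .projection import ElementPotencyMatrix

__all__ = [
    "EnergyGrid",
    "CrossSectionSet",
    "Spectrum",
    "DetectorResponse",
    "FilterSpec",
    "AcquisitionModel",
    "default_grid",
    "effective_weight",
    "mu_star",
    "molar_potency",
    "mass_potency",
    "element_potency_matrix",
    "load_xcom",
    "load_tasmics",
]

WATER = Composition({"H": 2, "O": 1})

#: Molar density of the water reference, mol/m^3 (~55 400).
WATER_MOLAR_DENSITY = WATER_DENSITY / WATER_MOLAR_MASS

ALUMINUM_DENSITY = 2699.0  # kg/m^3


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies in keV."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        energies = np.asarray(self.energies, dtype=float)
        if energies.ndim != 1 or energies.size < 2:
            raise ValueError("energy grid needs at least two points")
        if np.any(energies <= 0) or np.any(np.diff(energies) <= 0):
            raise ValueError("energies must be positive and strictly increasing")
        object.__setattr__(self, "energies", energies)

    def __len__(self) -> int:
        return len(self.energies)


def default_grid(max_kev: float = 140.0, min_kev: float = 5.0) -> EnergyGrid:
    """Working grid: 1 keV steps from ``min_kev`` to ``max_kev`` inclusive."""
    return EnergyGrid(np.arange(min_kev, max_kev + 0.5, 1.0))


@dataclass(frozen=True)
class CrossSectionSet:
    """Molar attenuation cross sections (m^2/mol) per element on a grid."""

    grid: EnergyGrid
    sigma: Mapping[str, np.ndarray]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for symbol, values in self.sigma.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.grid.energies.shape:
                raise ValueError(f"{symbol}: cross section not aligned with grid")
            if np.any(values <= 0):
                raise ValueError(f"{symbol}: cross sections must be positive")
            clean[symbol] = values
        object.__setattr__(self, "sigma", clean)

    def compound_sigma(self, c: Composition) -> np.ndarray:
        """Independent-atom cross section of a formula unit, m^2/mol."""
        total = np.zeros_like(self.grid.energies)
        for symbol, count in c.items():
            if symbol not in self.sigma:
                raise KeyError(f"no cross section for element {symbol}")
            total = total + count * self.sigma[symbol]
        return total

    def matrix(self, elements: Sequence[str]) -> np.ndarray:
        return np.stack([self.compound_sigma(Composition({e: 1})) for e in elements])


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin for one tube voltage."""

    grid: EnergyGrid
    fluence: np.ndarray
    tube_voltage: float

    def __post_init__(self) -> None:
        fluence = np.asarray(self.fluence, dtype=float)
        if fluence.shape != self.grid.energies.shape:
            raise ValueError("fluence not aligned with grid")
        if np.any(fluence < 0):
            raise ValueError("fluence must be non-negative")
        if np.any(fluence[self.grid.energies > self.tube_voltage] != 0):
            raise ValueError("fluence must vanish above the tube voltage")
        object.__setattr__(self, "fluence", fluence)


@dataclass(frozen=True)
class DetectorResponse:
    """Single-photon signal strength D(E) on a grid."""

    grid: EnergyGrid
    values: np.ndarray
    form: str = "tabulated"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.energies.shape:
            raise ValueError("detector response not aligned with grid")
        if np.any(values < 0):
            raise ValueError("detector response must be non-negative")
        object.__setattr__(self, "values", values)

    @classmethod
    def linear_ramp(cls, grid: EnergyGrid) -> "DetectorResponse":
        """Energy-integrating detector: signal proportional to photon energy."""
        return cls(grid, grid.energies.copy(), form="linear-ramp")

    @classmethod
    def unity(cls, grid: EnergyGrid) -> "DetectorResponse":
        """Photon-counting detector: equal weight per photon."""
        return cls(grid, np.ones_like(grid.energies), form="unity")


@dataclass(frozen=True)
class FilterSpec:
    """Beam filter: composition, thickness (m) and density (kg/m^3)."""

    composition: Composition = field(default_factory=lambda: Composition({"Al": 1}))
    thickness: float = 0.0
    density: float = ALUMINUM_DENSITY

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("filter thickness must be >= 0")
        if self.density <= 0:
            raise ValueError("filter density must be positive")

    def attenuation(self, xs: CrossSectionSet) -> np.ndarray:
        """Linear attenuation coefficient mu(E) of the filter, 1/m."""
        n = self.density / molar_mass(self.composition)
        return n * xs.compound_sigma(self.composition)


@dataclass(frozen=True)
class AcquisitionModel:
    """Spectra + filter + detector + cross sections: evaluates potencies."""

    spectra: Mapping[float, Spectrum]
    filter: FilterSpec
    detector: DetectorResponse
    xs: CrossSectionSet
    water_density: float = WATER_DENSITY

    def __post_init__(self) -> None:
        for kv, spectrum in self.spectra.items():
            if spectrum.grid.energies.shape != self.xs.grid.energies.shape or np.any(
                spectrum.grid.energies != self.xs.grid.energies
            ):
                raise ValueError(f"spectrum at {kv} kV is not on the cross-section grid")
        object.__setattr__(self, "spectra", dict(self.spectra))

    @property
    def voltages(self) -> tuple[float, ...]:
        return tuple(sorted(self.spectra))

    @property
    def water_molar_density(self) -> float:
        return self.water_density / WATER_MOLAR_MASS

    def weight(self, voltage: float) -> np.ndarray:
        if voltage not in self.spectra:
            raise KeyError(f"no spectrum for {voltage} kV")
        return effective_weight(
            self.spectra[voltage], self.filter, self.detector, self.xs
        )

    def with_filter_thickness(self, thickness: float) -> "AcquisitionModel":
        return replace(self, filter=replace(self.filter, thickness=thickness))


def effective_weight(
    spectrum: Spectrum,
    filt: FilterSpec,
    detector: DetectorResponse,
    xs: CrossSectionSet,
) -> np.ndarray:
    """Detected spectral weight S(E) = fluence x filter transmission x D(E)."""
    if spectrum.grid.energies.shape != xs.grid.energies.shape or np.any(
        spectrum.grid.energies != xs.grid.energies
    ):
        raise ValueError("spectrum and cross sections are on different grids")
    transmission = np.exp(-filt.attenuation(xs) * filt.thickness)
    return spectrum.fluence * transmission * detector.values


def _weighted_sigma(weight: np.ndarray, sigma: np.ndarray, grid: EnergyGrid) -> float:
    return float(np.trapezoid(weight * sigma, grid.energies))


def mu_star(
    c: Composition,
    n: float,
    weight: np.ndarray,
    model: AcquisitionModel,
) -> float:
    """Effective attenuation ratio of a substance at molar density n."""
    if n < 0:
        raise ValueError("molar density must be >= 0")
    grid = model.xs.grid
    denom = model.water_molar_density * _weighted_sigma(
        weight, model.xs.compound_sigma(WATER), grid
    )
    if denom <= 0:
        raise ZeroDivisionError("degenerate spectrum: water term vanishes")
    numer = n * _weighted_sigma(weight, model.xs.compound_sigma(c), grid)
    return numer / denom


def molar_potency(c: Composition, voltage: float, model: AcquisitionModel) -> float:
    """Molar HU potency, AHU m^3 mol^-1; intensive (no density argument)."""
    weight = model.weight(voltage)
    grid = model.xs.grid
    denom = model.water_molar_density * _weighted_sigma(
        weight, model.xs.compound_sigma(WATER), grid
    )
    if denom <= 0:
        raise ZeroDivisionError("degenerate spectrum: water term vanishes")
    return 1000.0 * _weighted_sigma(weight, model.xs.compound_sigma(c), grid) / denom


def mass_potency(c: Composition, voltage: float, model: AcquisitionModel) -> float:
    """Dimensionless mass HU potency; water evaluates to 1 at every voltage."""
    return (
        molar_potency(c, voltage, model)
        * model.water_density
        / (1000.0 * molar_mass(c))
    )


def element_potency_matrix(
    model: AcquisitionModel,
    elements: Sequence[str],
    voltages: Sequence[float] | None = None,
) -> ElementPotencyMatrix:
    """Theoretical molar potencies for single elements at each voltage."""
    if voltages is None:
        voltages = model.voltages
    sigma = model.xs.matrix(elements)  # elements x grid
    grid = model.xs.grid
    sigma_water = model.xs.compound_sigma(WATER)
    columns = []
    for kv in voltages:
        weight = model.weight(kv)
        denom = model.water_molar_density * _weighted_sigma(weight, sigma_water, grid)
        if denom <= 0:
            raise ZeroDivisionError("degenerate spectrum: water term vanishes")
        columns.append(
            1000.0 * np.trapezoid(weight * sigma, grid.energies, axis=1) / denom
        )
    values = np.stack(columns, axis=1)
    return ElementPotencyMatrix(tuple(elements), tuple(float(v) for v in voltages), values)


def load_xcom(
    source: Mapping[str, str | Path] | str | Path,
    grid: EnergyGrid,
    elements: Sequence[str] | None = None,
    energy_unit: str = "MeV",
) -> CrossSectionSet:
    """Read XCOM mass-attenuation exports and resample onto a working grid.

    ``source`` is either a mapping element -> file, or a directory holding
    one file per element named ``<symbol>.<anything>``.  Each file is a
    two-column whitespace or comma table of (energy, mass attenuation in
    cm^2/g); the total-with-coherent-scattering column is the expected
    dialect.  Values are converted to molar attenuation (m^2/mol) and
    interpolated log-log (cross sections are near power laws).
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        files: dict[str, Path] = {}
        for path in sorted(directory.iterdir()):
            symbol = path.stem
            if symbol in ATOMIC_MASS:
                files[symbol] = path
    else:
        files = {symbol: Path(path) for symbol, path in source.items()}
    if elements is not None:
        files = {symbol: files[symbol] for symbol in elements}
    if not files:
        raise ValueError("no XCOM element files found")
    to_kev = {"MeV": 1000.0, "keV": 1.0}[energy_unit]
    sigma: dict[str, np.ndarray] = {}
    for symbol, path in files.items():
        table = np.loadtxt(path, delimiter=None if path.suffix != ".csv" else ",")
        if table.ndim != 2 or table.shape[1] < 2:
            raise ValueError(f"{path}: expected a two-column (energy, mu/rho) table")
        energy_kev = table[:, 0] * to_kev
        # cm^2/g -> m^2/kg is 0.1; times molar mass gives m^2/mol
        molar_sigma = table[:, 1] * 0.1 * ATOMIC_MASS[symbol]
        if grid.energies[0] < energy_kev[0] or grid.energies[-1] > energy_kev[-1]:
            raise ValueError(f"{path}: working grid outside tabulated energy range")
        log_interp = np.interp(
            np.log(grid.energies), np.log(energy_kev), np.log(molar_sigma)
        )
        sigma[symbol] = np.exp(log_interp)
    return CrossSectionSet(grid=grid, sigma=sigma, provenance="xcom")


def load_tasmics(file: str | Path, voltage: float) -> Spectrum:
    """Read a tungsten-spectrum table and return the column for one voltage.

    The expected layout is a whitespace or comma table whose first column
    is photon energy (keV) and whose remaining columns are per-keV fluence,
    one column per tube potential, with a header row naming the potentials
    in kV.  Fluence above the tube voltage is forced to zero.
    """
    frame = pd.read_csv(file, sep=None, engine="python")
    energy = frame.iloc[:, 0].to_numpy(dtype=float)
    columns = {}
    for label in frame.columns[1:]:
        try:
            columns[float(str(label).strip().rstrip("kV").strip())] = label
        except ValueError:
            continue
    if voltage not in columns:
        raise ValueError(
            f"no spectrum column for {voltage} kV (available: {sorted(columns)})"
        )
    fluence = frame[columns[voltage]].to_numpy(dtype=float)
    fluence = np.where(energy > voltage, 0.0, np.clip(fluence, 0.0, None))
    return Spectrum(EnergyGrid(energy), fluence, float(voltage))
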