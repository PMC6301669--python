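"""Synthetic physics and data generators for end-to-end testing.

Every stage of the potency pipeline can run on generated inputs that share
the structural features of the real ones: elemental cross sections with a
photoelectric (a Z^4.5 E^-3) plus Compton (Z x Klein-Nishina) shape, a
bremsstrahlung-like Kramers tube spectrum with a sharp cutoff at the tube
voltage, compound potency tables of the form H = C A + Gaussian noise, and
noisy voxel volumes containing cylindrical bottle phantoms of known mu*.

All generators are deterministic under a fixed seed; each call owns its own
random generator (no global state).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import (
    ATOMIC_MASS,
    ATOMIC_NUMBER,
    WATER_DENSITY,
    Composition,
    CompoundPotencyTable,
    CompoundRecord,
    format_formula,
    molar_mass,
)
from .projection import ElementPotencyMatrix
from .spectral import (
    AcquisitionModel,
    CrossSectionSet,
    DetectorResponse,
    EnergyGrid,
    FilterSpec,
    Spectrum,
    default_grid,
)
from .volume import VoxelVolume

__all__ = [
    "THOMSON_CROSS_SECTION",
    "SyntheticXsParams",
    "NoiseModel",
    "CylinderSpec",
    "BottlePhantom",
    "klein_nishina",
    "synthetic_cross_sections",
    "synthetic_spectrum",
    "build_synthetic_model",
    "simulate_compound_table",
    "simulate_bottle_volume",
]

ELECTRON_RADIUS = 2.8179403262e-15  # m
ELECTRON_REST_ENERGY_KEV = 510.99895
AVOGADRO = 6.02214076e23

#: Low-energy (Thomson) limit of the Klein-Nishina cross section, m^2.
THOMSON_CROSS_SECTION = 8.0 * np.pi / 3.0 * ELECTRON_RADIUS**2


def klein_nishina(energy_kev: np.ndarray | float) -> np.ndarray | float:
    """Total Compton cross section per electron (m^2) at photon energy E.

    Approaches the Thomson cross section 6.652e-29 m^2 as E -> 0.
    """
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_ENERGY_KEV
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = (1.0 + k) / k**2 * (
            2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k
        )
        term2 = np.log1p(2.0 * k) / (2.0 * k)
        term3 = -(1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
        sigma = 2.0 * np.pi * ELECTRON_RADIUS**2 * (term1 + term2 + term3)
    sigma = np.where(k < 1e-6, THOMSON_CROSS_SECTION, sigma)
    return float(sigma) if np.isscalar(energy_kev) else sigma


def _default_photoelectric_scale() -> float:
    """Photoelectric amplitude making both terms equal for O at 30 keV.

    A single calibration point fixes the photoelectric/Compton balance at a
    physically plausible level for diagnostic energies; the Z^4.5 / E^-3
    scaling then carries the element and energy dependence.
    """
    z = 8.0
    return (
        z * klein_nishina(30.0) * AVOGADRO / (z**4.5 * 30.0**-3.0)
    )


@dataclass(frozen=True)
class SyntheticXsParams:
    """Parameters of the two-term synthetic cross-section model."""

    photoelectric_scale: float = field(default_factory=_default_photoelectric_scale)
    photoelectric_Z_exponent: float = 4.5
    photoelectric_E_exponent: float = -3.0

    def __post_init__(self) -> None:
        if self.photoelectric_scale <= 0:
            raise ValueError("photoelectric scale must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on molar potency, with a seed."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def _symbols(elements: Sequence[int | str]) -> list[str]:
    number_to_symbol = {z: s for s, z in ATOMIC_NUMBER.items()}
    out = []
    for e in elements:
        if isinstance(e, str):
            if e not in ATOMIC_NUMBER:
                raise ValueError(f"unknown element {e!r}")
            out.append(e)
        else:
            if e not in number_to_symbol:
                raise ValueError(f"unsupported atomic number Z={e} (1..20 available)")
            out.append(number_to_symbol[e])
    return out


def synthetic_cross_sections(
    elements: Sequence[int | str],
    grid: EnergyGrid,
    params: SyntheticXsParams | None = None,
) -> CrossSectionSet:
    """Molar attenuation sigma_Z(E) = a Z^4.5 E^-3 + Z sigma_KN(E) N_A.

    The first term mimics photoelectric absorption, the second incoherent
    scattering from Z quasi-free electrons; together they reproduce the
    qualitative shape of tabulated cross sections below 200 keV (strictly
    positive, decreasing in energy, steeper for high Z).
    """
    if not elements:
        raise ValueError("element list is empty")
    if grid.energies[0] < 1.0 or grid.energies[-1] > 200.0:
        raise ValueError("synthetic cross sections support 1-200 keV only")
    p = params or SyntheticXsParams()
    compton_molar = klein_nishina(grid.energies) * AVOGADRO
    sigma = {}
    for symbol in _symbols(elements):
        z = float(ATOMIC_NUMBER[symbol])
        photo = (
            p.photoelectric_scale
            * z**p.photoelectric_Z_exponent
            * grid.energies**p.photoelectric_E_exponent
        )
        sigma[symbol] = photo + z * compton_molar
    return CrossSectionSet(grid=grid, sigma=sigma, provenance="synthetic")


def synthetic_spectrum(kv: float, grid: EnergyGrid) -> Spectrum:
    """Kramers-shaped tube fluence: Phi(E) ~ (E0/E - 1) below E0 = kV keV.

    A continuum-only stand-in for a tungsten-anode spectrum (characteristic
    lines omitted), with the hard cutoff at the tube voltage.
    """
    if not 40.0 <= kv <= 150.0:
        raise ValueError("tube voltage must lie in [40, 150] kV")
    fluence = np.clip(kv / grid.energies - 1.0, 0.0, None)
    fluence[grid.energies > kv] = 0.0
    return Spectrum(grid=grid, fluence=fluence, tube_voltage=float(kv))


def build_synthetic_model(
    voltages: Sequence[float] = (80.0, 100.0, 120.0, 140.0),
    elements: Sequence[str] | None = None,
    filter_thickness: float = 0.0,
    params: SyntheticXsParams | None = None,
    grid: EnergyGrid | None = None,
) -> AcquisitionModel:
    """Assemble a complete synthetic acquisition model.

    Defaults: all 20 supported elements, a 5 keV..max-voltage grid at 1 keV
    steps, an aluminum filter of the given thickness, and an
    energy-integrating (linear-ramp) detector.
    """
    if grid is None:
        grid = default_grid(max_kev=max(voltages))
    if elements is None:
        elements = list(ATOMIC_MASS)
    xs = synthetic_cross_sections(list(elements), grid, params)
    spectra = {float(kv): synthetic_spectrum(float(kv), grid) for kv in voltages}
    return AcquisitionModel(
        spectra=spectra,
        filter=FilterSpec(thickness=filter_thickness),
        detector=DetectorResponse.linear_ramp(grid),
        xs=xs,
    )


def simulate_compound_table(
    A_true: ElementPotencyMatrix,
    compounds: Sequence[Composition | tuple[str, Composition]],
    noise: NoiseModel = NoiseModel(),
    water_density: float = WATER_DENSITY,
) -> CompoundPotencyTable:
    """Generate a measured-style potency table from a known elemental matrix.

    Molar potencies are H = C A_true + eps with eps ~ N(0, sd^2) i.i.d.,
    then converted to the dimensionless mass potencies a scanner reports.
    """
    rng = np.random.default_rng(noise.seed)
    named: list[tuple[str, Composition]] = []
    for item in compounds:
        if isinstance(item, tuple):
            named.append(item)
        else:
            named.append((format_formula(item), item))
    element_index = {e: i for i, e in enumerate(A_true.elements)}
    records = []
    for name, comp in named:
        missing = [e for e in comp if e not in element_index]
        if missing:
            raise ValueError(f"{name}: elements {missing} absent from A_true")
        counts = np.zeros(len(A_true.elements))
        for symbol, count in comp.items():
            counts[element_index[symbol]] = count
        molar = counts @ A_true.values  # AHU m^3 / mol at each voltage
        molar = molar + rng.normal(0.0, noise.sd, size=molar.shape)
        mm = molar_mass(comp)
        eta = molar * water_density / (1000.0 * mm)
        records.append(
            CompoundRecord(
                name=name,
                formula=format_formula(comp),
                composition=comp,
                supplier="synthetic",
                mass_potency={kv: float(v) for kv, v in zip(A_true.voltages, eta)},
            )
        )
    return CompoundPotencyTable(records=tuple(records), voltages=A_true.voltages)


@dataclass(frozen=True)
class CylinderSpec:
    """Axis-aligned (z) cylinder: fill radius, wall thickness, height; metres."""

    center: tuple[float, float, float]
    radius: float
    height: float
    wall_thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.radius < 0 or self.height <= 0 or self.wall_thickness < 0:
            raise ValueError("cylinder dimensions must be non-negative (height > 0)")


@dataclass(frozen=True)
class BottlePhantom:
    """A simulated scan plus its exact discretized ground truth."""

    volume: VoxelVolume
    fill_mask: np.ndarray
    wall_mask: np.ndarray
    integral_mu_star: float  # fill + wall, m^3
    integral_mu_star_fill: float  # fill only, m^3
    fill_volume: float  # m^3


def simulate_bottle_volume(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    geometry: CylinderSpec,
    mu_star_fill: float,
    mu_star_wall: float = 1.0,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
    blur_sigma_vox: float = 0.0,
) -> BottlePhantom:
    """Simulate a CT scan of a cylindrical bottle in air.

    Voxels inside the fill get HU = 1000 (mu*_fill - 1), the wall shell
    HU = 1000 (mu*_wall - 1), everything else air at -1000 HU (mu* ~ 0);
    i.i.d. Gaussian noise of the given sd is added everywhere.
    ``blur_sigma_vox`` smooths the mu* map with a Gaussian kernel (in
    voxels) to emulate the finite spatial resolution of reconstruction;
    the blur conserves the total mu* integral.  The exact mu* integrals of
    the discretized phantom are returned for use as an oracle.
    """
    nx, ny, nz = shape
    sx, sy, sz = spacing
    if min(spacing) <= 0:
        raise ValueError("voxel spacing must be positive")
    cx, cy, cz = geometry.center
    outer = geometry.radius + geometry.wall_thickness
    if (
        cx - outer < 0 or cx + outer > nx * sx
        or cy - outer < 0 or cy + outer > ny * sy
        or cz - geometry.height / 2 < 0 or cz + geometry.height / 2 > nz * sz
    ):
        raise ValueError("cylinder does not fit inside the volume")
    x = (np.arange(nx) + 0.5) * sx
    y = (np.arange(ny) + 0.5) * sy
    z = (np.arange(nz) + 0.5) * sz
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    in_z = np.abs(z - cz) <= geometry.height / 2
    fill_xy = r2 <= geometry.radius**2
    wall_xy = (r2 <= outer**2) & ~fill_xy
    fill_mask = fill_xy[:, :, None] & in_z[None, None, :]
    wall_mask = wall_xy[:, :, None] & in_z[None, None, :]

    mu = np.zeros(shape)
    mu[fill_mask] = mu_star_fill
    mu[wall_mask] = mu_star_wall
    if blur_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        mu = gaussian_filter(mu, sigma=blur_sigma_vox, mode="constant", cval=0.0)
    hu = 1000.0 * (mu - 1.0)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd_hu, size=shape)

    voxel = sx * sy * sz
    integral_fill = float(fill_mask.sum()) * mu_star_fill * voxel
    integral = integral_fill + float(wall_mask.sum()) * mu_star_wall * voxel
    return BottlePhantom(
        volume=VoxelVolume(hu, spacing=spacing),
        fill_mask=fill_mask,
        wall_mask=wall_mask,
        integral_mu_star=integral,
        integral_mu_star_fill=integral_fill,
        fill_volume=float(fill_mask.sum()) * voxel,
    )
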