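"""Fitting the one free model parameter: the aluminum filter thickness.

The acquisition model is fully specified except for the filtration of the
tube spectrum, summarized as an equivalent aluminum thickness t.  It is fit
by least squares on the logarithm of the potencies (so that low-Z elements,
whose potencies are orders of magnitude smaller, are not underweighted):

    chi2(t) = sum over (element, voltage) of (ln p_obs - ln p_model(t))^2.

The 95% confidence interval comes from the chi-square profile: after
rescaling the residual variance by chi2_min/(N-1), thicknesses with
Delta chi2 <= 3.84 (the 95% point of chi-square with one degree of freedom)
are retained.  The interval may be asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .projection import ElementPotencyMatrix
from .spectral import WATER, AcquisitionModel, element_potency_matrix

__all__ = ["FilterFitResult", "log_chi2", "fit_filter_thickness"]

DELTA_CHI2_95 = 3.841458820694124  # chi2(1 dof) 95% quantile


@dataclass(frozen=True)
class FilterFitResult:
    """Best-fit thickness (m), its 95% CI, and the chi-square profile."""

    thickness: float
    ci95: tuple[float, float]
    chi2_min: float
    profile: tuple[tuple[float, float], ...]
    ci_on_boundary: bool = False


class _PotencyEvaluator:
    """Precomputed arrays for fast potency evaluation versus thickness."""

    def __init__(self, model: AcquisitionModel, elements: Sequence[str],
                 voltages: Sequence[float]):
        grid = model.xs.grid
        self.energies = grid.energies
        self.mu_filter = model.filter.attenuation(model.xs)
        self.base = np.stack(
            [model.spectra[kv].fluence * model.detector.values for kv in voltages]
        )  # voltages x grid
        self.sigma = model.xs.matrix(elements)  # elements x grid
        self.sigma_water = model.xs.compound_sigma(WATER)
        self.n_water = model.water_molar_density

    def potencies(self, thickness: float) -> np.ndarray:
        """Elements x voltages molar potency matrix at the given thickness."""
        weights = self.base * np.exp(-self.mu_filter * thickness)[None, :]
        denom = self.n_water * np.trapezoid(
            weights * self.sigma_water[None, :], self.energies, axis=1
        )
        numer = np.trapezoid(
            weights[:, None, :] * self.sigma[None, :, :], self.energies, axis=2
        )  # voltages x elements
        return 1000.0 * (numer / denom[:, None]).T


def log_chi2(
    thickness: float,
    observed: ElementPotencyMatrix,
    model: AcquisitionModel,
) -> float:
    """Sum of squared log-residuals between observed and model potencies."""
    if np.any(observed.values <= 0):
        raise ValueError("observed potencies must be positive")
    predicted = element_potency_matrix(
        model.with_filter_thickness(thickness), observed.elements, observed.voltages
    )
    return float(np.sum((np.log(observed.values) - np.log(predicted.values)) ** 2))


def fit_filter_thickness(
    observed: ElementPotencyMatrix,
    model: AcquisitionModel,
    search: tuple[float, float] = (0.0, 0.06),
    tolerance: float = 1e-5,
    profile_points: int = 121,
) -> FilterFitResult:
    """Minimize the log chi-square over thickness and profile the 95% CI.

    ``search`` is the bracketing interval in metres; the minimizer is
    located to ``tolerance`` (default 0.01 mm).  A minimum on the search
    boundary raises, since the bracket then does not contain the optimum.
    """
    lo, hi = search
    if not 0 <= lo < hi:
        raise ValueError("search interval must satisfy 0 <= lo < hi")
    if np.any(observed.values <= 0):
        raise ValueError("observed potencies must be positive")
    evaluator = _PotencyEvaluator(model, observed.elements, observed.voltages)
    log_obs = np.log(observed.values)

    def chi2(t: float) -> float:
        return float(np.sum((log_obs - np.log(evaluator.potencies(t))) ** 2))

    result = minimize_scalar(chi2, bounds=(lo, hi), method="bounded",
                             options={"xatol": tolerance})
    t_best = float(result.x)
    chi2_min = float(result.fun)
    if t_best - lo < 2 * tolerance and chi2(lo) <= chi2_min + 1e-12:
        raise ValueError("chi-square minimum lies on the lower search boundary")
    if hi - t_best < 2 * tolerance and chi2(hi) <= chi2_min + 1e-12:
        raise ValueError("chi-square minimum lies on the upper search boundary")

    n_cells = observed.values.size
    variance = max(chi2_min / (n_cells - 1), 1e-300)
    level = chi2_min + DELTA_CHI2_95 * variance

    def excess(t: float) -> float:
        return chi2(t) - level

    boundary = False
    if excess(lo) <= 0:
        ci_lo, boundary = lo, True
    else:
        ci_lo = float(brentq(excess, lo, t_best, xtol=tolerance))
    if excess(hi) <= 0:
        ci_hi, boundary = hi, True
    else:
        ci_hi = float(brentq(excess, t_best, hi, xtol=tolerance))

    grid = np.linspace(lo, hi, profile_points)
    profile = tuple((float(t), chi2(float(t))) for t in grid)
    return FilterFitResult(
        thickness=t_best,
        ci95=(ci_lo, ci_hi),
        chi2_min=chi2_min,
        profile=profile,
        ci_on_boundary=boundary,
    )
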