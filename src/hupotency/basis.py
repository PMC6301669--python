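"""Material basis: SVD of the elemental potency matrix and rank selection.

The elements x voltages potency matrix is factored A = U diag(s) V^T.  The
left singular vectors are abstract "materials" (element-concentration
combinations) ordered by how strongly they move the CT number; the right
singular vectors live over tube voltages.  The number of components that
rise above measurement noise — the intrinsic dimensionality of what a
multi-voltage scan can observe — is chosen by the Bayesian information
criterion applied to rank-k fits of the compound-level observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .materials import ATOMIC_NUMBER
from .projection import DesignMatrix, ElementPotencyMatrix

__all__ = [
    "SVDBasis",
    "BICCurve",
    "svd_basis",
    "rank_truncate",
    "bic_curve",
    "left_power_law",
]


@dataclass(frozen=True)
class SVDBasis:
    """SVD of an element-potency matrix with a fixed sign convention."""

    elements: tuple[str, ...]
    voltages: tuple[float, ...]
    singular_values: np.ndarray
    left_vectors: np.ndarray  # elements x k, orthonormal columns
    right_vectors: np.ndarray  # voltages x k, orthonormal columns

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        if k is None:
            k = len(self.singular_values)
        if not 1 <= k <= len(self.singular_values):
            raise ValueError(f"rank k={k} out of range")
        return (
            self.left_vectors[:, :k]
            * self.singular_values[:k]
        ) @ self.right_vectors[:, :k].T


def svd_basis(A: ElementPotencyMatrix) -> SVDBasis:
    """Thin SVD with a deterministic sign convention.

    Each left/right vector pair is flipped so the largest-magnitude
    component of the left vector is positive, making the factorization
    reproducible across linear-algebra backends.
    """
    U, s, Vt = np.linalg.svd(A.values, full_matrices=False)
    for j in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, j]))
        if U[pivot, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return SVDBasis(
        elements=A.elements,
        voltages=A.voltages,
        singular_values=s,
        left_vectors=U,
        right_vectors=Vt.T,
    )


def rank_truncate(basis: SVDBasis, k: int) -> np.ndarray:
    """Best rank-k approximation (Eckart-Young) of the decomposed matrix."""
    return basis.reconstruct(k)


@dataclass(frozen=True)
class BICCurve:
    """BIC versus retained rank; the argmin selects the dimensionality."""

    entries: dict[int, float]
    rss: dict[int, float]
    argmin: int
    n_observations: int

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.entries)
        return pd.DataFrame(
            {"k": ks, "rss": [self.rss[k] for k in ks], "bic": [self.entries[k] for k in ks]}
        ).set_index("k")


def bic_curve(
    H: pd.DataFrame | np.ndarray,
    C: DesignMatrix,
    A: ElementPotencyMatrix,
    kmax: int | None = None,
    n_params: Literal["rank", "full"] = "rank",
    likelihood: Literal["mle", "fixed_sigma"] = "mle",
    sigma: float | None = None,
    rss_mode: Literal["truncate", "refit"] = "truncate",
    rss_floor: float = 1e-25,
) -> BICCurve:
    """BIC of rank-k models of A fitted to the compound observations.

    For each k a rank-k surrogate of the elemental matrix is scored by its
    residual sum of squares over all compound x voltage cells (N_o), and

        B(k) = N_p ln N_o - 2 ln L,

    the conventional minimized form of the criterion, is recorded.  With
    the default Gaussian profile likelihood,
    2 ln L = -N_o (ln(2 pi RSS/N_o) + 1); with ``likelihood="fixed_sigma"``
    the external-variance form 2 ln L = -RSS/sigma^2 is used instead.

    ``rss_mode="truncate"`` (default) uses RSS_k = ||C A_k - H||^2 with A_k
    the Frobenius-optimal truncation of A; ``"refit"`` re-estimates the
    per-voltage coefficients within the span of the first k left singular
    vectors (the best fit the retained basis allows, nested across k).
    N_p counts one parameter per retained singular component by default
    (``n_params="rank"``); ``"full"`` counts k (rows + cols - k), the free
    parameters of a rank-k matrix.  The defaults score the measured data,
    whose residual floor is model error; for rank selection on
    noise-dominated synthetic data the consistent combination is
    ``rss_mode="refit", n_params="full"``.
    """
    values = H.to_numpy(dtype=float) if isinstance(H, pd.DataFrame) else np.asarray(H, float)
    if values.shape[0] != len(C.compounds):
        raise ValueError("H rows do not match the design matrix")
    basis = svd_basis(A)
    max_rank = len(basis.singular_values)
    if kmax is None:
        kmax = max_rank
    if not 1 <= kmax <= max_rank:
        raise ValueError(f"kmax={kmax} out of range 1..{max_rank}")
    n_obs = values.size
    n_rows, n_cols = A.values.shape
    entries: dict[int, float] = {}
    rss_map: dict[int, float] = {}
    for k in range(1, kmax + 1):
        if rss_mode == "truncate":
            residual = C.counts @ basis.reconstruct(k) - values
        elif rss_mode == "refit":
            design = C.counts @ basis.left_vectors[:, :k]
            coefficients, *_ = np.linalg.lstsq(design, values, rcond=None)
            residual = design @ coefficients - values
        else:
            raise ValueError(f"unknown rss_mode {rss_mode!r}")
        rss = float(np.sum(residual**2))
        rss_map[k] = rss
        if likelihood == "mle":
            if rss <= rss_floor:
                warnings.warn(
                    "RSS is at the numerical floor; Gaussian MLE is degenerate",
                    RuntimeWarning,
                    stacklevel=2,
                )
                rss = rss_floor
            two_ln_l = -n_obs * (np.log(2.0 * np.pi * rss / n_obs) + 1.0)
        elif likelihood == "fixed_sigma":
            if sigma is None or sigma <= 0:
                raise ValueError("fixed_sigma likelihood requires sigma > 0")
            two_ln_l = -rss / sigma**2
        else:
            raise ValueError(f"unknown likelihood {likelihood!r}")
        np_k = k if n_params == "rank" else k * (n_rows + n_cols - k)
        entries[k] = float(np_k * np.log(n_obs) - two_ln_l)
    argmin = min(entries, key=entries.get)
    return BICCurve(entries=entries, rss=rss_map, argmin=argmin, n_observations=n_obs)


def left_power_law(
    basis: SVDBasis,
    elements: Sequence[str] | None = None,
    fit: Literal["linear", "loglog"] = "linear",
) -> float:
    """Power-law exponent b of the first left singular vector, |u1| ~ a Z^b.

    ``fit="linear"`` performs the least-squares fit u1 = a Z^b in linear
    coordinates (residuals weighted by the component values themselves,
    emphasising the large high-Z components); ``fit="loglog"`` regresses
    log|u1| on log Z with equal weight per element.  The two differ when
    the curve is not an exact power law.
    """
    if elements is None:
        elements = basis.elements
    if len(elements) < 3:
        raise ValueError("need at least 3 elements to fit a power law")
    index = {e: i for i, e in enumerate(basis.elements)}
    u1 = np.array([basis.left_vectors[index[e], 0] for e in elements])
    if np.any(u1 == 0):
        raise ValueError("first left singular vector has zero components")
    z = np.array([ATOMIC_NUMBER[e] for e in elements], dtype=float)
    magnitude = np.abs(u1)
    log_slope, log_intercept = np.polyfit(np.log(z), np.log(magnitude), 1)
    if fit == "loglog":
        return float(log_slope)
    if fit != "linear":
        raise ValueError(f"unknown fit mode {fit!r}")
    (amplitude, exponent), _ = curve_fit(
        lambda zz, a, b: a * zz**b,
        z,
        magnitude,
        p0=[float(np.exp(log_intercept)), float(log_slope)],
        maxfev=10000,
    )
    return float(exponent)
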