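"""Least-squares projection of compound potencies onto elemental potencies.

Under the independent-atom approximation a compound's molar HU potency is
the stoichiometric sum of its elements' potencies, H = C A, where C counts
atoms per formula unit.  Given measured H (compounds x voltages) the
elemental matrix A (elements x voltages) is recovered per voltage by
minimizing ||C A - H||^2_F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .materials import (
    ATOMIC_NUMBER,
    STUDY_ELEMENTS,
    CompoundPotencyTable,
    CompoundRecord,
    compound_molar_potency,
)

__all__ = [
    "DesignMatrix",
    "ElementPotencyMatrix",
    "build_design_matrix",
    "compound_potency_matrix",
    "project_to_elements",
]


@dataclass(frozen=True)
class DesignMatrix:
    """Atom-count matrix: rows are compounds, columns are elements."""

    compounds: tuple[str, ...]
    elements: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.compounds), len(self.elements)):
            raise ValueError("counts shape does not match labels")
        if np.any(counts < 0):
            raise ValueError("atom counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.compounds, columns=self.elements)


@dataclass(frozen=True)
class ElementPotencyMatrix:
    """Molar HU potencies (AHU m^3 mol^-1): elements x tube voltages."""

    elements: tuple[str, ...]
    voltages: tuple[float, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.elements), len(self.voltages)):
            raise ValueError("values shape does not match labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("potency values must be finite")
        object.__setattr__(self, "values", values)

    def row(self, element: str) -> np.ndarray:
        return self.values[self.elements.index(element)]

    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[e] for e in self.elements], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.elements, columns=self.voltages)
        frame.index.name = "element"
        return frame


def build_design_matrix(
    compounds: Sequence[CompoundRecord],
    elements: Sequence[str] = STUDY_ELEMENTS,
) -> DesignMatrix:
    """Build the compound x element atom-count matrix C."""
    elements = tuple(elements)
    index = {e: j for j, e in enumerate(elements)}
    counts = np.zeros((len(compounds), len(elements)))
    for i, record in enumerate(compounds):
        for symbol, count in record.composition.items():
            if symbol not in index:
                raise ValueError(
                    f"compound {record.name!r} contains element {symbol!r} "
                    "outside the element list"
                )
            counts[i, index[symbol]] = count
    return DesignMatrix(tuple(r.name for r in compounds), elements, counts)


def compound_potency_matrix(
    table: CompoundPotencyTable,
    water_density: float = 998.0,
) -> pd.DataFrame:
    """Molar-potency matrix H (compounds x voltages, AHU m^3 mol^-1)."""
    rows = {
        r.name: compound_molar_potency(r, water_density) for r in table.records
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(table.voltages)]
    frame.index.name = "compound"
    return frame


def project_to_elements(
    H: pd.DataFrame | np.ndarray,
    C: DesignMatrix,
    voltages: Sequence[float] | None = None,
) -> ElementPotencyMatrix:
    """Solve A = argmin ||C A - H||^2_F, one voltage column at a time.

    Uses an orthogonal-decomposition least-squares solver; the residual
    C A - H is orthogonal to the column space of C at the solution.  C must
    have full column rank.
    """
    if isinstance(H, pd.DataFrame):
        if tuple(H.index) != C.compounds:
            raise ValueError("H rows are not aligned with the design matrix")
        if voltages is None:
            voltages = tuple(float(v) for v in H.columns)
        values = H.to_numpy(dtype=float)
    else:
        values = np.asarray(H, dtype=float)
        if voltages is None:
            raise ValueError("voltages required when H is a bare array")
    if values.shape[0] != len(C.compounds):
        raise ValueError("H row count does not match the design matrix")
    rank = np.linalg.matrix_rank(C.counts)
    if rank < len(C.elements):
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {len(C.elements)})"
        )
    solution, *_ = np.linalg.lstsq(C.counts, values, rcond=None)
    return ElementPotencyMatrix(C.elements, tuple(float(v) for v in voltages), solution)
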