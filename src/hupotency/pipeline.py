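"""The end-to-end experimental analysis on the packaged powder table.

Chains the steps a user would otherwise wire by hand: load the measured
mass potencies, convert to molecular molar potencies, project onto the 13
study elements, and decompose the resulting elements x voltages matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .basis import BICCurve, SVDBasis, bic_curve, left_power_law, svd_basis
from .materials import STUDY_ELEMENTS, WATER_DENSITY, CompoundPotencyTable, load_powder_table
from .projection import (
    DesignMatrix,
    ElementPotencyMatrix,
    build_design_matrix,
    compound_potency_matrix,
    project_to_elements,
)

__all__ = ["ExperimentalAnalysis", "run_experimental_analysis"]


@dataclass(frozen=True)
class ExperimentalAnalysis:
    """All intermediate products of the powder-table analysis."""

    table: CompoundPotencyTable
    H: pd.DataFrame  # compounds x voltages molar potencies
    C: DesignMatrix
    A: ElementPotencyMatrix  # elements x voltages
    basis: SVDBasis
    bic: BICCurve

    @property
    def power_law_exponent(self) -> float:
        return left_power_law(self.basis)


def run_experimental_analysis(
    water_density: float = WATER_DENSITY,
) -> ExperimentalAnalysis:
    """Run the powder-table pipeline and return every intermediate object."""
    table = load_powder_table()
    H = compound_potency_matrix(table, water_density)
    C = build_design_matrix(table.records, STUDY_ELEMENTS)
    A = project_to_elements(H, C)
    basis = svd_basis(A)
    bic = bic_curve(H, C, A)
    return ExperimentalAnalysis(table=table, H=H, C=C, A=A, basis=basis, bic=bic)
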