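"""Cellular unit conversions: fmol/ug -> amol/cell -> % of total cell
protein -> uM in the chloroplast.

The chain rests on three cellular constants: protein content per cell
(27.6 pg for the UVM4 strain; strain-specific and configurable), the cell
volume (270 um^3, with 1 um^3 = 1 fL) and the fraction of the cell volume
occupied by the chloroplast (0.5). All conversions are linear, so protein
rank order is preserved across every derived unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "CellModel",
    "AbundanceRecord",
    "amol_per_cell",
    "mass_fraction",
    "chloroplast_concentration_uM",
    "transgene_contribution_percent",
    "contextualize",
]


@dataclass(frozen=True)
class CellModel:
    """Cellular constants of the quantified strain."""

    protein_pg_per_cell: float = 27.6
    cell_volume_fL: float = 270.0
    chloroplast_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.protein_pg_per_cell <= 0:
            raise ValueError("protein_pg_per_cell must be positive")
        if self.cell_volume_fL <= 0:
            raise ValueError("cell_volume_fL must be positive")
        if not 0 < self.chloroplast_fraction <= 1:
            raise ValueError("chloroplast_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AbundanceRecord:
    protein: str
    amol_per_cell: float
    mass_fraction_percent: float
    chloroplast_uM: float
    mature_mw_da: "float | None" = None


def amol_per_cell(fmol_per_ug: float, cell: CellModel = CellModel()) -> float:
    """amol of protein per cell from fmol per ug of total cell protein:
    ``amol = fmol_per_ug * protein_pg_per_cell / 1000``."""
    if fmol_per_ug < 0:
        raise ValueError("fmol_per_ug must be non-negative")
    return fmol_per_ug * cell.protein_pg_per_cell / 1000.0


def mass_fraction(
    amol: float, mature_mw_da: float, cell: CellModel = CellModel()
) -> float:
    """Percent of total cell protein contributed by ``amol`` per cell of a
    protein whose mature chain weighs ``mature_mw_da``."""
    if mature_mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    if amol < 0:
        raise ValueError("amol must be non-negative")
    grams = amol * 1e-18 * mature_mw_da
    return grams / (cell.protein_pg_per_cell * 1e-12) * 100.0


def chloroplast_concentration_uM(amol: float, cell: CellModel = CellModel()) -> float:
    """Molar concentration (uM) in the chloroplast:
    ``amol / (cell_volume_fL * chloroplast_fraction) * 1000``."""
    if amol < 0:
        raise ValueError("amol must be non-negative")
    volume_fL = cell.cell_volume_fL * cell.chloroplast_fraction
    if volume_fL <= 0:
        raise ValueError("chloroplast volume must be positive")
    return amol / volume_fL * 1000.0


def transgene_contribution_percent(
    native_percent: float, fold_overexpression: float
) -> float:
    """Mass fraction contributed by a transgene that raises a protein's
    total level ``fold_overexpression``-fold over a ``native_percent``
    baseline: ``native * (fold - 1)``."""
    if native_percent < 0:
        raise ValueError("native_percent must be non-negative")
    if fold_overexpression < 1:
        raise ValueError("fold_overexpression must be >= 1")
    return native_percent * (fold_overexpression - 1.0)


def contextualize(
    abundances: pd.DataFrame,
    cell: CellModel = CellModel(),
    mature_mw: "Mapping[str, float] | None" = None,
) -> pd.DataFrame:
    """Apply the full conversion chain to a per-protein abundance table.

    ``abundances`` must carry a ``protein`` column and either
    ``fmol_per_ug`` or ``amol_per_cell``. Mass fractions are emitted only
    for proteins present in ``mature_mw`` (NaN otherwise).
    """
    if "protein" not in abundances.columns:
        raise ValueError("abundance table needs a 'protein' column")
    df = abundances.copy()
    if "amol_per_cell" not in df.columns:
        if "fmol_per_ug" not in df.columns:
            raise ValueError("need a 'fmol_per_ug' or 'amol_per_cell' column")
        df["amol_per_cell"] = [amol_per_cell(v, cell) for v in df["fmol_per_ug"]]
    mws = dict(mature_mw) if mature_mw else {}
    df["mature_mw_da"] = [mws.get(p) for p in df["protein"]]
    df["mass_fraction_percent"] = [
        mass_fraction(a, mw, cell) if mw is not None else float("nan")
        for a, mw in zip(df["amol_per_cell"], df["mature_mw_da"])
    ]
    df["chloroplast_uM"] = [
        chloroplast_concentration_uM(a, cell) for a in df["amol_per_cell"]
    ]
    return df
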