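"""Packaged reference data for the Chlamydomonas Calvin-Benson cycle study.

Loaders for the published per-peptide quantification table, the
cross-method comparison table, the CBC reaction map, a synthetic
metabolite table and a synthetic mature-chain FASTA, plus factories for
the CBC QconCAT construct and the study's spike-in design.

Documented study constants live here as module-level values: the CBC
construct molecular weight (47,921 Da) and extinction coefficient
(37,400 M-1 cm-1) were determined spectroscopically on the purified
protein, and the metabolic labeling efficiency was measured at 99.39%.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .chemistry import ProteinSequence, QPeptide, molecular_weight_average, read_fasta
from .construct import QconCATConstruct, SpikeSeries

__all__ = [
    "CBC_QPROT_MW",
    "CBC_QPROT_EPSILON_280",
    "LABELING_EFFICIENCY",
    "SAMPLE_PROTEIN_UG",
    "table1_quantification",
    "table2_method_comparison",
    "cbc_qpeptides",
    "cbc_construct",
    "default_spike_series",
    "reaction_map",
    "synthetic_metabolites",
    "mature_proteins",
    "mature_molecular_weights",
]

#: Average molecular weight of the CBC QconCAT construct, Da.
CBC_QPROT_MW = 47921.0
#: Extinction coefficient of the CBC QconCAT at 280 nm, M-1 cm-1.
CBC_QPROT_EPSILON_280 = 37400.0
#: Measured 15N labeling efficiency of the heavy construct.
LABELING_EFFICIENCY = 0.9939
#: Micrograms of total cell protein per digest.
SAMPLE_PROTEIN_UG = 20.0

_DATA = resources.files("qconpipe.data")


def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    with _DATA.joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#", **kwargs)


def table1_quantification() -> pd.DataFrame:
    """Published per-peptide quantification of the 12 CBC subunits.

    Columns: protein, peptide, mean/SD/n of the per-peptide amol-per-cell
    values, the per-protein pooled median, the protein's percentage of
    total cell protein, and the externally computed ionization rank/score.
    """
    return _read_csv("cbc_table1_quantification.csv")


def table2_method_comparison() -> pd.DataFrame:
    """Published cross-method comparison (QconCAT vs iBAQ rank, Mass
    Western amounts and emPAI-derived chloroplast concentrations)."""
    return _read_csv("cbc_table2_method_comparison.csv")


def cbc_qpeptides(labeling_efficiency: float = LABELING_EFFICIENCY) -> list[QPeptide]:
    """The Q-peptides of the CBC panel as :class:`QPeptide` objects."""
    df = table1_quantification()
    return [
        QPeptide.from_sequence(
            row.peptide,
            row.protein,
            labeling_efficiency=labeling_efficiency,
            ionization_rank=int(row.dpop_rank),
            ionization_score=float(row.dpop_score),
        )
        for row in df.itertuples()
    ]


def cbc_construct(labeling_efficiency: float = LABELING_EFFICIENCY) -> QconCATConstruct:
    """The CBC QconCAT construct with its documented constants.

    The construct's own sequence (tag, linkers) is not part of the
    packaged data, so the molecular weight and extinction coefficient are
    the documented spectroscopic constants rather than recomputed values.
    """
    return QconCATConstruct(
        name="CBC-Qprot",
        peptides=tuple(cbc_qpeptides(labeling_efficiency)),
        mw=CBC_QPROT_MW,
        epsilon_280=CBC_QPROT_EPSILON_280,
        labeling_efficiency=labeling_efficiency,
    )


def default_spike_series(
    n_replicates: int = 6,
    qprot: str = "CBC-Qprot",
    sample_protein_ug: float = SAMPLE_PROTEIN_UG,
) -> list[SpikeSeries]:
    """The study's spike-in design: replicates 1-3 receive 12.5/25/50/100 ng
    of construct, replicates 4 onward 25/50/100/200 ng, each into 20 ug of
    total cell protein."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    low = (12.5, 25.0, 50.0, 100.0)
    high = (25.0, 50.0, 100.0, 200.0)
    return [
        SpikeSeries(
            qprot=qprot,
            amounts_ng=low if i < 3 else high,
            sample_protein_ug=sample_protein_ug,
        )
        for i in range(n_replicates)
    ]


def reaction_map() -> pd.DataFrame:
    """CBC reaction map: enzyme, catalytic subunit(s), reversibility and
    substrate/product metabolites, mirroring the cycle's 11 enzymes."""
    return _read_csv("cbc_reaction_map.csv")


def synthetic_metabolites() -> pd.DataFrame:
    """SYNTHETIC chloroplast metabolite concentrations (uM) for exercising
    the occupancy stage; see the file header for provenance."""
    return _read_csv("metabolites_synthetic.csv")


def mature_proteins() -> list[ProteinSequence]:
    """SYNTHETIC stand-in mature chains for the 12 CBC subunits.

    The real mature sequences (transit peptide removed) are not packaged;
    these deterministic surrogate sequences reproduce the mature
    molecular weights implied by the published per-cell amounts and
    mass fractions, which is all the mass-fraction arithmetic needs.
    """
    with resources.as_file(_DATA.joinpath("mature_proteins_synthetic.fasta")) as p:
        return read_fasta(p, is_mature=True)


def mature_molecular_weights(
    overrides: "dict[str, float] | None" = None,
) -> dict[str, float]:
    """Average molecular weights (Da) of the mature chains, from the
    packaged FASTA, with optional per-protein overrides."""
    mws = {p.identifier: molecular_weight_average(p) for p in mature_proteins()}
    if overrides:
        mws.update(overrides)
    return mws
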