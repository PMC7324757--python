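"""QconCAT construct model and spike-in bookkeeping.

A QconCAT is an artificial protein of concatenated proteotypic peptides
expressed with heavy isotopes. Because the peptides sit on one
polypeptide, tryptic digestion releases them in a strict 1:1 molar ratio:
a spiked mass of construct therefore carries an identical molar amount of
every heavy peptide, which is the calibration anchor of the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chemistry import QPeptide

__all__ = [
    "QconCATConstruct",
    "SpikeSeries",
    "spike_fmol",
    "concentration_from_a280",
]


@dataclass(frozen=True)
class QconCATConstruct:
    """A QconCAT construct: ordered Q-peptides plus tag/linker mass.

    ``mw`` is the average molecular weight of the whole construct
    (tag included) as used in spectroscopic quantification, so the molar
    amount of each internal peptide equals the molar amount of construct.
    ``purity`` scales the effective spiked amount (default 1: no
    correction).
    """

    name: str
    peptides: tuple[QPeptide, ...]
    mw: float
    epsilon_280: float
    labeling_efficiency: float = 0.9939
    purity: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        if not self.peptides:
            raise ValueError("construct needs at least one Q-peptide")
        seqs = [p.sequence for p in self.peptides]
        if len(set(seqs)) != len(seqs):
            raise ValueError(
                "duplicate Q-peptide violates the strict 1:1 internal stoichiometry"
            )
        if self.mw <= 0:
            raise ValueError("construct molecular weight must be positive")
        if self.epsilon_280 <= 0:
            raise ValueError("extinction coefficient must be positive")
        if not 0.0 < self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must be in (0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")

    @property
    def peptide_sequences(self) -> tuple[str, ...]:
        return tuple(p.sequence for p in self.peptides)

    def parent_of(self, peptide: str) -> str:
        for p in self.peptides:
            if p.sequence == peptide:
                return p.parent_protein
        raise KeyError(f"peptide {peptide!r} not in construct {self.name!r}")


@dataclass(frozen=True)
class SpikeSeries:
    """The spike amounts (ng of construct) applied to one replicate digest
    of ``sample_protein_ug`` micrograms of total cell protein."""

    qprot: str
    amounts_ng: tuple[float, ...]
    sample_protein_ug: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "amounts_ng", tuple(float(a) for a in self.amounts_ng))
        if not self.amounts_ng:
            raise ValueError("spike series must contain at least one amount")
        if any(a <= 0 for a in self.amounts_ng):
            raise ValueError("spike amounts must be strictly positive")
        if any(b <= a for a, b in zip(self.amounts_ng, self.amounts_ng[1:])):
            raise ValueError("spike amounts must be strictly increasing")
        if self.sample_protein_ug <= 0:
            raise ValueError("sample_protein_ug must be positive")


def spike_fmol(amount_ng: float, mw_da: float) -> float:
    """Molar amount (fmol) of construct — and hence of every internal
    Q-peptide — in ``amount_ng`` nanograms of a construct of ``mw_da``."""
    if mw_da <= 0:
        raise ValueError("molecular weight must be positive")
    if amount_ng < 0:
        raise ValueError("amount_ng must be non-negative")
    return amount_ng / mw_da * 1e6


def concentration_from_a280(
    a280: float, epsilon: float, mw_da: float, path_cm: float = 1.0
) -> float:
    """Lambert-Beer protein concentration in ug/ul (= g/L).

    ``c = A280 / (epsilon * l) * MW`` — the spectroscopic quantification
    step used to adjust a purified construct stock.
    """
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    if a280 < 0:
        raise ValueError("absorbance must be non-negative")
    return a280 / (epsilon * path_cm) * mw_da
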