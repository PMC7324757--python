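"""Sequence-level peptide chemistry.

Tryptic digestion, monoisotopic and average peptide masses, nitrogen
counts, heavy-isotope (15N) mass shifts and A280 extinction coefficients.
All mass arithmetic is driven by the residue table shipped with the
package (``data/residues.csv``), which lists per-residue monoisotopic and
average masses, nitrogen counts and W/Y/C chromophore flags.

Heavy peptides here are metabolically 15N-labeled: every nitrogen atom of
a peptide (one backbone amide per residue plus side-chain nitrogens of
R, K, N, Q, H and W) is shifted by the 15N-14N mass difference, scaled by
the labeling efficiency of the expression culture. Partial labeling is
modeled as a deterministic centroid shift; the full isotopologue binomial
distribution is available separately as a diagnostic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

__all__ = [
    "DELTA_N15",
    "WATER_MONOISOTOPIC",
    "WATER_AVERAGE",
    "CANONICAL_RESIDUES",
    "ProteinSequence",
    "QPeptide",
    "validate_residues",
    "tryptic_digest",
    "monoisotopic_mass",
    "molecular_weight_average",
    "count_nitrogen",
    "heavy_mass",
    "extinction_coefficient_280",
    "isotopologue_distribution",
    "read_fasta",
    "write_fasta",
]

#: Mass difference between 15N and 14N, in Da.
DELTA_N15 = 0.9970349

WATER_MONOISOTOPIC = 18.0105646
WATER_AVERAGE = 18.0153

# Pace extinction coefficients at 280 nm (M-1 cm-1).
_EPS_TRP = 5500.0
_EPS_TYR = 1490.0
_EPS_CYSTINE = 125.0


def _load_residue_table() -> dict[str, dict]:
    table = {}
    with resources.files("qconpipe.data").joinpath("residues.csv").open() as fh:
        for row in csv.DictReader(fh):
            table[row["residue"]] = {
                "mono": float(row["monoisotopic_da"]),
                "avg": float(row["average_da"]),
                "n": int(row["n_nitrogen"]),
                "chromophore": row["chromophore"],
            }
    return table


_RESIDUES = _load_residue_table()
CANONICAL_RESIDUES = frozenset(_RESIDUES)
_MONO = {r: v["mono"] for r, v in _RESIDUES.items()}
_AVG = {r: v["avg"] for r, v in _RESIDUES.items()}
_NCOUNT = {r: v["n"] for r, v in _RESIDUES.items()}


def validate_residues(sequence: str, context: str = "sequence") -> None:
    """Reject empty or non-canonical sequences.

    Ambiguity codes (B, J, O, U, X, Z) and anything else outside the 20
    canonical one-letter codes raise a ``ValueError`` naming the offending
    character and its 1-based position.
    """
    if not sequence:
        raise ValueError(f"empty {context}")
    for i, ch in enumerate(sequence):
        if ch not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {ch!r} at position {i + 1} in {context}"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein amino-acid sequence.

    ``is_mature`` flags the transit-peptide-removed form whose molecular
    weight enters mass-fraction calculations.
    """

    identifier: str
    residues: str
    is_mature: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        validate_residues(self.residues, context=f"protein {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _as_residues(protein: "ProteinSequence | str") -> str:
    return protein.residues if isinstance(protein, ProteinSequence) else protein


def tryptic_digest(
    protein: "ProteinSequence | str", missed_cleavages: int = 0
) -> list[str]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Missed-cleavage products are generated by merging adjacent fully
    cleaved fragments. At ``missed_cleavages=0`` the returned peptides
    concatenate back to the input sequence, in order.
    """
    seq = _as_residues(protein)
    validate_residues(seq)
    if not 0 <= missed_cleavages <= 3:
        raise ValueError("missed_cleavages must be between 0 and 3")
    sites = [
        i + 1
        for i, ch in enumerate(seq)
        if ch in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P")
    ]
    bounds = [0, *sites]
    if not sites or sites[-1] != len(seq):
        bounds.append(len(seq))
    fragments = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    if missed_cleavages == 0:
        return fragments
    peptides = []
    for i in range(len(fragments)):
        for m in range(missed_cleavages + 1):
            if i + m < len(fragments):
                peptides.append("".join(fragments[i : i + m + 1]))
    return peptides


def monoisotopic_mass(peptide: str) -> float:
    """Monoisotopic mass of a peptide in Da (residue masses + water)."""
    validate_residues(peptide, context="peptide")
    return sum(_MONO[r] for r in peptide) + WATER_MONOISOTOPIC


def molecular_weight_average(protein: "ProteinSequence | str") -> float:
    """Average (chemical) molecular weight in Da."""
    seq = _as_residues(protein)
    validate_residues(seq)
    return sum(_AVG[r] for r in seq) + WATER_AVERAGE


def count_nitrogen(peptide: str) -> int:
    """Number of nitrogen atoms: one backbone N per residue plus
    side-chain N (R +3, K/N/Q/W +1, H +2)."""
    validate_residues(peptide, context="peptide")
    return sum(_NCOUNT[r] for r in peptide)


def heavy_mass(peptide: str, labeling_efficiency: float = 1.0) -> float:
    """Centroid mass of the metabolically 15N-labeled peptide.

    ``light mass + n_N * dM(15N) * efficiency``. At the 99.39% efficiency
    of the study the all-light species probability (1-eff)^N is negligible,
    so the centroid model suffices for area-level quantification.
    """
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labeling_efficiency must be in (0, 1]")
    return monoisotopic_mass(peptide) + count_nitrogen(peptide) * DELTA_N15 * labeling_efficiency


def extinction_coefficient_280(
    protein: "ProteinSequence | str", cystines_paired: bool = True
) -> float:
    """Molar extinction coefficient at 280 nm (M-1 cm-1), Pace values.

    Trp 5500, Tyr 1490; paired cysteines contribute 125 per cystine
    (``n_C // 2``) when ``cystines_paired`` is set.
    """
    seq = _as_residues(protein)
    validate_residues(seq)
    eps = seq.count("W") * _EPS_TRP + seq.count("Y") * _EPS_TYR
    if cystines_paired:
        eps += (seq.count("C") // 2) * _EPS_CYSTINE
    return eps


def isotopologue_distribution(n_nitrogen: int, labeling_efficiency: float):
    """Diagnostic binomial distribution of 15N incorporation.

    Returns the probability of k = 0..n heavy nitrogens for a peptide with
    ``n_nitrogen`` nitrogen atoms at the given per-atom labeling
    efficiency. Not used in quantification (areas, not spectra, are the
    pipeline currency).
    """
    if n_nitrogen < 0:
        raise ValueError("n_nitrogen must be non-negative")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ValueError("labeling_efficiency must be in (0, 1]")
    k = range(n_nitrogen + 1)
    return stats.binom.pmf(list(k), n_nitrogen, labeling_efficiency)


@dataclass(frozen=True)
class QPeptide:
    """A proteotypic quantification peptide.

    Carries the light (14N) and heavy (15N) monoisotopic masses, the
    nitrogen count and, optionally, an externally supplied ionization
    propensity rank/score (such ranks are consumed as input only, never
    computed here).
    """

    sequence: str
    parent_protein: str
    light_mass: float
    heavy_mass: float
    n_nitrogen: int
    ionization_rank: int | None = None
    ionization_score: float | None = None
    c_terminal: bool = False

    def __post_init__(self) -> None:
        validate_residues(self.sequence, context="Q-peptide")
        if not self.c_terminal and self.sequence[-1] not in "KR":
            raise ValueError(
                f"Q-peptide {self.sequence!r} must end in K or R "
                "(C-terminal construct peptides are exempt)"
            )
        if not self.heavy_mass > self.light_mass:
            raise ValueError("heavy_mass must exceed light_mass")
        if self.ionization_score is not None and not 0.0 <= self.ionization_score <= 1.0:
            raise ValueError("ionization_score must lie in [0, 1]")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        parent_protein: str,
        labeling_efficiency: float = 1.0,
        ionization_rank: int | None = None,
        ionization_score: float | None = None,
        c_terminal: bool = False,
    ) -> "QPeptide":
        return cls(
            sequence=sequence,
            parent_protein=parent_protein,
            light_mass=monoisotopic_mass(sequence),
            heavy_mass=heavy_mass(sequence, labeling_efficiency),
            n_nitrogen=count_nitrogen(sequence),
            ionization_rank=ionization_rank,
            ionization_score=ionization_score,
            c_terminal=c_terminal,
        )


def read_fasta(path: "str | Path", is_mature: bool = False) -> list[ProteinSequence]:
    """Read a multi-record protein FASTA into ``ProteinSequence`` objects."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinSequence(
                identifier=rec.id,
                residues=str(rec.seq),
                is_mature=is_mature,
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinSequence], path: "str | Path") -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.identifier, description=p.description or "")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")
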