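"""Synthetic-data generator emulating the QconCAT LC-MS measurement.

Generates ground-truth proteomes and simulated heavy/light extracted-ion-
chromatogram (XIC) area tables with the statistical structure of the
study: 12 target proteins spanning a ~128-fold abundance range, 2-3
Q-peptides per protein, peptide-specific response factors whose spread
can reach ~370-fold, 4 spike levels in two replicate-specific series,
multiplicative log-normal noise and random missing observations.

The central modelling assumption — shared by real QconCAT data — is that
a peptide's response factor is identical for its heavy and light forms
(same sequence, co-elution), so it cancels in the light/heavy area ratio.
The noiseless round trip through the quantification stage asserts exactly
this cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemistry import QPeptide, molecular_weight_average
from .construct import QconCATConstruct, SpikeSeries, spike_fmol

__all__ = [
    "GroundTruth",
    "simulate_ground_truth",
    "construct_for_truth",
    "simulate_xic_table",
    "simulate_elution_peak",
    "synthesize_protein_with_mass",
    "XIC_COLUMNS",
]

XIC_COLUMNS = [
    "peptide",
    "protein",
    "replicate",
    "spike_ng",
    "light_area",
    "heavy_area",
]

# residues allowed inside a synthetic tryptic peptide (no K/R/P to keep
# the peptide digest-stable in any concatenation)
_INTERNAL = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass(frozen=True)
class GroundTruth:
    """True per-protein abundances and per-peptide measurement parameters.

    ``proteins``: columns ``protein``, ``fmol_per_ug`` (fmol per ug of
    total cell protein). ``peptides``: columns ``peptide``, ``protein``,
    ``response_factor``, ``detection_probability``.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    noise_cv: float
    seed: int

    def abundance_of(self, protein: str) -> float:
        sel = self.proteins.loc[self.proteins["protein"] == protein, "fmol_per_ug"]
        if sel.empty:
            raise KeyError(f"unknown protein {protein!r}")
        return float(sel.iloc[0])


def _random_tryptic_peptide(rng: np.random.Generator, existing: set) -> str:
    while True:
        length = int(rng.integers(7, 17))
        body = "".join(rng.choice(_INTERNAL, size=length - 1))
        pep = body + str(rng.choice(["K", "R"]))
        if pep not in existing:
            existing.add(pep)
            return pep


def simulate_ground_truth(
    n_proteins: int = 12,
    abundance_range: tuple[float, float] = (10.0, 1300.0),
    peptides_per_protein: tuple[int, int] = (2, 3),
    response_factor_sigma: float = 1.7,
    detection_probability: float = 0.85,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground-truth proteome.

    Abundances (fmol per ug total protein) are log-uniform over
    ``abundance_range``; the default range spans the ~128-fold spread of
    the CBC panel (~10 to ~1300 fmol/ug, i.e. ~0.3 to ~36 amol/cell at
    27.6 pg protein per cell). Response factors are log-normal with
    ``sigma`` 1.7, wide enough that the max/min spread within a construct
    of ~30 peptides can reach the ~370-fold observed for equimolar
    construct peptides. Deterministic for a fixed seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = abundance_range
    if not (0 < lo <= hi):
        raise ValueError("abundance_range must satisfy 0 < min <= max")
    pmin, pmax = peptides_per_protein
    if not (1 <= pmin <= pmax):
        raise ValueError("peptides_per_protein must satisfy 1 <= min <= max")
    if not 0.0 < detection_probability <= 1.0:
        raise ValueError("detection_probability must be in (0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    rng = np.random.default_rng(seed)
    names = [f"P{i + 1:02d}" for i in range(n_proteins)]
    if lo == hi:
        abundances = np.full(n_proteins, lo)
    else:
        abundances = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_proteins))
    proteins = pd.DataFrame({"protein": names, "fmol_per_ug": abundances})

    rows = []
    existing: set = set()
    for name in names:
        k = int(rng.integers(pmin, pmax + 1))
        for _ in range(k):
            rows.append(
                {
                    "peptide": _random_tryptic_peptide(rng, existing),
                    "protein": name,
                    "response_factor": float(
                        np.exp(rng.normal(0.0, response_factor_sigma))
                    ),
                    "detection_probability": detection_probability,
                }
            )
    peptides = pd.DataFrame(rows)
    return GroundTruth(
        proteins=proteins, peptides=peptides, noise_cv=noise_cv, seed=int(seed)
    )


_TAG = "AAALEHHHHHHHHHHHH"  # linker + tandem-His purification tag


def construct_for_truth(
    truth: GroundTruth,
    name: str = "SYN-Qprot",
    labeling_efficiency: float = 0.9939,
) -> QconCATConstruct:
    """Build the QconCAT construct that carries the truth's Q-peptides.

    The construct molecular weight is computed from the concatenated
    peptide sequence plus a purification-tag stub, and its extinction
    coefficient from the sequence chromophores (floor of 1000 applied so
    tryptophan-free draws stay physically usable)."""
    from .chemistry import extinction_coefficient_280

    seqs = list(truth.peptides["peptide"])
    concat = "".join(seqs) + _TAG
    peps = [
        QPeptide.from_sequence(s, p, labeling_efficiency=labeling_efficiency)
        for s, p in zip(truth.peptides["peptide"], truth.peptides["protein"])
    ]
    return QconCATConstruct(
        name=name,
        peptides=tuple(peps),
        mw=molecular_weight_average(concat),
        epsilon_280=max(extinction_coefficient_280(concat), 1000.0),
        labeling_efficiency=labeling_efficiency,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit median (so ratio medians are
    unbiased) and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_xic_table(
    truth: GroundTruth,
    series: Sequence[SpikeSeries],
    construct: QconCATConstruct,
    n_replicates: "int | None" = None,
    area_per_fmol: float = 1.0,
) -> pd.DataFrame:
    """Simulate one heavy/light XIC area table.

    For observation (peptide, spike, replicate):

    - ``light_area = fmol_per_ug * sample_ug * response_factor * noise``
    - ``heavy_area = spike_fmol * response_factor * noise'``

    with independent log-normal noise draws and observations dropped
    independently with probability ``1 - detection_probability``.
    Deterministic given the truth's seed.
    """
    if n_replicates is None:
        n_replicates = len(series)
    if n_replicates != len(series):
        raise ValueError(
            f"n_replicates={n_replicates} does not match {len(series)} spike series"
        )
    covered = set(construct.peptide_sequences)
    missing = set(truth.peptides["peptide"]) - covered
    if missing:
        raise ValueError(f"construct does not cover truth peptides: {sorted(missing)}")

    rng = np.random.default_rng([int(truth.seed), 0x51C])
    abundance = dict(zip(truth.proteins["protein"], truth.proteins["fmol_per_ug"]))

    rows = []
    for rep_idx, ser in enumerate(series, start=1):
        for _, pep in truth.peptides.iterrows():
            fmol_per_ug = abundance[pep["protein"]]
            rf = pep["response_factor"]
            for amount_ng in ser.amounts_ng:
                detected = rng.random() <= pep["detection_probability"]
                noise = _lognormal_noise(rng, truth.noise_cv, 2)
                if not detected:
                    continue
                light = fmol_per_ug * ser.sample_protein_ug * rf * area_per_fmol * noise[0]
                heavy = (
                    spike_fmol(amount_ng, construct.mw) * rf * area_per_fmol * noise[1]
                )
                rows.append(
                    {
                        "peptide": pep["peptide"],
                        "protein": pep["protein"],
                        "replicate": rep_idx,
                        "spike_ng": amount_ng,
                        "light_area": light,
                        "heavy_area": heavy,
                    }
                )
    return pd.DataFrame(rows, columns=XIC_COLUMNS)


def simulate_elution_peak(
    area: float,
    rt_center: float = 300.0,
    width_s: float = 5.0,
    sampling_hz: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian elution peak whose trapezoidal integral equals
    ``area`` (within 0.1% once the peak width covers >= 10 samples).

    ``width_s`` is the Gaussian sigma in seconds; the trace spans
    +/- 6 sigma around ``rt_center``.
    """
    if width_s <= 0:
        raise ValueError("width_s must be positive")
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    if area < 0:
        raise ValueError("area must be non-negative")
    dt = 1.0 / sampling_hz
    times = np.arange(rt_center - 6 * width_s, rt_center + 6 * width_s + dt / 2, dt)
    if area == 0:
        return times, np.zeros_like(times)
    amplitude = area / (width_s * np.sqrt(2 * np.pi))
    intensities = amplitude * np.exp(-0.5 * ((times - rt_center) / width_s) ** 2)
    return times, intensities


def synthesize_protein_with_mass(
    target_average_mw: float, rng: np.random.Generator
) -> str:
    """Generate a random protein sequence whose average molecular weight
    approximates ``target_average_mw`` (typically within ~0.1 Da).

    Residues are drawn uniformly until the remaining mass budget fits a
    final residue pair, which is then chosen to minimize the error. Used
    to build synthetic stand-in chains for proteins whose sequences are
    not packaged but whose molecular weight must be controlled.
    """
    from .chemistry import WATER_AVERAGE, _AVG, molecular_weight_average

    best_seq, best_abs = None, np.inf
    for _ in range(20):  # random restarts escape swap-refinement optima
        seq = _attempt_synthesis(target_average_mw, rng)
        err = abs(molecular_weight_average(seq) - target_average_mw)
        if err < best_abs:
            best_seq, best_abs = seq, err
        if best_abs < 0.02:
            break
    return best_seq


def _attempt_synthesis(target_average_mw: float, rng: np.random.Generator) -> str:
    from .chemistry import WATER_AVERAGE, _AVG, molecular_weight_average

    residues = list(_AVG)
    masses = dict(_AVG)
    min_m, max_m = min(masses.values()), max(masses.values())
    budget = target_average_mw - WATER_AVERAGE
    if budget < 2 * min_m:
        raise ValueError("target molecular weight too small")
    seq: list[str] = []
    # greedy fill, leaving room for a closing pair
    while budget > 2 * max_m:
        allowed = [r for r in residues if masses[r] <= budget - 2 * min_m]
        r = str(rng.choice(allowed))
        seq.append(r)
        budget -= masses[r]
    best_pair, best_err = ("G", "G"), np.inf
    for a in residues:
        for b in residues:
            err = abs(budget - masses[a] - masses[b])
            if err < best_err:
                best_pair, best_err = (a, b), err
    seq.extend(best_pair)
    # single-residue swap refinement toward the target
    for _ in range(200):
        err = target_average_mw - molecular_weight_average("".join(seq))
        if abs(err) < 0.02:
            break
        best_gain, best_swap = 0.0, None
        for i, old in enumerate(seq):
            for r in residues:
                new_err = err - (masses[r] - masses[old])
                gain = abs(err) - abs(new_err)
                if gain > best_gain + 1e-12:
                    best_gain, best_swap = gain, (i, r)
        if best_swap is None:
            break
        seq[best_swap[0]] = best_swap[1]
    return "".join(seq)
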