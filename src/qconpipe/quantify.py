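"""Absolute quantification from heavy/light XIC area tables.

One quantification value is one (peptide, spike level, replicate) triple:

    fmol_per_ug = (light_area / heavy_area) * spike_fmol / sample_ug

The light/heavy ratio cancels the peptide-specific response factor (heavy
and light forms share sequence and elution), and the heavy amount is
known exactly from the spiked construct mass and its molecular weight.
Per-protein abundance is the median over the pooled values of all the
protein's Q-peptides, across all spike levels and replicates; per-peptide
mean +/- SD and n are retained for reporting.

Observations whose ratio falls outside a configurable dynamic-range
filter, or whose heavy area is zero, are censored (dropped and counted),
not treated as errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .construct import QconCATConstruct, SpikeSeries, spike_fmol

__all__ = [
    "RatioFilter",
    "PeptideQuantValue",
    "ProteinQuantResult",
    "integrate_xic",
    "peptide_quant",
    "quantify_observations",
    "aggregate_protein",
    "aggregate_by_replicate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatioFilter:
    """Keep observations with ``min_ratio <= light/heavy <= max_ratio``.

    The default 0.05-20 window keeps both channels within a quantifiable
    dynamic range; it is a documented modelling choice, not a published
    rule."""

    min_ratio: float = 0.05
    max_ratio: float = 20.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_ratio < self.max_ratio:
            raise ValueError("require 0 <= min_ratio < max_ratio")

    def keeps(self, ratio: float) -> bool:
        return self.min_ratio <= ratio <= self.max_ratio


@dataclass(frozen=True)
class PeptideQuantValue:
    peptide: str
    protein: str
    replicate: int
    spike_ng: float
    ratio: float
    fmol_per_ug: float


@dataclass(frozen=True)
class ProteinQuantResult:
    """Per-protein result: pooled median plus per-peptide statistics
    (columns ``peptide``, ``mean``, ``sd``, ``n``)."""

    protein: str
    median_fmol_per_ug: float
    n_values: int
    peptide_stats: pd.DataFrame


def integrate_xic(
    times: np.ndarray, intensities: np.ndarray, window: tuple[float, float]
) -> float:
    """Trapezoidal XIC area over a retention-time window."""
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.shape != intensities.shape:
        raise ValueError("times and intensities must have equal shape")
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    mask = (times >= t0) & (times <= t1)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than two samples")
    return float(np.trapezoid(intensities[mask], times[mask]))


def _heavy_correction(construct: QconCATConstruct, n_nitrogen: int) -> float:
    """Fraction of construct molecules carrying at least one 15N in a
    peptide of ``n_nitrogen`` nitrogens: 1 - (1-eff)^N."""
    return 1.0 - (1.0 - construct.labeling_efficiency) ** n_nitrogen


def peptide_quant(
    obs: Mapping,
    series: SpikeSeries,
    construct: QconCATConstruct,
    filters: RatioFilter = RatioFilter(),
    correct_labeling: bool = False,
) -> "PeptideQuantValue | None":
    """Quantify one XIC observation; returns ``None`` when censored.

    ``obs`` needs keys peptide, protein, replicate, spike_ng, light_area,
    heavy_area. With ``correct_labeling`` the heavy area is divided by
    1-(1-eff)^N to account for the unlabeled construct impurity.
    """
    light = float(obs["light_area"])
    heavy = float(obs["heavy_area"])
    if light < 0 or heavy < 0:
        raise ValueError("XIC areas must be non-negative")
    if heavy == 0:
        return None
    if correct_labeling:
        from .chemistry import count_nitrogen

        heavy = heavy / _heavy_correction(construct, count_nitrogen(obs["peptide"]))
    ratio = light / heavy
    if not filters.keeps(ratio):
        return None
    heavy_fmol = spike_fmol(float(obs["spike_ng"]), construct.mw) * construct.purity
    return PeptideQuantValue(
        peptide=str(obs["peptide"]),
        protein=str(obs["protein"]),
        replicate=int(obs["replicate"]),
        spike_ng=float(obs["spike_ng"]),
        ratio=ratio,
        fmol_per_ug=ratio * heavy_fmol / series.sample_protein_ug,
    )


def quantify_observations(
    observations: pd.DataFrame,
    series: Sequence[SpikeSeries],
    construct: QconCATConstruct,
    filters: RatioFilter = RatioFilter(),
    correct_labeling: bool = False,
) -> pd.DataFrame:
    """Quantify a whole XIC table.

    ``series`` holds one :class:`SpikeSeries` per replicate (replicate r
    uses ``series[r-1]``). Returns one row per retained observation with
    ``ratio`` and ``fmol_per_ug`` columns; censored rows are dropped and
    counted in the log.
    """
    required = {"peptide", "protein", "replicate", "spike_ng", "light_area", "heavy_area"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table lacks columns: {sorted(missing)}")
    n_censored = 0
    rows = []
    for obs in observations.to_dict("records"):
        rep = int(obs["replicate"])
        if not 1 <= rep <= len(series):
            raise ValueError(f"replicate {rep} has no spike series")
        value = peptide_quant(
            obs, series[rep - 1], construct, filters, correct_labeling
        )
        if value is None:
            n_censored += 1
            logger.debug(
                "censored observation peptide=%s replicate=%s spike=%s",
                obs["peptide"], obs["replicate"], obs["spike_ng"],
            )
            continue
        rows.append(value.__dict__)
    logger.info(
        "quantified %d observations, censored %d", len(rows), n_censored
    )
    return pd.DataFrame(
        rows,
        columns=["peptide", "protein", "replicate", "spike_ng", "ratio", "fmol_per_ug"],
    )


def aggregate_protein(values: pd.DataFrame) -> list[ProteinQuantResult]:
    """Aggregate quantification values to protein level.

    Per peptide: mean +/- SD (ddof=1; SD 0 for a single value) and n.
    Per protein: the median over the pooled values of all its peptides.
    """
    if values.empty:
        raise ValueError("no quantification values to aggregate")
    results = []
    for protein, grp in values.groupby("protein", sort=True):
        stats = (
            grp.groupby("peptide")["fmol_per_ug"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="size")
            .reset_index()
        )
        results.append(
            ProteinQuantResult(
                protein=str(protein),
                median_fmol_per_ug=float(grp["fmol_per_ug"].median()),
                n_values=int(len(grp)),
                peptide_stats=stats,
            )
        )
    return results


def aggregate_by_replicate(values: pd.DataFrame) -> pd.DataFrame:
    """Per (protein, replicate) medians — the replicate-level abundances
    used for strain-vs-recipient statistics."""
    if values.empty:
        raise ValueError("no quantification values to aggregate")
    out = (
        values.groupby(["protein", "replicate"])["fmol_per_ug"]
        .median()
        .reset_index()
        .rename(columns={"fmol_per_ug": "fmol_per_ug_median"})
    )
    return out
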