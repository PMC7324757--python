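"""Pipeline configuration: a flat, validated YAML surface.

Unknown keys are rejected (``extra="forbid"``), all constants are
validated positive, and the seed is recorded in every output header so
that any pipeline run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import reference
from .cell import CellModel
from .construct import QconCATConstruct, SpikeSeries
from .quantify import RatioFilter

__all__ = [
    "PipelineConfig",
    "load_config",
    "default_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellConfig(_Strict):
    protein_pg_per_cell: float = 27.6
    cell_volume_fL: float = 270.0
    chloroplast_fraction: float = 0.5

    def build(self) -> CellModel:
        return CellModel(
            protein_pg_per_cell=self.protein_pg_per_cell,
            cell_volume_fL=self.cell_volume_fL,
            chloroplast_fraction=self.chloroplast_fraction,
        )


class ConstructConfig(_Strict):
    name: str = "CBC-Qprot"
    mw_da: float = reference.CBC_QPROT_MW
    epsilon_280: float = reference.CBC_QPROT_EPSILON_280
    labeling_efficiency: float = reference.LABELING_EFFICIENCY
    purity: float = 1.0

    @field_validator("mw_da", "epsilon_280")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


class SpikeConfig(_Strict):
    sample_protein_ug: float = 20.0
    series: list[list[float]] = [
        [12.5, 25.0, 50.0, 100.0],
        [12.5, 25.0, 50.0, 100.0],
        [12.5, 25.0, 50.0, 100.0],
        [25.0, 50.0, 100.0, 200.0],
        [25.0, 50.0, 100.0, 200.0],
        [25.0, 50.0, 100.0, 200.0],
    ]

    def build(self, qprot: str) -> list[SpikeSeries]:
        return [
            SpikeSeries(
                qprot=qprot,
                amounts_ng=tuple(s),
                sample_protein_ug=self.sample_protein_ug,
            )
            for s in self.series
        ]


class FilterConfig(_Strict):
    min_ratio: float = 0.05
    max_ratio: float = 20.0
    correct_labeling: bool = False

    def build(self) -> RatioFilter:
        return RatioFilter(min_ratio=self.min_ratio, max_ratio=self.max_ratio)


class SimulationConfig(_Strict):
    n_proteins: int = 12
    abundance_range: tuple[float, float] = (10.0, 1300.0)
    peptides_per_protein: tuple[int, int] = (2, 3)
    response_factor_sigma: float = 1.7
    detection_probability: float = 0.85
    noise_cv: float = 0.2
    # per-strain overexpression folds keyed by protein; the recipient
    # strain carries an empty mapping
    strains: dict[str, dict[str, float]] = {"UVM4": {}}
    control_strain: str = "UVM4"


class StatsConfig(_Strict):
    alpha: float = 0.01
    adjustment: str = "holm"
    dunnett_mc_draws: int = 50_000

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must be in (0, 1)")
        return v


class PipelineConfig(_Strict):
    cell: CellConfig = CellConfig()
    qconcat: ConstructConfig = ConstructConfig()
    spikes: SpikeConfig = SpikeConfig()
    filters: FilterConfig = FilterConfig()
    simulation: SimulationConfig = SimulationConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0


def default_config() -> PipelineConfig:
    """Defaults mirroring the study design, with four transformant
    strains overexpressing the eighth synthetic protein (the SBP1-like
    target) at the observed folds."""
    cfg = PipelineConfig()
    cfg.simulation.strains = {
        "UVM4": {},
        "HA5": {"P08": 1.6},
        "HA11": {"P08": 1.7},
        "St1": {"P08": 3.0},
        "St12": {"P08": 2.2},
    }
    return cfg


def load_config(path: "str | Path | None") -> PipelineConfig:
    """Load and validate a YAML config; ``None`` yields the defaults.

    Validation failures (including unknown keys) raise before any
    computation runs."""
    if path is None:
        return default_config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable digest of the full configuration."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
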