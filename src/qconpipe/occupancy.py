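"""Substrate-per-binding-site analysis of the Calvin-Benson cycle.

Compares chloroplast metabolite concentrations against the molar
concentration of the substrate-binding sites of the enzyme that consumes
them. With the default of one binding site per catalytic subunit, the
binding-site concentration equals the subunit concentration from the
quantification stage (oligomerization does not change site molarity
under this convention).

Regimes: a substrate below its enzyme's binding-site concentration
(fold < 1) cannot saturate the sites; between 1 and 4.5-fold it is "only
slightly above" them; beyond 4.5-fold it is in clear excess. Both
thresholds are left-closed (fold exactly 1 is near-sites, exactly 4.5 is
excess).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import reference

__all__ = [
    "REGIME_NEAR_THRESHOLD",
    "REGIME_EXCESS_THRESHOLD",
    "EnzymeSpec",
    "OccupancyRecord",
    "classify_regime",
    "binding_site_concentration",
    "substrate_per_binding_site",
    "cbc_enzymes",
    "occupancy_table",
    "plot_occupancy",
]

logger = logging.getLogger(__name__)

REGIME_NEAR_THRESHOLD = 1.0
REGIME_EXCESS_THRESHOLD = 4.5


@dataclass(frozen=True)
class EnzymeSpec:
    """An enzyme, its catalytic subunit(s) and binding sites per subunit."""

    name: str
    subunits: tuple[str, ...]
    binding_sites_per_subunit: int = 1
    number: "int | None" = None
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "subunits", tuple(self.subunits))
        if not self.subunits:
            raise ValueError("enzyme needs at least one catalytic subunit")
        if self.binding_sites_per_subunit < 1:
            raise ValueError("binding_sites_per_subunit must be >= 1")


@dataclass(frozen=True)
class OccupancyRecord:
    enzyme: str
    substrate: str
    substrate_uM: float
    binding_site_uM: float
    fold: float
    regime: str
    role: str = "substrate"


def classify_regime(fold: float) -> str:
    if fold <= 0:
        raise ValueError("fold must be positive")
    if fold < REGIME_NEAR_THRESHOLD:
        return "below-sites"
    if fold < REGIME_EXCESS_THRESHOLD:
        return "near-sites"
    return "excess"


def binding_site_concentration(
    enzyme: EnzymeSpec, subunit_uM: Mapping[str, float]
) -> float:
    """uM of substrate-binding sites: subunit concentration times sites
    per subunit, summed over catalytic subunits."""
    total = 0.0
    for subunit in enzyme.subunits:
        if subunit not in subunit_uM:
            raise ValueError(
                f"no concentration available for subunit {subunit!r} of {enzyme.name}"
            )
        total += float(subunit_uM[subunit]) * enzyme.binding_sites_per_subunit
    if total <= 0:
        raise ValueError(f"binding-site concentration of {enzyme.name} is not positive")
    return total


def substrate_per_binding_site(
    substrate_uM: float,
    enzyme: EnzymeSpec,
    subunit_uM: Mapping[str, float],
    substrate_name: str = "substrate",
    role: str = "substrate",
) -> OccupancyRecord:
    """One enzyme-metabolite occupancy record."""
    if substrate_uM <= 0:
        raise ValueError("substrate concentration must be positive")
    sites = binding_site_concentration(enzyme, subunit_uM)
    fold = substrate_uM / sites
    return OccupancyRecord(
        enzyme=enzyme.name,
        substrate=substrate_name,
        substrate_uM=float(substrate_uM),
        binding_site_uM=sites,
        fold=fold,
        regime=classify_regime(fold),
        role=role,
    )


def cbc_enzymes(reaction_map: "pd.DataFrame | None" = None) -> list[EnzymeSpec]:
    """The 11 CBC enzymes from the packaged reaction map."""
    rmap = reference.reaction_map() if reaction_map is None else reaction_map
    enzymes = []
    for (name, number, subunits, reversible), _ in rmap.groupby(
        ["enzyme", "number", "subunits", "reversible"], sort=False
    ):
        enzymes.append(
            EnzymeSpec(
                name=name,
                subunits=tuple(str(subunits).split(";")),
                number=int(number),
                reversible=bool(reversible),
            )
        )
    return enzymes


def occupancy_table(
    metabolites: "Mapping[str, float] | pd.DataFrame",
    subunit_uM: Mapping[str, float],
    enzymes: "Sequence[EnzymeSpec] | None" = None,
    reaction_map: "pd.DataFrame | None" = None,
    include_products: bool = True,
) -> list[OccupancyRecord]:
    """Occupancy records for every (enzyme, substrate) pair in the map.

    Product-side records are added for enzymes flagged reversible (their
    product pools equilibrate with the substrate pool). A metabolite
    missing from the table produces a logged warning and a skipped
    record, not an error.
    """
    if isinstance(metabolites, pd.DataFrame):
        conc = dict(zip(metabolites["metabolite"], metabolites["um"]))
    else:
        conc = dict(metabolites)
    rmap = reference.reaction_map() if reaction_map is None else reaction_map
    if enzymes is None:
        enzymes = cbc_enzymes(rmap)
    by_name = {e.name: e for e in enzymes}
    records = []
    for row in rmap.itertuples():
        enzyme = by_name.get(row.enzyme)
        if enzyme is None:
            continue
        if row.role == "product" and not (include_products and enzyme.reversible):
            continue
        if row.metabolite not in conc:
            logger.warning(
                "metabolite %s (needed by %s) missing from table; record skipped",
                row.metabolite, row.enzyme,
            )
            continue
        records.append(
            substrate_per_binding_site(
                conc[row.metabolite],
                enzyme,
                subunit_uM,
                substrate_name=row.metabolite,
                role=row.role,
            )
        )
    return records


def records_to_frame(records: Iterable[OccupancyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def plot_occupancy(records: Sequence[OccupancyRecord], path: str) -> None:
    """Log-log scatter of substrate-per-binding-site fold versus substrate
    concentration, with the regime thresholds drawn."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(list(records))
    fig, ax = plt.subplots(figsize=(6, 5))
    for role, marker in (("substrate", "o"), ("product", "^")):
        sub = df[df["role"] == role]
        if sub.empty:
            continue
        ax.scatter(sub["substrate_uM"], sub["fold"], marker=marker, label=role)
        for row in sub.itertuples():
            ax.annotate(
                f"{row.enzyme}/{row.substrate}",
                (row.substrate_uM, row.fold),
                fontsize=6,
            )
    ax.axhline(REGIME_NEAR_THRESHOLD, ls="--", lw=0.8, color="grey")
    ax.axhline(REGIME_EXCESS_THRESHOLD, ls=":", lw=0.8, color="grey")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("substrate concentration (uM)")
    ax.set_ylabel("substrate per binding site (fold)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
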