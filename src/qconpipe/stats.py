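"""Comparative statistics: strain-vs-recipient fold changes with
many-to-one multiple testing, and cross-method abundance comparisons.

Dunnett's many-to-one comparison is implemented by seeded Monte-Carlo
simulation of the null distribution of the maximum absolute t statistic
over the k treatment-vs-control contrasts (group means drawn at their
actual per-group precisions, pooled variance as a scaled chi-square), so
the familywise error calibration needs no external critical-value tables.
``scipy.stats.dunnett`` exists and is used as an independent cross-check
in the test suite, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "holm_adjust",
    "log2_fold_change",
    "DunnettResult",
    "anova_dunnett",
    "dunnett_null_maxabs_t",
    "method_fold",
    "RankConcordance",
    "rank_concordance",
    "compare_to_recipient",
]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending, multiply the i-th smallest (1-based) by ``m - i + 1``,
    enforce a cumulative maximum so adjusted values are monotone, cap at
    1, and restore the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(adjusted), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def log2_fold_change(
    transformant_values: Sequence[float],
    recipient_values: Sequence[float],
    stat: Callable = np.mean,
) -> float:
    """log2 of the ratio of group summaries (mean by default)."""
    t = np.asarray(transformant_values, dtype=float)
    r = np.asarray(recipient_values, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both groups must be non-empty")
    mt, mr = float(stat(t)), float(stat(r))
    if mt <= 0 or mr <= 0:
        raise ValueError("group summaries must be positive for a log ratio")
    return float(np.log2(mt / mr))


def dunnett_null_maxabs_t(
    group_sizes: Sequence[int],
    n_draws: int = 50_000,
    rng: "np.random.Generator | int | None" = None,
) -> np.ndarray:
    """Monte-Carlo draws of max_j |T_j| under the many-to-one null.

    ``group_sizes[0]`` is the control. Group means are simulated at
    precision 1/n_j, the pooled variance as chi-square with
    ``N - k - 1`` degrees of freedom, reproducing the correlation
    structure of the Dunnett contrasts for equal or unequal n.
    """
    ns = np.asarray(group_sizes, dtype=float)
    if ns.size < 2:
        raise ValueError("need a control group and at least one treatment")
    if np.any(ns < 2):
        raise ValueError("every group needs at least two observations")
    df = int(ns.sum() - ns.size)
    rng = np.random.default_rng(rng)
    means = rng.standard_normal((n_draws, ns.size)) / np.sqrt(ns)
    diffs = means[:, 1:] - means[:, :1]
    scale = np.sqrt(1.0 / ns[1:] + 1.0 / ns[0])
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    t = diffs / scale / s[:, None]
    return np.max(np.abs(t), axis=1)


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    anova_p: float
    t_statistics: np.ndarray
    p_adjusted: np.ndarray
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted < self.alpha


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    n_mc: int = 50_000,
    seed: "int | np.random.Generator | None" = 0,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one adjusted p-values.

    ``groups[0]`` is the control; each treatment j is compared to it with
    a pooled-variance t statistic, and the adjusted p-value is the null
    probability that the familywise maximum |T| exceeds |t_j|, estimated
    from ``n_mc`` seeded Monte-Carlo draws (adjusted p is therefore
    monotone in |t|).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need a control group and at least one treatment")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    f_statistic, anova_p = sps.f_oneway(*arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum() - ns.size)
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    s2 = sse / df
    scale = np.sqrt(s2 * (1.0 / ns[1:] + 1.0 / ns[0]))
    t_stats = (means[1:] - means[0]) / scale
    draws = dunnett_null_maxabs_t(ns, n_draws=n_mc, rng=seed)
    p_adj = np.array([(draws >= abs(t)).mean() for t in t_stats])
    return DunnettResult(
        f_statistic=float(f_statistic),
        anova_p=float(anova_p),
        t_statistics=t_stats,
        p_adjusted=p_adj,
        alpha=alpha,
    )


def method_fold(a: float, b: float) -> float:
    """Cross-method fold ratio ``a / b``; the caller picks the numerator
    per comparison convention (e.g. emPAI/QconCAT for overestimation)."""
    if a <= 0 or b <= 0:
        raise ValueError("both values must be positive")
    return a / b


@dataclass(frozen=True)
class RankConcordance:
    rho: float
    discordant_pairs: tuple[tuple, ...]


def rank_concordance(
    ranks_a: Sequence, ranks_b: Sequence, bottom_k: int = 3, labels: "Sequence | None" = None
) -> RankConcordance:
    """Spearman rho between two rankings plus the discordant pairs among
    the ``bottom_k`` lowest-abundance entries of ranking ``a``.

    ``ranks_a`` must be a valid permutation-style ranking (1 = most
    abundant); ``ranks_b`` may be any comparable rank scores of the same
    items.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size != b.size:
        raise ValueError("rankings must have equal length")
    if sorted(a) != list(range(1, a.size + 1)):
        raise ValueError("ranks_a must be a permutation of 1..n")
    if labels is None:
        labels = list(range(a.size))
    rho = float(sps.spearmanr(a, b).statistic)
    bottom = np.argsort(a)[-bottom_k:]
    discordant = []
    for ii in range(len(bottom)):
        for jj in range(ii + 1, len(bottom)):
            i, j = bottom[ii], bottom[jj]
            if (a[i] - a[j]) * (b[i] - b[j]) < 0:
                discordant.append(tuple(sorted((labels[i], labels[j]), key=str)))
    return RankConcordance(rho=rho, discordant_pairs=tuple(discordant))


def compare_to_recipient(
    abundances: pd.DataFrame,
    control: str,
    alpha: float = 0.01,
    value_column: str = "value",
) -> pd.DataFrame:
    """Strain-vs-recipient fold-change table.

    ``abundances`` is long-format with columns strain, protein, replicate
    and ``value_column`` (replicate-level abundances). For each protein,
    every non-control strain is compared to the control with a two-sided
    pooled-variance t-test; p-values are Holm-adjusted within the protein
    and flagged at ``alpha``. log2 fold changes use group means.
    """
    required = {"strain", "protein", "replicate", value_column}
    missing = required - set(abundances.columns)
    if missing:
        raise ValueError(f"abundance table lacks columns: {sorted(missing)}")
    if control not in set(abundances["strain"]):
        raise ValueError(f"control strain {control!r} absent from table")
    rows = []
    for protein, grp in abundances.groupby("protein", sort=True):
        ctrl = grp.loc[grp["strain"] == control, value_column].to_numpy()
        strains = [s for s in grp["strain"].unique() if s != control]
        raw = []
        fcs = []
        for strain in strains:
            vals = grp.loc[grp["strain"] == strain, value_column].to_numpy()
            t = sps.ttest_ind(vals, ctrl)
            p = float(t.pvalue)
            # two identical zero-variance groups yield 0/0: no evidence
            if np.isnan(p):
                p = 1.0
            raw.append(p)
            fcs.append(log2_fold_change(vals, ctrl))
        adj = holm_adjust(raw) if raw else np.array([])
        for strain, fc, p_raw, p_adj in zip(strains, fcs, raw, adj):
            rows.append(
                {
                    "protein": protein,
                    "strain": strain,
                    "log2_fc": fc,
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)
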