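"""Classical inter-group statistics per gene on raw Ct values.

An ideal reference gene shows no systematic Ct difference between
experimental groups, so each candidate is screened with a per-group
Shapiro–Wilk normality check, a one-way fixed-effects ANOVA across groups,
and — where the ANOVA is significant — post hoc pairwise comparisons
(Tukey HSD by default, unadjusted two-sided t-tests as an alternative).
A gene is called "stable" when its ANOVA p-value is at or above alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .ctdata import CtTable

__all__ = [
    "InterGroupResult",
    "normality_screen",
    "anova_per_gene",
    "posthoc",
]


@dataclass
class InterGroupResult:
    """ANOVA verdicts plus optional normality screen, per gene."""

    anova: pd.DataFrame            # columns: F, p_value, stable
    normality: pd.DataFrame | None  # long: gene, group, W, p_value, normal
    alpha: float


def normality_screen(table: CtTable, genes: list[str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro–Wilk per gene × group.

    Groups with fewer than 3 values or zero spread cannot be tested; they
    are flagged (``W`` NaN) rather than failed.
    """
    genes = list(genes) if genes is not None else table.candidate_genes
    rows = []
    for gene in genes:
        for grp in table.group_labels:
            vals = table.ct.loc[table.groups == grp, gene].to_numpy(float)
            if vals.size < 3 or np.ptp(vals) == 0:
                rows.append({"gene": gene, "group": grp, "W": np.nan,
                             "p_value": np.nan, "normal": None})
                continue
            w, p = stats.shapiro(vals)
            rows.append({"gene": gene, "group": grp, "W": float(w),
                         "p_value": float(p), "normal": bool(p >= alpha)})
    return pd.DataFrame(rows)


def anova_per_gene(table: CtTable, genes: list[str] | None = None,
                   alpha: float = 0.05, with_normality: bool = True,
                   fallback: Literal["none", "kruskal"] = "none") -> InterGroupResult:
    """One-way fixed-effects ANOVA of Ct across groups, per gene.

    A gene with zero within- and between-group variance (constant column)
    has an undefined F; it is reported stable with ``F`` NaN and ``p`` 1.
    With ``fallback="kruskal"`` any gene failing the per-group normality
    screen is tested with Kruskal–Wallis instead (its ``F`` is then NaN);
    the default keeps the parametric ANOVA throughout.
    """
    genes = list(genes) if genes is not None else table.candidate_genes
    labels = table.group_labels
    if len(labels) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if table.group_sizes().min() < 2:
        raise ValueError("ANOVA needs >= 2 replicates per group")
    norm = (
        normality_screen(table, genes, alpha)
        if with_normality or fallback == "kruskal"
        else None
    )
    rows = {}
    for gene in genes:
        samples = [table.ct.loc[table.groups == g, gene].to_numpy(float)
                   for g in labels]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            rows[gene] = {"F": np.nan, "p_value": 1.0, "stable": True}
            continue
        non_normal = False
        if fallback == "kruskal" and norm is not None:
            flags = norm.loc[norm["gene"] == gene, "normal"]
            non_normal = (flags == False).any()  # noqa: E712 (NaN-safe)
        if non_normal:
            _, p = stats.kruskal(*samples)
            rows[gene] = {"F": np.nan, "p_value": float(p),
                          "stable": bool(p >= alpha)}
        else:
            f, p = stats.f_oneway(*samples)
            rows[gene] = {"F": float(f), "p_value": float(p),
                          "stable": bool(p >= alpha)}
    anova = pd.DataFrame(rows).T[["F", "p_value", "stable"]]
    if not with_normality:
        norm = None
    return InterGroupResult(anova=anova, normality=norm, alpha=alpha)


def posthoc(
    table: CtTable,
    gene: str,
    method: Literal["tukey", "ttest"] = "tukey",
) -> pd.DataFrame:
    """Pairwise post hoc p-values between groups for one gene.

    ``tukey`` gives studentized-range (family-wise corrected) p-values;
    ``ttest`` gives unadjusted two-sided two-sample t-tests, the
    star-annotation convention commonly shown on group-mean plots.
    Returns a symmetric group × group p-value matrix.
    """
    labels = table.group_labels
    samples = [table.ct.loc[table.groups == g, gene].to_numpy(float) for g in labels]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs >= 2 replicates")
    k = len(labels)
    p = np.ones((k, k))
    if method == "tukey":
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
            pass  # identical constant groups: leave p = 1
        else:
            res = stats.tukey_hsd(*samples)
            p = np.asarray(res.pvalue, float)
            np.fill_diagonal(p, 1.0)
    elif method == "ttest":
        for i in range(k):
            for j in range(i + 1, k):
                if np.ptp(samples[i]) == 0 and np.ptp(samples[j]) == 0:
                    pij = 1.0 if samples[i][0] == samples[j][0] else 0.0
                else:
                    pij = float(stats.ttest_ind(samples[i], samples[j]).pvalue)
                p[i, j] = p[j, i] = pij
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    return pd.DataFrame(p, index=labels, columns=labels)
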