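"""Pairwise ΔCt stability analysis (Silver et al. style).

For every pair of candidate reference genes (a, b) the per-sample signed
difference ``δ_s = Ct_a,s − Ct_b,s`` is formed; a stable pair keeps δ
constant across samples, so the pair's score is the sample SD of δ (n−1
denominator).  A gene's overall score is the arithmetic mean of the SDs of
all pairs containing it; lower means more stable.  The reported "mean ΔCt"
of a pair is the mean of |δ_s| — for pairs whose expression levels are far
apart this equals the gap between the two genes' mean Ct, while for
near-coincident genes the absolute value keeps the figure non-negative.

Because δ subtracts two genes measured in the same sample, any per-sample
loading effect common to all genes cancels exactly; the SD reflects only
gene-specific variation.

Per-gene mean SDs are compared between genes with two-sided Mann–Whitney
tests on their sets of pair SDs, and the outcome is summarised as a
compact letter display: genes that are not significantly different share a
letter.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairwiseDeltaCtResult",
    "pairwise_delta_ct",
    "rank_by_mean_sd",
    "sd_letter_groups",
    "mann_whitney_p",
    "compact_letter_display",
]

from .ctdata import CtTable


@dataclass
class PairwiseDeltaCtResult:
    """All pairwise ΔCt summaries plus the per-gene aggregate."""

    pairs: pd.DataFrame        # columns: gene_a, gene_b, mean_delta_ct, sd
    mean_sd: pd.Series         # per-gene mean of its pair SDs
    genes: list[str]

    def pair_sds_of(self, gene: str) -> np.ndarray:
        """The n−1 pair SDs contributed by one gene."""
        mask = (self.pairs["gene_a"] == gene) | (self.pairs["gene_b"] == gene)
        return self.pairs.loc[mask, "sd"].to_numpy(float)

    def to_long_frame(self) -> pd.DataFrame:
        """Both orientations of every pair (the conventional long layout)."""
        fwd = self.pairs.rename(columns={"gene_a": "gene", "gene_b": "partner"})
        rev = self.pairs.rename(columns={"gene_b": "gene", "gene_a": "partner"})
        long = pd.concat([fwd, rev], ignore_index=True)
        long["mean_sd"] = long["gene"].map(self.mean_sd)
        return long.sort_values(["gene", "partner"], kind="stable").reset_index(drop=True)


def pairwise_delta_ct(
    table: CtTable, genes: list[str] | None = None
) -> PairwiseDeltaCtResult:
    """Compute mean |ΔCt| and the SD of signed ΔCt for every gene pair."""
    genes = list(genes) if genes is not None else table.candidate_genes
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in candidate list")
    if len(genes) < 3:
        raise ValueError("pairwise ΔCt needs >= 3 candidate genes")
    rows = []
    for a, b in itertools.combinations(genes, 2):
        delta = table.ct[a].to_numpy(float) - table.ct[b].to_numpy(float)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "mean_delta_ct": float(np.mean(np.abs(delta))),
                "sd": float(np.std(delta, ddof=1)),
            }
        )
    pairs = pd.DataFrame(rows)
    mean_sd = pd.Series(
        {
            g: pairs.loc[
                (pairs["gene_a"] == g) | (pairs["gene_b"] == g), "sd"
            ].mean()
            for g in genes
        },
        name="mean_sd",
    )
    return PairwiseDeltaCtResult(pairs=pairs, mean_sd=mean_sd, genes=genes)


def rank_by_mean_sd(result: PairwiseDeltaCtResult) -> pd.Series:
    """Rank genes by ascending mean pair SD; ties keep input order."""
    order = {g: i for i, g in enumerate(result.genes)}
    ranked = sorted(result.genes, key=lambda g: (result.mean_sd[g], order[g]))
    return pd.Series({g: i + 1 for i, g in enumerate(ranked)}, name="rank").reindex(
        result.genes
    )


def mann_whitney_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> float:
    """Two-sided Mann–Whitney p-value.

    Uses the exact null distribution when both sets have at most
    ``exact_max_n`` values; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size <= exact_max_n and y.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compact_letter_display(
    items: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds unordered item pairs that differ significantly;
    items sharing a letter are not significantly different.  Letters are
    issued in the order ``items`` is given (callers pass items sorted by
    ascending score).
    """
    sig = {frozenset(p) for p in significant if len(frozenset(p)) == 2}
    # start with one group holding everything, then split on each significant
    # pair and absorb any group contained in another
    groups: list[set[str]] = [set(items)]
    for pair in sorted(sig, key=sorted):
        a, b = sorted(pair)
        split: list[set[str]] = []
        for grp in groups:
            if a in grp and b in grp:
                split.extend([grp - {a}, grp - {b}])
            else:
                split.append(grp)
        groups = []
        for g in split:
            if g and not any(g < h for h in split) and g not in groups:
                groups.append(g)
    # order groups by the first (best-ranked) item they contain
    pos = {it: i for i, it in enumerate(items)}
    groups.sort(key=lambda g: min(pos[it] for it in g))
    letters = {it: "" for it in items}
    for letter_i, grp in enumerate(groups):
        letter = chr(ord("a") + letter_i)
        for it in items:
            if it in grp:
                letters[it] += letter
    return letters


def sd_letter_groups(
    result: PairwiseDeltaCtResult, alpha: float = 0.05
) -> pd.Series:
    """Compact letters for the per-gene pair-SD sets.

    Genes whose sets of pair SDs do not differ (two-sided Mann–Whitney,
    ``p >= alpha``) share a letter.  With fewer than 3 SD values per gene
    the test is underpowered; a warning is emitted and the comparison still
    runs.
    """
    sets = {g: result.pair_sds_of(g) for g in result.genes}
    if min(v.size for v in sets.values()) < 3:
        warnings.warn("fewer than 3 pair SDs per gene: Mann-Whitney is underpowered")
    significant = set()
    for a, b in itertools.combinations(result.genes, 2):
        if mann_whitney_p(sets[a], sets[b]) < alpha:
            significant.add((a, b))
    order = {g: i for i, g in enumerate(result.genes)}
    by_score = sorted(result.genes, key=lambda g: (result.mean_sd[g], order[g]))
    letters = compact_letter_display(by_score, significant)
    return pd.Series(letters, name="letter").reindex(result.genes)
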