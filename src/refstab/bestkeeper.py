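"""BestKeeper-style analysis on raw quantification cycles.

BestKeeper works directly on crossing points (Ct), never on
efficiency-transformed quantities: per-gene descriptive statistics, a
per-sample index defined as the geometric mean Ct of the candidate
references, an ordinary least-squares regression of each gene on that
index, and a Pearson correlation of each candidate against the designated
target gene to detect co-regulation.

The dispersion reported as "std dev [±CP]" follows the BestKeeper tool's
convention of the mean absolute deviation from the arithmetic mean (MAD);
the classical n-1 standard deviation is available via ``convention="sd"``.
CV% is 100 · dispersion / arithmetic-mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .ctdata import CtTable

__all__ = [
    "DescriptiveStats",
    "IndexRegression",
    "TargetCorrelation",
    "descriptive_stats",
    "bestkeeper_index",
    "gene_vs_index_regression",
    "correlation_with_target",
]


@dataclass
class DescriptiveStats:
    """Per-gene descriptive statistics of raw Ct (genes as columns)."""

    table: pd.DataFrame  # rows: n, geo_mean, ar_mean, min, max, dispersion, cv_percent
    convention: str

    def __getitem__(self, gene: str) -> pd.Series:
        return self.table[gene]


@dataclass
class IndexRegression:
    """OLS of each gene's Ct on the BestKeeper index (genes as columns)."""

    table: pd.DataFrame  # rows: r, r_squared, intercept, slope, slope_se, p_value


@dataclass
class TargetCorrelation:
    """Pearson correlation of each candidate with the target gene's Ct."""

    table: pd.DataFrame  # rows: r, p_value
    target_gene: str


def _dispersion(values: np.ndarray, convention: str) -> float:
    if convention == "mad":
        return float(np.mean(np.abs(values - values.mean())))
    if convention == "sd":
        return float(np.std(values, ddof=1))
    raise ValueError(f"unknown dispersion convention {convention!r}")


def descriptive_stats(
    table: CtTable,
    genes: list[str] | None = None,
    convention: Literal["mad", "sd"] = "mad",
) -> DescriptiveStats:
    """n, geometric/arithmetic mean, min, max, dispersion and CV% per gene."""
    genes = list(genes) if genes is not None else table.candidate_genes
    rows = {}
    for gene in genes:
        ct = table.ct[gene].to_numpy(float)
        if ct.size == 0:
            raise ValueError(f"empty Ct column for {gene!r}")
        ar = float(ct.mean())
        disp = _dispersion(ct, convention)
        rows[gene] = {
            "n": float(ct.size),
            "geo_mean": float(stats.gmean(ct)),
            "ar_mean": ar,
            "min": float(ct.min()),
            "max": float(ct.max()),
            "dispersion": disp,
            "cv_percent": 100.0 * disp / ar,
        }
    return DescriptiveStats(pd.DataFrame(rows), convention)


def bestkeeper_index(table: CtTable, genes: list[str] | None = None) -> pd.Series:
    """Per-sample geometric mean Ct over the candidate reference genes."""
    genes = list(genes) if genes is not None else table.candidate_genes
    if len(genes) < 2:
        raise ValueError("index needs >= 2 genes")
    ct = table.ct[genes].to_numpy(float)
    if (ct <= 0).any():
        raise ValueError("geometric mean undefined for non-positive Ct")
    return pd.Series(
        stats.gmean(ct, axis=1), index=table.ct.index, name="bestkeeper_index"
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t-transform
    ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def gene_vs_index_regression(
    table: CtTable,
    index: pd.Series | None = None,
    genes: list[str] | None = None,
) -> IndexRegression:
    """OLS of each gene's Ct on the index, with Pearson r and its p-value."""
    genes = list(genes) if genes is not None else table.candidate_genes
    if index is None:
        index = bestkeeper_index(table, genes)
    x = index.to_numpy(float)
    if x.size < 3:
        raise ValueError("regression needs >= 3 samples")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance index")
    rows = {}
    for gene in genes:
        y = table.ct[gene].to_numpy(float)
        res = stats.linregress(x, y)
        r, p = _pearson_with_p(x, y)
        rows[gene] = {
            "r": r,
            "r_squared": r**2,
            "intercept": float(res.intercept),
            "slope": float(res.slope),
            "slope_se": float(res.stderr),
            "p_value": p,
        }
    return IndexRegression(pd.DataFrame(rows))


def correlation_with_target(
    table: CtTable, genes: list[str] | None = None
) -> TargetCorrelation:
    """Pearson correlation of each candidate's Ct with the target's Ct.

    A strong, significant correlation suggests the candidate is
    co-regulated with the gene of interest and unfit as a neutral control.
    """
    if table.target_gene is None:
        raise ValueError("no target gene designated")
    genes = list(genes) if genes is not None else table.candidate_genes
    y = table.ct[table.target_gene].to_numpy(float)
    if y.size < 3:
        raise ValueError("correlation needs >= 3 samples")
    rows = {}
    for gene in genes:
        r, p = _pearson_with_p(table.ct[gene].to_numpy(float), y)
        rows[gene] = {"r": r, "p_value": p}
    return TargetCorrelation(pd.DataFrame(rows), table.target_gene)
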