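"""Core data model and transforms for RT-qPCR quantification-cycle (Ct) data.

A :class:`CtTable` is the single input currency of every stability method:
a complete samples × genes matrix of Ct values, a group label per sample,
and an optionally designated target gene (the gene of interest, which is
*not* a candidate reference).  Ct values live on a log2-like scale — one
cycle corresponds to one doubling at 100 % amplification efficiency — so
expression-scale methods (geNorm, NormFinder) first convert Ct to relative
quantities via ``RQ = E^(Ct_cal - Ct)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "EfficiencyMap",
    "RelativeQuantityTable",
    "DilutionSeries",
    "DilutionFit",
    "read_ct_table",
    "write_ct_table",
    "ct_to_relative_quantity",
    "efficiency_from_dilution",
    "log2_rq",
]


class CtDataError(ValueError):
    """Raised for malformed or inconsistent Ct input."""


@dataclass
class CtTable:
    """Complete Ct matrix with per-sample group labels.

    Parameters
    ----------
    ct
        DataFrame indexed by sample id, one column per gene, finite
        positive Ct values (cycles).
    groups
        Series mapping sample id -> group label, aligned with ``ct.index``.
    target_gene
        Optional name of the target (gene of interest).  When set, the
        remaining columns are the candidate reference genes.
    """

    ct: pd.DataFrame
    groups: pd.Series
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.ct, pd.DataFrame):
            self.ct = pd.DataFrame(self.ct)
        self.ct = self.ct.astype(float)
        if self.ct.shape[1] < 2:
            raise CtDataError("need at least 2 gene columns")
        if self.ct.columns.duplicated().any():
            raise CtDataError("gene names must be unique")
        if self.ct.index.duplicated().any():
            raise CtDataError("sample ids must be unique")
        bad = self.ct.isna() | ~np.isfinite(self.ct) | (self.ct <= 0)
        if bad.any().any():
            sample, gene = next(
                (s, g) for s in self.ct.index for g in self.ct.columns
                if bad.at[s, g]
            )
            raise CtDataError(
                f"non-finite or non-positive Ct for sample {sample!r}, gene {gene!r}"
            )
        self.groups = pd.Series(self.groups).reindex(self.ct.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise CtDataError(f"sample {missing!r} has no group label")
        if self.target_gene is not None and self.target_gene not in self.ct.columns:
            raise CtDataError(f"unknown target gene {self.target_gene!r}")

    # -- convenience views -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def candidate_genes(self) -> list[str]:
        """Genes excluding the designated target."""
        return [g for g in self.ct.columns if g != self.target_gene]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts(sort=False)

    def subset(self, genes: Iterable[str]) -> "CtTable":
        genes = list(genes)
        target = self.target_gene if self.target_gene in genes else None
        return CtTable(self.ct[genes].copy(), self.groups.copy(), target)

    def drop_samples(self, sample_ids: Iterable[str]) -> "CtTable":
        keep = self.ct.index.difference(list(sample_ids))
        return CtTable(
            self.ct.loc[keep].copy(), self.groups.loc[keep].copy(), self.target_gene
        )


@dataclass
class EfficiencyMap:
    """Per-gene amplification efficiency E (fold per cycle, E = 2 is 100 %)."""

    efficiencies: Mapping[str, float]

    def __post_init__(self) -> None:
        self.efficiencies = dict(self.efficiencies)
        for gene, e in self.efficiencies.items():
            if not np.isfinite(e) or e <= 1.0:
                raise CtDataError(f"efficiency for {gene!r} must be > 1, got {e}")

    @classmethod
    def uniform(cls, genes: Iterable[str], e: float = 2.0) -> "EfficiencyMap":
        return cls({g: e for g in genes})

    @classmethod
    def from_percent(cls, percent: Mapping[str, float]) -> "EfficiencyMap":
        """Build from efficiency percentages (98 -> E = 1.98)."""
        return cls({g: 1.0 + p / 100.0 for g, p in percent.items()})

    def __getitem__(self, gene: str) -> float:
        return self.efficiencies[gene]

    def covers(self, genes: Iterable[str]) -> bool:
        return all(g in self.efficiencies for g in genes)


@dataclass
class RelativeQuantityTable:
    """Efficiency-transformed expression quantities on the linear scale.

    Under the default per-gene minimum-Ct calibrator each gene's maximum RQ
    is exactly 1 and all values lie in (0, 1].
    """

    rq: pd.DataFrame
    groups: pd.Series
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if (self.rq <= 0).any().any():
            raise CtDataError("relative quantities must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.rq.columns)

    @property
    def candidate_genes(self) -> list[str]:
        return [g for g in self.rq.columns if g != self.target_gene]

    def subset(self, genes: Iterable[str]) -> "RelativeQuantityTable":
        genes = list(genes)
        target = self.target_gene if self.target_gene in genes else None
        return RelativeQuantityTable(self.rq[genes].copy(), self.groups.copy(), target)


@dataclass
class DilutionSeries:
    """Standard-curve input: replicate Ct values over a serial dilution.

    ``points`` maps gene -> DataFrame with columns ``log10_amount`` and
    ``ct`` (one row per replicate measurement).
    """

    points: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        self.points = {g: pd.DataFrame(df) for g, df in self.points.items()}
        for gene, df in self.points.items():
            if not {"log10_amount", "ct"} <= set(df.columns):
                raise CtDataError(
                    f"dilution series for {gene!r} needs log10_amount and ct columns"
                )
            if df["log10_amount"].nunique() < 3:
                raise CtDataError(
                    f"dilution series for {gene!r} needs >= 3 distinct points"
                )

    @classmethod
    def read_csv(cls, path: str | Path) -> "DilutionSeries":
        long = pd.read_csv(path)
        return cls({g: df[["log10_amount", "ct"]] for g, df in long.groupby("gene")})


@dataclass
class DilutionFit:
    """Per-gene standard-curve fit and the efficiency acceptance verdict."""

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    acceptable: bool


# ---------------------------------------------------------------------------
# I/O


def read_ct_table(
    path: str | Path,
    group_column: str = "group",
    target: str | None = None,
    missing: Literal["error", "drop-sample"] = "error",
) -> CtTable:
    """Read a wide-format Ct CSV: sample id in the first column, one group
    column, and one numeric column per gene.

    Parameters
    ----------
    missing
        ``"error"`` (default) rejects any blank/non-numeric Ct cell;
        ``"drop-sample"`` removes the affected sample from all genes —
        every downstream method requires a complete matrix, and silent
        imputation would distort SD-based statistics.
    """
    raw = pd.read_csv(path, index_col=0)
    if group_column not in raw.columns:
        raise CtDataError(f"group column {group_column!r} not found")
    groups = raw[group_column].astype(str)
    gene_cols = [c for c in raw.columns if c != group_column]
    ct = raw[gene_cols].apply(pd.to_numeric, errors="coerce")
    bad = ct.isna()
    if bad.any().any():
        if missing == "drop-sample":
            ct = ct.loc[~bad.any(axis=1)]
            groups = groups.loc[ct.index]
        else:
            sample = ct.index[bad.any(axis=1)][0]
            gene = ct.columns[bad.loc[sample].values][0]
            raise CtDataError(
                f"missing or non-numeric Ct for sample {sample!r}, gene {gene!r}"
            )
    if target is not None and target not in gene_cols:
        raise CtDataError(f"unknown target gene {target!r}")
    return CtTable(ct, groups, target)


def write_ct_table(table: CtTable, path: str | Path, group_column: str = "group") -> None:
    """Write a CtTable back to the same wide CSV schema ``read_ct_table`` reads."""
    out = table.ct.copy()
    out.insert(0, group_column, table.groups)
    out.index.name = out.index.name or "sample"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Transforms


def ct_to_relative_quantity(
    table: CtTable,
    eff: EfficiencyMap | None = None,
    calibrator: Literal["min", "mean"] = "min",
) -> RelativeQuantityTable:
    """Convert Ct to relative quantities: ``RQ = E^(Ct_cal - Ct)``.

    The default calibrator is the per-gene minimum Ct (the most abundant
    sample), which puts each gene's RQ in (0, 1].  geNorm ratios, ΔCt
    differences and NormFinder's gene-centred model are all invariant to
    the calibrator choice; it only fixes the per-gene scale.
    """
    if eff is None:
        eff = EfficiencyMap.uniform(table.genes)
    if not eff.covers(table.genes):
        missing = [g for g in table.genes if g not in eff.efficiencies]
        raise CtDataError(f"no efficiency for genes {missing}")
    rq = {}
    for gene in table.genes:
        ct = table.ct[gene]
        ct_cal = ct.min() if calibrator == "min" else ct.mean()
        rq[gene] = np.power(eff[gene], ct_cal - ct)
    return RelativeQuantityTable(
        pd.DataFrame(rq, index=table.ct.index), table.groups.copy(), table.target_gene
    )


def log2_rq(table: RelativeQuantityTable) -> pd.DataFrame:
    """Elementwise log2 of the relative quantities (shape preserved)."""
    return np.log2(table.rq)


def efficiency_from_dilution(
    series: DilutionSeries,
    min_percent: float = 90.0,
    max_percent: float = 110.0,
    min_r_squared: float = 0.99,
) -> dict[str, DilutionFit]:
    """Estimate amplification efficiency per gene from a standard curve.

    Least-squares fit of Ct on log10(input amount); efficiency% is
    ``(10^(-1/slope) - 1) * 100``.  A fit is flagged acceptable when the
    efficiency lies in [90, 110] % and R² >= 0.99.
    """
    fits: dict[str, DilutionFit] = {}
    for gene, df in series.points.items():
        x = df["log10_amount"].to_numpy(float)
        y = df["ct"].to_numpy(float)
        if np.ptp(x) == 0:
            raise CtDataError(f"zero variance in dilution amounts for {gene!r}")
        res = stats.linregress(x, y)
        eff_pct = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
        r2 = res.rvalue**2
        fits[gene] = DilutionFit(
            gene=gene,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(r2),
            efficiency_percent=float(eff_pct),
            acceptable=bool(min_percent <= eff_pct <= max_percent and r2 >= min_r_squared),
        )
    return fits
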