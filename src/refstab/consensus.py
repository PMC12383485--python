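"""Consensus ranking and the stepwise reference-gene validation workflow.

The consensus follows the RefFinder convention: each stability method
(geNorm, NormFinder, BestKeeper dispersion, pairwise ΔCt) contributes a
per-gene rank, and genes are ordered by the geometric mean of their ranks.
Before aggregation the workflow applies the exclusion filters a careful
validation study uses:

1. compute all four method results and ranks on the full candidate panel;
2. abundance filter — a reference whose mean Ct sits more than 5 cycles
   from the target amplifies in a different phase of the reaction and is
   excluded;
3. co-regulation filter — a reference whose Ct correlates strongly and
   significantly with the target is not a neutral control and is excluded
   (a regression slope vs the BestKeeper index well above 1 raises an
   advisory flag but never excludes on its own);
4. inter-group filter — a reference with a significant one-way ANOVA
   across experimental groups responds to treatment and is excluded;
5. threshold audit — the published per-method guideline cutoffs are
   checked and reported as advisory flags;
6. method ranks are recomputed on the surviving genes and aggregated by
   geometric mean;
7. the best gene, best pair and best triplet are the top 1/2/3 survivors.

Every decision is recorded with its evidence in the report's decision log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .bestkeeper import (
    IndexRegression,
    TargetCorrelation,
    bestkeeper_index,
    correlation_with_target,
    descriptive_stats,
    gene_vs_index_regression,
)
from .ctdata import CtTable, EfficiencyMap, ct_to_relative_quantity
from .deltact import pairwise_delta_ct, rank_by_mean_sd, sd_letter_groups
from .genorm import StabilityThresholds, genorm_ranking
from .intergroup import anova_per_gene
from .normfinder import normfinder_stability

__all__ = [
    "MethodRanks",
    "ConsensusRanking",
    "ValidationReport",
    "WorkflowConfig",
    "aggregate_ranks",
    "abundance_filter",
    "coregulation_filter",
    "run_workflow",
    "render_report",
]

METHODS = ["genorm", "normfinder", "bestkeeper", "delta_ct"]


@dataclass
class WorkflowConfig:
    """Tunable knobs of the validation workflow."""

    thresholds: StabilityThresholds = field(default_factory=StabilityThresholds)
    efficiency: EfficiencyMap | None = None
    calibrator: str = "min"
    dispersion: str = "mad"
    posthoc_method: str = "tukey"

    @classmethod
    def from_mapping(cls, data: Mapping) -> "WorkflowConfig":
        data = dict(data)
        thr = StabilityThresholds(**data.pop("thresholds", {}))
        eff = data.pop("efficiency", None)
        if eff is not None:
            eff = EfficiencyMap(eff)
        return cls(thresholds=thr, efficiency=eff, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class MethodRanks:
    """Per-gene rank under each stability method (average ranks on ties)."""

    ranks: pd.DataFrame  # genes x methods; NaN where a method is unavailable

    @property
    def available(self) -> pd.DataFrame:
        return self.ranks.notna()


@dataclass
class ConsensusRanking:
    """Geometric-mean rank per gene and the resulting order."""

    geomean_rank: pd.Series
    order: list[str]  # most stable first

    def to_frame(self) -> pd.DataFrame:
        out = self.geomean_rank.to_frame("geomean_rank")
        out["final_rank"] = [self.order.index(g) + 1 for g in out.index]
        return out


@dataclass
class ValidationReport:
    """Everything the workflow computed, plus the decision log."""

    candidates: list[str]
    target_gene: str | None
    method_ranks_full: MethodRanks
    genorm: object
    normfinder: object
    descriptives: object
    index_regression: IndexRegression
    target_correlation: TargetCorrelation | None
    delta_ct: object
    delta_ct_letters: pd.Series
    anova: pd.DataFrame
    abundance: pd.DataFrame | None
    coregulation: pd.DataFrame | None
    threshold_audit: pd.DataFrame
    survivors: list[str]
    consensus: ConsensusRanking | None
    best_gene: str | None
    best_pair: list[str] | None
    best_triplet: list[str] | None
    status: str  # "ok" | "insufficient stable genes"
    decision_log: list[dict]
    thresholds: StabilityThresholds


def _average_ranks(score: pd.Series) -> pd.Series:
    return pd.Series(
        stats.rankdata(score.to_numpy(float), method="average"),
        index=score.index,
    )


def aggregate_ranks(ranks: MethodRanks) -> ConsensusRanking:
    """Geometric mean of each gene's available method ranks."""
    df = ranks.ranks
    if df.notna().sum(axis=1).min() < 2:
        raise ValueError("need >= 2 available methods per gene")
    geo = np.exp(np.log(df).mean(axis=1, skipna=True)).rename("geomean_rank")
    order = list(geo.sort_values(kind="stable").index)
    return ConsensusRanking(geomean_rank=geo, order=order)


def abundance_filter(
    table: CtTable, thresholds: StabilityThresholds | None = None
) -> pd.DataFrame:
    """Mean-Ct gap of each candidate to the target; fail iff gap > cutoff."""
    if table.target_gene is None:
        raise ValueError("abundance filter needs a designated target gene")
    thresholds = thresholds or StabilityThresholds()
    target_mean = table.ct[table.target_gene].mean()
    rows = {}
    for gene in table.candidate_genes:
        gap = abs(table.ct[gene].mean() - target_mean)
        rows[gene] = {
            "gap_cycles": float(gap),
            "passed": bool(gap <= thresholds.abundance_gap_cycles),
        }
    return pd.DataFrame(rows).T


def coregulation_filter(
    target_corr: TargetCorrelation,
    regression: IndexRegression,
    thresholds: StabilityThresholds | None = None,
) -> pd.DataFrame:
    """Fail a gene iff |r| >= cutoff with p < alpha against the target.

    A regression slope vs the index exceeding 1 by more than the slope
    margin raises the non-fatal ``slope_divergence`` flag: supporting
    evidence of non-independence, not a standalone exclusion criterion.
    """
    thresholds = thresholds or StabilityThresholds()
    rows = {}
    for gene in target_corr.table.columns:
        r = target_corr.table.at["r", gene]
        p = target_corr.table.at["p_value", gene]
        slope = (
            regression.table.at["slope", gene]
            if gene in regression.table.columns
            else np.nan
        )
        rows[gene] = {
            "r": float(r),
            "p_value": float(p),
            "slope": float(slope),
            "slope_divergence": bool(
                np.isfinite(slope) and slope > 1.0 + thresholds.slope_margin
            ),
            "passed": not (abs(r) >= thresholds.coregulation_r and p < thresholds.alpha),
        }
    return pd.DataFrame(rows).T


def _method_ranks(
    table: CtTable,
    genes: list[str],
    config: WorkflowConfig,
) -> tuple[MethodRanks, dict]:
    """Rank the given genes under each method, recomputed on that panel."""
    rq = ct_to_relative_quantity(
        table.subset(genes), config.efficiency, config.calibrator
    )
    parts: dict = {}
    ranks = pd.DataFrame(index=genes, columns=METHODS, dtype=float)

    gn = genorm_ranking(rq, genes)
    parts["genorm"] = gn
    ranks["genorm"] = gn.ranking.astype(float)

    nf = normfinder_stability(rq, genes)
    parts["normfinder"] = nf
    ranks["normfinder"] = _average_ranks(nf.stability)

    desc = descriptive_stats(table, genes, convention=config.dispersion)
    parts["descriptives"] = desc
    ranks["bestkeeper"] = _average_ranks(desc.table.loc["dispersion"])

    dct = pairwise_delta_ct(table, genes)
    parts["delta_ct"] = dct
    ranks["delta_ct"] = _average_ranks(dct.mean_sd)

    return MethodRanks(ranks), parts


def run_workflow(table: CtTable, config: WorkflowConfig | None = None) -> ValidationReport:
    """Execute the full stepwise validation on a Ct table."""
    config = config or WorkflowConfig()
    thr = config.thresholds
    candidates = table.candidate_genes
    if len(candidates) < 3:
        raise ValueError("workflow needs >= 3 candidate reference genes")
    log: list[dict] = []

    # -- step 1: all methods on the full panel -----------------------------
    full_ranks, parts = _method_ranks(table, candidates, config)
    gn, nf, desc, dct = (
        parts["genorm"], parts["normfinder"], parts["descriptives"], parts["delta_ct"]
    )
    letters = sd_letter_groups(dct, alpha=thr.alpha)
    index = bestkeeper_index(table, candidates)
    reg = gene_vs_index_regression(table, index, candidates)
    anova_res = anova_per_gene(table, candidates, alpha=thr.alpha)
    log.append({
        "step": 1,
        "action": "computed geNorm, NormFinder, BestKeeper and pairwise dCt on all candidates",
        "genes": list(candidates),
    })

    survivors = list(candidates)

    # -- step 2: abundance gap to the target --------------------------------
    abundance = None
    if table.target_gene is not None:
        abundance = abundance_filter(table, thr)
        for gene in candidates:
            if not abundance.at[gene, "passed"]:
                survivors.remove(gene)
                log.append({
                    "step": 2, "action": "excluded", "gene": gene,
                    "reason": f"mean-Ct gap to {table.target_gene} "
                              f"{abundance.at[gene, 'gap_cycles']:.2f} cycles "
                              f"> {thr.abundance_gap_cycles:g}",
                })
    else:
        log.append({"step": 2, "action": "skipped", "reason": "no target gene designated"})

    # -- step 3: co-regulation with the target -------------------------------
    coreg = None
    target_corr = None
    if table.target_gene is not None:
        target_corr = correlation_with_target(table, candidates)
        coreg = coregulation_filter(target_corr, reg, thr)
        for gene in candidates:
            if gene in survivors and not coreg.at[gene, "passed"]:
                survivors.remove(gene)
                log.append({
                    "step": 3, "action": "excluded", "gene": gene,
                    "reason": f"co-regulated with target: r={coreg.at[gene, 'r']:.3f}, "
                              f"p={coreg.at[gene, 'p_value']:.3g}",
                })
        for gene in candidates:
            if coreg.at[gene, "slope_divergence"]:
                log.append({
                    "step": 3, "action": "flagged", "gene": gene,
                    "reason": f"index-regression slope {coreg.at[gene, 'slope']:.2f} > "
                              f"{1 + thr.slope_margin:g} (non-independence, advisory)",
                })
    else:
        log.append({"step": 3, "action": "skipped", "reason": "no target gene designated"})

    # -- step 4: inter-group ANOVA -------------------------------------------
    for gene in candidates:
        if gene in survivors and not anova_res.anova.at[gene, "stable"]:
            survivors.remove(gene)
            log.append({
                "step": 4, "action": "excluded", "gene": gene,
                "reason": f"significant inter-group ANOVA: "
                          f"p={anova_res.anova.at[gene, 'p_value']:.3g} < {thr.alpha:g}",
            })

    # -- step 5: advisory threshold audit ------------------------------------
    audit = pd.DataFrame({
        "genorm_m": gn.m,
        "m_lt_heterogeneous": gn.m < thr.genorm_m_heterogeneous,
        "m_lt_homogeneous": gn.m < thr.genorm_m_homogeneous,
        "normfinder_rho": nf.stability,
        "rho_lt_cutoff": nf.stability < thr.normfinder_stability,
        "bk_dispersion": desc.table.loc["dispersion"],
        "sd_lt_1": desc.table.loc["dispersion"] < thr.bestkeeper_sd,
        "cv_percent": desc.table.loc["cv_percent"],
        "cv_lt_2": desc.table.loc["cv_percent"] < thr.bestkeeper_cv_percent,
        "r_vs_index": reg.table.loc["r"],
        "r_ge_cutoff": reg.table.loc["r"] >= thr.bestkeeper_r,
    })
    for gene in candidates:
        flags = [
            c for c in ["m_lt_homogeneous", "rho_lt_cutoff", "sd_lt_1", "cv_lt_2", "r_ge_cutoff"]
            if not audit.at[gene, c]
        ]
        if flags:
            log.append({
                "step": 5, "action": "audit-flag", "gene": gene,
                "reason": "guideline thresholds not met: " + ", ".join(flags),
            })

    # -- steps 6-7: consensus on survivors and recommendations ---------------
    consensus = None
    best = pair = triplet = None
    if len(survivors) < 2:
        status = "insufficient stable genes"
        log.append({"step": 6, "action": "aborted",
                    "reason": f"only {len(survivors)} survivor(s)"})
        if len(survivors) == 1:
            best = survivors[0]
    else:
        status = "ok"
        if len(survivors) >= 3:
            surv_ranks, _ = _method_ranks(table, survivors, config)
            consensus = aggregate_ranks(surv_ranks)
        else:
            # too few genes to re-run the panel methods: order the pair by
            # the full-panel consensus restricted to the survivors
            full = aggregate_ranks(full_ranks)
            geo = full.geomean_rank[survivors]
            consensus = ConsensusRanking(
                geomean_rank=geo, order=list(geo.sort_values(kind="stable").index)
            )
            log.append({"step": 6, "action": "degraded",
                        "reason": "fewer than 3 survivors; ranked by full-panel consensus"})
        best = consensus.order[0]
        pair = consensus.order[:2]
        triplet = consensus.order[:3] if len(survivors) >= 3 else None
        if triplet is None:
            log.append({"step": 7, "action": "warning",
                        "reason": "fewer than 3 survivors; no triplet recommended"})
        log.append({
            "step": 7, "action": "recommended",
            "best": best, "pair": pair, "triplet": triplet,
        })

    return ValidationReport(
        candidates=candidates,
        target_gene=table.target_gene,
        method_ranks_full=full_ranks,
        genorm=gn,
        normfinder=nf,
        descriptives=desc,
        index_regression=reg,
        target_correlation=target_corr,
        delta_ct=dct,
        delta_ct_letters=letters,
        anova=anova_res.anova,
        abundance=abundance,
        coregulation=coreg,
        threshold_audit=audit,
        survivors=survivors,
        consensus=consensus,
        best_gene=best,
        best_pair=pair,
        best_triplet=triplet,
        status=status,
        decision_log=log,
        thresholds=thr,
    )


# ---------------------------------------------------------------------------
# Rendering


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json())
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_dict(report: ValidationReport) -> dict:
    """JSON-ready summary of a validation report."""
    return _jsonable({
        "status": report.status,
        "candidates": report.candidates,
        "target_gene": report.target_gene,
        "survivors": report.survivors,
        "best_gene": report.best_gene,
        "best_pair": report.best_pair,
        "best_triplet": report.best_triplet,
        "method_ranks": report.method_ranks_full.ranks,
        "genorm_m": report.genorm.m,
        "normfinder_rho": report.normfinder.stability,
        "bestkeeper_descriptives": report.descriptives.table,
        "index_regression": report.index_regression.table,
        "target_correlation": (
            report.target_correlation.table if report.target_correlation else None
        ),
        "delta_ct_mean_sd": report.delta_ct.mean_sd,
        "delta_ct_letters": report.delta_ct_letters,
        "anova": report.anova,
        "abundance": report.abundance,
        "coregulation": report.coregulation,
        "threshold_audit": report.threshold_audit,
        "consensus": report.consensus.to_frame() if report.consensus else None,
        "decision_log": report.decision_log,
    })


def _markdown(report: ValidationReport) -> str:
    lines = ["# Reference-gene stability validation report", ""]
    lines += [f"Status: **{report.status}**", ""]
    if report.best_gene:
        lines += [f"- Best gene: **{report.best_gene}**"]
    if report.best_pair:
        lines += [f"- Best pair: **{', '.join(report.best_pair)}**"]
    if report.best_triplet:
        lines += [f"- Best triplet: **{', '.join(report.best_triplet)}**"]
    lines += [""]

    def section(title: str, frame: pd.DataFrame | pd.Series | None):
        if frame is None:
            return
        lines.append(f"## {title}")
        lines.append("")
        shown = frame.round(4)
        fmt = lambda p: "0.00" if p < 0.0005 else f"{p:.4g}"
        if isinstance(shown, pd.DataFrame) and "p_value" in shown.columns:
            shown = shown.copy()
            shown["p_value"] = [fmt(p) for p in frame["p_value"]]
        elif isinstance(shown, pd.DataFrame) and "p_value" in shown.index:
            shown = shown.astype(object)
            shown.loc["p_value"] = [fmt(p) for p in frame.loc["p_value"]]
        lines.append("```")
        lines.append(shown.to_string())
        lines.append("```")
        lines.append("")

    section("geNorm M-values", report.genorm.to_frame())
    section("NormFinder stability", report.normfinder.to_frame())
    section("BestKeeper descriptive statistics", report.descriptives.table)
    section("Regression vs BestKeeper index", report.index_regression.table)
    if report.target_correlation is not None:
        section(
            f"Correlation with target ({report.target_correlation.target_gene})",
            report.target_correlation.table,
        )
    dct_frame = report.delta_ct.mean_sd.to_frame("mean_sd")
    dct_frame["letter"] = report.delta_ct_letters
    section("Pairwise ΔCt per-gene mean SD", dct_frame)
    section("Inter-group ANOVA", report.anova)
    if report.abundance is not None:
        section("Abundance gap vs target", report.abundance)
    if report.coregulation is not None:
        section("Co-regulation filter", report.coregulation)
    if report.consensus is not None:
        section("Consensus (geometric-mean rank over survivors)", report.consensus.to_frame())

    lines.append("## Decision log")
    lines.append("")
    for entry in report.decision_log:
        detail = {k: v for k, v in entry.items() if k not in ("step", "action")}
        lines.append(f"- step {entry['step']} [{entry['action']}] {detail}")
    lines.append("")
    return "\n".join(lines)


def render_report(
    report: ValidationReport,
    out_dir: str | Path,
    formats: Iterable[str] = ("md", "json", "csv", "png"),
) -> list[Path]:
    """Write the report bundle; returns the paths written.

    ``csv`` emits one file per result block (descriptives, regression,
    target correlation, pairwise ΔCt long table, method ranks, consensus,
    ANOVA).  ``png`` draws the consensus bar chart.  p-values below 0.0005
    are displayed as ``0.00`` in the Markdown tables only; stored values
    stay exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = set(formats)
    written: list[Path] = []

    if "json" in formats:
        path = out_dir / "report.json"
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=2)
        written.append(path)

    if "md" in formats:
        path = out_dir / "report.md"
        path.write_text(_markdown(report))
        written.append(path)

    if "csv" in formats:
        blocks = {
            "genorm.csv": report.genorm.to_frame(),
            "normfinder.csv": report.normfinder.to_frame(),
            "bestkeeper_descriptives.csv": report.descriptives.table,
            "index_regression.csv": report.index_regression.table,
            "delta_ct_pairs.csv": report.delta_ct.to_long_frame(),
            "method_ranks.csv": report.method_ranks_full.ranks,
            "anova.csv": report.anova,
        }
        if report.target_correlation is not None:
            blocks["target_correlation.csv"] = report.target_correlation.table
        if report.consensus is not None:
            blocks["consensus.csv"] = report.consensus.to_frame()
        for name, frame in blocks.items():
            path = out_dir / name
            frame.to_csv(path)
            written.append(path)

    if "png" in formats and report.consensus is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        geo = report.consensus.geomean_rank.loc[report.consensus.order]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(geo.index, geo.to_numpy(), color="#4878a8")
        ax.set_ylabel("geometric-mean rank")
        ax.set_title("Consensus stability ranking (lower = more stable)")
        fig.tight_layout()
        path = out_dir / "consensus_ranking.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    return written
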