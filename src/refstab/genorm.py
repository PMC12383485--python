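"""geNorm expression-stability measure M with iterative least-stable exclusion.

For genes j, k the pairwise variation ``V_jk`` is the sample SD (n-1
denominator) over samples of ``log2(RQ_j / RQ_k)``; a gene's M-value is the
arithmetic mean of its pairwise variations against every other gene in the
active set.  Because V is built from ratios, M is invariant to per-gene
rescaling of the quantities — the calibrator choice cancels.  The ranking
procedure repeatedly drops the highest-M gene and recomputes M on the
survivors until two genes remain; those two cannot be separated by M (their
M values are equal by construction) and keep ranks 1–2 ordered by their
full-panel M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctdata import RelativeQuantityTable, log2_rq

__all__ = [
    "StabilityThresholds",
    "GeNormResult",
    "pairwise_variation",
    "m_values",
    "genorm_ranking",
    "normalization_factor_variation",
]


@dataclass
class StabilityThresholds:
    """Published guideline cutoffs used by the threshold audit and filters.

    All are advisory conventions from the respective tools' documentation,
    exposed as configuration: geNorm M < 1.0 for heterogeneous and < 0.5
    for homogeneous sample sets; NormFinder stability < 0.15; BestKeeper
    SD < 1 cycle, CV < 2 %, r vs index >= 0.9; an abundance gap to the
    target above 5 cycles disqualifies a reference; |r| >= 0.65 (with
    p < alpha) against the target flags co-regulation — the default cutoff
    is the Fisher-z midpoint between a correlation regarded as benign
    (r = 0.512) and one regarded as disqualifying (r = 0.759), i.e. the
    maximum-margin separator of those reference cases; regression slope
    more than ``slope_margin`` above 1 flags non-independence; V_k/k+1
    below 0.15 means k references suffice.
    """

    genorm_m_heterogeneous: float = 1.0
    genorm_m_homogeneous: float = 0.5
    normfinder_stability: float = 0.15
    bestkeeper_sd: float = 1.0
    bestkeeper_cv_percent: float = 2.0
    bestkeeper_r: float = 0.9
    abundance_gap_cycles: float = 5.0
    coregulation_r: float = 0.65
    slope_margin: float = 0.2
    v_threshold: float = 0.15
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class GeNormResult:
    """Full-panel M-values, ranking and the exclusion trajectory."""

    m: pd.Series                      # full-panel M per gene
    ranking: pd.Series                # 1 = most stable
    exclusion_order: list[str]        # worst first
    best_pair: tuple[str, str]        # the two survivors
    v_curve: pd.Series | None = None  # V_k/k+1 indexed by k

    @property
    def ranked_genes(self) -> list[str]:
        return list(self.ranking.sort_values().index)

    def to_frame(self) -> pd.DataFrame:
        step = {g: i + 1 for i, g in enumerate(self.exclusion_order)}
        return pd.DataFrame(
            {
                "M": self.m,
                "rank": self.ranking,
                "excluded_at_step": pd.Series(
                    {g: step.get(g, np.nan) for g in self.m.index}
                ),
            }
        )


def pairwise_variation(
    rq: RelativeQuantityTable, gene_j: str, gene_k: str
) -> float:
    """SD over samples of the log2 ratio of two genes' quantities.

    Symmetric, non-negative, and invariant to rescaling either gene.
    Requesting a gene against itself returns 0 (degenerate but defined).
    """
    logs = log2_rq(rq)
    ratio = logs[gene_j] - logs[gene_k]
    if len(ratio) < 2:
        raise ValueError("pairwise variation needs >= 2 samples")
    return float(ratio.std(ddof=1))


def _log_matrix(rq: RelativeQuantityTable, genes: list[str]) -> np.ndarray:
    return np.log2(rq.rq[genes].to_numpy(float))


def _m_from_logs(logs: np.ndarray) -> np.ndarray:
    """M per column: mean over other columns of SD(log ratio)."""
    n = logs.shape[1]
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            v[j, k] = v[k, j] = np.std(logs[:, j] - logs[:, k], ddof=1)
    return v.sum(axis=1) / (n - 1)


def m_values(
    rq: RelativeQuantityTable, genes: list[str] | None = None
) -> pd.Series:
    """M-value per gene over the given active set (>= 3 genes).

    For a 2-gene set the shared pairwise variation is returned for both
    genes (the value is then uninformative for choosing between them).
    """
    genes = list(genes) if genes is not None else rq.candidate_genes
    if len(genes) < 2:
        raise ValueError("M-values need >= 2 genes")
    if len(genes) == 2:
        shared = pairwise_variation(rq, genes[0], genes[1])
        return pd.Series([shared, shared], index=genes, name="M")
    m = _m_from_logs(_log_matrix(rq, genes))
    return pd.Series(m, index=genes, name="M")


def genorm_ranking(
    rq: RelativeQuantityTable,
    genes: list[str] | None = None,
    with_v_curve: bool = True,
) -> GeNormResult:
    """Iterative least-stable-gene exclusion.

    Ties in M are broken by (lower full-panel M, then input gene order) so
    that the output is deterministic.
    """
    genes = list(genes) if genes is not None else rq.candidate_genes
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs >= 3 genes")
    full_m = m_values(rq, genes)
    order = {g: i for i, g in enumerate(genes)}

    active = list(genes)
    exclusion: list[str] = []
    while len(active) > 2:
        m = m_values(rq, active)
        # worst = highest M; ties -> higher full-panel M, then later input order
        worst = max(active, key=lambda g: (m[g], full_m[g], order[g]))
        exclusion.append(worst)
        active.remove(worst)

    pair = sorted(active, key=lambda g: (full_m[g], order[g]))
    ranking = pd.Series(index=full_m.index, dtype=int, name="rank")
    ranking[pair[0]], ranking[pair[1]] = 1, 2
    for i, g in enumerate(reversed(exclusion)):
        ranking[g] = 3 + i

    v_curve = None
    if with_v_curve and len(genes) >= 3:
        ranked = list(ranking.sort_values().index)
        v_curve = normalization_factor_variation(rq, ranked)
    return GeNormResult(
        m=full_m,
        ranking=ranking,
        exclusion_order=exclusion,
        best_pair=(pair[0], pair[1]),
        v_curve=v_curve,
    )


def normalization_factor_variation(
    rq: RelativeQuantityTable, ranked_genes: list[str]
) -> pd.Series:
    """Pairwise variation V_k/k+1 of successive normalization factors.

    ``NF_k`` is the geometric mean of the top-k ranked genes' quantities
    per sample; ``V_k`` is the SD over samples of ``log2(NF_k / NF_k+1)``.
    A small V_k indicates that adding the (k+1)-th gene no longer changes
    the normalization factor, i.e. k references suffice.
    """
    if len(ranked_genes) < 3:
        raise ValueError("V curve needs >= 3 ranked genes")
    logs = np.log2(rq.rq[ranked_genes].to_numpy(float))
    out = {}
    for k in range(2, len(ranked_genes)):
        nf_k = logs[:, :k].mean(axis=1)          # log2 of geometric mean
        nf_k1 = logs[:, : k + 1].mean(axis=1)
        out[k] = float(np.std(nf_k - nf_k1, ddof=1))
    return pd.Series(out, name="V_k/k+1").rename_axis("k")
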