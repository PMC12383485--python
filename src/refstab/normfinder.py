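"""Model-based stability estimation separating intra- and inter-group variation.

The estimator follows the Andersen-style variance-decomposition idea:
log-scale expression of gene i in group g, replicate j, is centred by the
per-sample mean over genes (removing the shared sample-loading effect),
then decomposed into an intragroup variance and a between-group deviation
of the gene-specific group means.  Because the sample-centred residual of
gene i contains a -1/n share of every gene's noise, the raw intragroup
variance is corrected for that contamination; the intergroup deviation is
shrunk towards zero in proportion to its estimation noise, so that genes
measured imprecisely are not spuriously called differentially expressed.

Stability for gene i:

    rho_i = mean over groups of ( |d~_ig| + sqrt(sigma^2_ig / n_g) )

i.e. the magnitude of the (shrunken) systematic group effect plus the
standard error of the gene's group mean.  Lower is more stable.  With a
single group the score reduces to the corrected intragroup SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctdata import RelativeQuantityTable, log2_rq

__all__ = ["NormFinderResult", "normfinder_stability"]


@dataclass
class NormFinderResult:
    """Per-gene stability with its per-group variance components."""

    stability: pd.Series            # rho per gene; lower = more stable
    ranking: pd.Series              # 1 = most stable
    intra_var: pd.DataFrame         # sigma^2_ig, genes x groups
    inter_dev: pd.DataFrame         # shrunken d~_ig, genes x groups
    gamma_sq: pd.Series | float     # per-gene between-group variance gamma^2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.stability, "rank": self.ranking})


def normfinder_stability(
    rq: RelativeQuantityTable, genes: list[str] | None = None
) -> NormFinderResult:
    """Compute per-gene stability values from relative quantities.

    Requires >= 3 genes when more than one group is present (the
    sample-centring contamination correction has an n/(n-2) factor), and
    >= 2 replicates per group.  Both clamps (intragroup variance and the
    between-group variance gamma^2) floor method-of-moments estimates at
    zero, which small replicate counts can otherwise push negative.
    """
    genes = list(genes) if genes is not None else rq.candidate_genes
    n = len(genes)
    logs = log2_rq(rq.subset(genes))
    groups = rq.groups
    labels = list(dict.fromkeys(groups))
    G = len(labels)

    if G > 1 and n < 3:
        raise ValueError("group-aware stability needs >= 3 genes")
    sizes = {g: int((groups == g).sum()) for g in labels}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs >= 2 replicates")

    # sample-centre: remove the per-sample mean over genes
    z = logs.sub(logs.mean(axis=1), axis=0)

    m = pd.DataFrame(index=genes, columns=labels, dtype=float)   # group means
    s2 = pd.DataFrame(index=genes, columns=labels, dtype=float)  # raw variances
    for g in labels:
        block = z.loc[groups == g]
        m[g] = block.mean(axis=0)
        s2[g] = block.var(axis=0, ddof=1)

    if G == 1:
        g = labels[0]
        if n >= 3:
            corr = (s2[g] - s2[g].sum() / (n * (n - 1))) * n / (n - 2)
            sigma2 = corr.clip(lower=0.0)
        else:
            sigma2 = s2[g].clip(lower=0.0)
        rho = np.sqrt(sigma2)
        ranking = _rank(rho, genes)
        return NormFinderResult(
            stability=rho.rename("rho"),
            ranking=ranking,
            intra_var=sigma2.to_frame(g),
            inter_dev=pd.DataFrame(0.0, index=genes, columns=[g]),
            gamma_sq=0.0,
        )

    # correct each gene's intragroup variance for the -1/n centring share
    sigma2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for g in labels:
        S_g = s2[g].sum()
        sigma2[g] = ((s2[g] - S_g / (n * (n - 1))) * n / (n - 2)).clip(lower=0.0)

    # intergroup deviations and their per-gene shrinkage: the deviations
    # sum to zero across groups, so their G-1 variance is sum(d^2)/(G-1);
    # subtracting the mean sampling noise of the group means yields the
    # systematic between-group variance gamma^2_i
    d = m.sub(m.mean(axis=1), axis=0)
    n_g = pd.Series(sizes)
    sampling_var = sigma2.div(n_g, axis=1)
    gamma2 = (d.pow(2).sum(axis=1) / (G - 1) - sampling_var.mean(axis=1)).clip(lower=0.0)

    denom = sampling_var.add(gamma2, axis=0)
    shrink = denom.rdiv(gamma2, axis=0).where(denom > 0, 0.0)
    d_tilde = d * shrink

    se = np.sqrt(sigma2.div(n_g, axis=1))
    rho = (d_tilde.abs() + se).mean(axis=1).rename("rho")
    ranking = _rank(rho, genes)
    return NormFinderResult(
        stability=rho,
        ranking=ranking,
        intra_var=sigma2,
        inter_dev=d_tilde,
        gamma_sq=gamma2.rename("gamma_sq"),
    )


def _rank(score: pd.Series, input_order: list[str]) -> pd.Series:
    order = {g: i for i, g in enumerate(input_order)}
    ranked = sorted(score.index, key=lambda g: (score[g], order[g]))
    return pd.Series(
        {g: i + 1 for i, g in enumerate(ranked)}, name="rank"
    ).reindex(score.index)
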