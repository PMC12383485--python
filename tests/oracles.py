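"""Independent brute-force reference implementations used only in tests.

Every function here recomputes a quantity from first principles with the
most literal possible code (explicit loops, closed forms, exhaustive
enumeration), deliberately sharing nothing with the package's
implementation paths.
"""

import itertools
import math

import numpy as np


def sample_sd(values):
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def brute_pairwise_variation(log_j, log_k):
    """SD of elementwise log-ratios."""
    return sample_sd([a - b for a, b in zip(log_j, log_k)])


def brute_m_values(logs):
    """logs: samples x genes array of log2 quantities -> list of M."""
    logs = np.asarray(logs, float)
    n = logs.shape[1]
    out = []
    for j in range(n):
        vs = [
            brute_pairwise_variation(logs[:, j], logs[:, k])
            for k in range(n)
            if k != j
        ]
        out.append(sum(vs) / len(vs))
    return out


def brute_genorm_exclusion(logs, genes):
    """Full reimplementation of iterative worst-gene removal.

    Ties broken by (full-panel M, input order), matching the documented
    deterministic convention.
    """
    full_m = dict(zip(genes, brute_m_values(logs)))
    order = {g: i for i, g in enumerate(genes)}
    active = list(genes)
    cols = {g: np.asarray(logs)[:, i] for i, g in enumerate(genes)}
    excluded = []
    while len(active) > 2:
        m = dict(
            zip(active, brute_m_values(np.column_stack([cols[g] for g in active])))
        )
        worst = max(active, key=lambda g: (m[g], full_m[g], order[g]))
        excluded.append(worst)
        active.remove(worst)
    pair = sorted(active, key=lambda g: (full_m[g], order[g]))
    return excluded, pair


def brute_geometric_mean(values):
    values = list(values)
    prod = 1.0
    for v in values:
        prod *= v
    return prod ** (1.0 / len(values))


def brute_index(ct_matrix):
    """Per-sample geometric mean over genes (rows = samples)."""
    return [brute_geometric_mean(row) for row in np.asarray(ct_matrix, float)]


def brute_ols(x, y):
    """Closed-form least squares: slope, intercept, pearson r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    slope = (xc * yc).sum() / (xc * xc).sum()
    intercept = y.mean() - slope * x.mean()
    r = (xc * yc).sum() / math.sqrt((xc * xc).sum() * (yc * yc).sum())
    return slope, intercept, r


def brute_anova_f(groups):
    """One-way fixed-effects F from sums of squares written out."""
    k = len(groups)
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def brute_pair_sds(ct_matrix, genes):
    """dict (gene_a, gene_b) -> SD of per-sample signed Ct differences."""
    ct = np.asarray(ct_matrix, float)
    out = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(genes), 2):
        out[(a, b)] = sample_sd(ct[:, i] - ct[:, j])
    return out


def brute_mannwhitney(x, y):
    """Exact two-sided Mann-Whitney by exhaustive enumeration.

    Enumerates all C(n+m, n) assignments of the pooled ranks (tie-free
    data only) and returns (U_x, two-sided p).
    """
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle needs tie-free data"
    rank_of = {v: i + 1 for i, v in enumerate(combined)}
    n, m = len(x), len(y)

    def u_of(ranks):
        return sum(ranks) - n * (n + 1) / 2

    u_obs = u_of([rank_of[v] for v in x])
    mid = n * m / 2.0
    total = 0
    extreme = 0
    for subset in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if abs(u_of(subset) - mid) >= abs(u_obs - mid) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def brute_normfinder_single_group(logs):
    """Single-group stability: corrected intragroup SD per gene.

    logs: samples x genes.  Sample-centre, take each gene's n-1 variance,
    subtract the centring contamination S/(n(n-1)), rescale by n/(n-2),
    clamp at zero, return the square roots.
    """
    logs = np.asarray(logs, float)
    z = logs - logs.mean(axis=1, keepdims=True)
    n = logs.shape[1]
    s2 = z.var(axis=0, ddof=1)
    corr = (s2 - s2.sum() / (n * (n - 1))) * n / (n - 2)
    return np.sqrt(np.clip(corr, 0.0, None))
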