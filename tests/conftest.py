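import numpy as np
import pandas as pd
import pytest

from refstab import CtTable, default_3t3l1_config, simulate_ct


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(ct_matrix, genes, groups, target=None, sample_ids=None):
    """Build a CtTable from a plain matrix (rows = samples)."""
    ct_matrix = np.asarray(ct_matrix, float)
    n = ct_matrix.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    ct = pd.DataFrame(ct_matrix, index=sample_ids, columns=genes)
    return CtTable(ct, pd.Series(list(groups), index=sample_ids), target)


def random_table(rng, n_genes=4, n_samples=8, n_groups=2, base=20.0, sd=0.5):
    """Random complete Ct table for oracle-equivalence checks."""
    genes = [f"g{i}" for i in range(n_genes)]
    ct = base + rng.normal(0, sd, size=(n_samples, n_genes)) + rng.uniform(
        0, 5, size=n_genes
    )
    groups = [f"grp{i % n_groups}" for i in range(n_samples)]
    return make_table(ct, genes, groups)


@pytest.fixture
def clean_panel():
    """One draw of the six-gene adipocyte panel plus target, no stressors."""
    table, truth = simulate_ct(default_3t3l1_config(), seed=7)
    return table


@pytest.fixture
def stressed_panel():
    """Panel with the co-regulated Actb and treatment-shifted GAPDH."""
    table, truth = simulate_ct(
        default_3t3l1_config(actb_coupling=0.76, gapdh_shift=0.6), seed=1
    )
    return table
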