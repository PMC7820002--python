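import numpy as np
import pandas as pd
import pytest

from mhelink import cohort as syn
from mhelink import diffexp as de
from mhelink.matrix import OmicsMatrix


def make_matrix(values, n_case, n_control, omic="gene", feature_ids=None):
    """Small OmicsMatrix helper: values is (features x samples) array-like."""
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    assert n == n_case + n_control
    cols = [f"P{i + 1:02d}" for i in range(n)]
    idx = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    groups = pd.Series(["MHE"] * n_case + ["CTRL"] * n_control, index=cols)
    return OmicsMatrix(pd.DataFrame(values, index=idx, columns=cols), groups, omic)


@pytest.fixture(scope="session")
def default_cohort():
    return syn.generate_full_cohort()


@pytest.fixture(scope="session")
def step1(default_cohort):
    """Normalized matrices and differential tables for the default cohort."""
    c = default_cohort
    gn = de.vst_normalize(c.genes)
    mn = de.vst_normalize(c.metabolites, calibrate=False)
    gene_table = de.moderated_ttest(gn)
    metab_table = de.moderated_ttest(mn)
    cyto_table = de.wilcoxon_panel(c.cytokines)
    return {
        "genes_norm": gn, "metab_norm": mn,
        "gene_table": gene_table, "metab_table": metab_table,
        "cyto_table": cyto_table,
        "sig_genes": de.significant_features(gene_table),
        "sig_metab": de.significant_features(metab_table),
        "sig_cyto": de.significant_features(cyto_table),
    }


@pytest.fixture(scope="session")
def serum_significant(default_cohort, step1):
    """Significant serum features (normalized metabolites + raw cytokines)."""
    vals = pd.concat([
        step1["metab_norm"].values.loc[step1["sig_metab"]],
        default_cohort.cytokines.values.loc[step1["sig_cyto"]],
    ])
    return OmicsMatrix(vals, default_cohort.groups, omic="serum")
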