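"""Shared two-group testing helpers (Welch test + Benjamini-Hochberg)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def welch_de_table(expr: pd.DataFrame, group_a: list, group_b: list) -> pd.DataFrame:
    """Gene-wise Welch comparison of two sample groups on a log-scale matrix.

    Returns a frame indexed by gene with columns ``logFC`` (mean A - mean B),
    ``p`` and ``fdr`` (Benjamini-Hochberg).  Genes with zero variance in both
    groups get p = 1 when the means agree and p = 0 otherwise (a deterministic
    difference).
    """
    a = expr.loc[:, group_a].to_numpy(dtype=float)
    b = expr.loc[:, group_b].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(logfc) <= 1e-12)] = 1.0
    p[degenerate & (np.abs(logfc) > 1e-12)] = 0.0
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({"logFC": logfc, "p": p, "fdr": fdr}, index=expr.index)
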