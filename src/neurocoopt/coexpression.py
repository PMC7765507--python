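"""Median expression correlation (MEC) of gene lists.

For each gene of a list, the MEC is the median Spearman correlation of its
expression profile with every other gene of the same list.  The median of
the per-gene MECs summarises how tightly a list is co-expressed; it is
compared against random control lists of equal size with a z-test on the
control medians.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ControlListSet, ZTestResult, ztest_vs_controls
from .genelists import GeneList

logger = logging.getLogger(__name__)


def spearman_corr(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Spearman correlation matrix (average ranks for ties)."""
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValueError("need >=2 genes and >=3 samples")
    rho = stats.spearmanr(expr.to_numpy(dtype=float), axis=1).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=expr.index, columns=expr.index)


def mec_from_corr(corr: np.ndarray) -> np.ndarray:
    """Per-gene median of off-diagonal correlations of a square matrix."""
    n = corr.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.array([np.median(corr[i][mask[i]]) for i in range(n)])


@dataclass(frozen=True)
class MECResult:
    list_name: str
    per_gene: pd.Series       # gene -> median Spearman rho with list partners
    median: float             # median of the per-gene MECs
    n_skipped_missing: int
    n_skipped_constant: int


def mec(expr: pd.DataFrame, gene_list: GeneList,
        max_partners: int | None = None, seed: int = 0) -> MECResult:
    """Median Spearman correlation of each list gene against its list partners.

    Genes absent from the matrix or with constant expression (Spearman
    undefined) are skipped and counted.  For very large lists,
    ``max_partners`` caps the number of (seeded, randomly chosen) partner
    genes per gene; the default is the exact all-pairs computation.
    """
    present = [g for g in sorted(gene_list.genes) if g in expr.index]
    n_missing = len(gene_list) - len(present)
    sub = expr.loc[present]
    constant = sub.nunique(axis=1) <= 1
    n_constant = int(constant.sum())
    if n_constant:
        logger.warning("%s: %d genes with constant expression excluded from MEC",
                       gene_list.name, n_constant)
    usable = list(sub.index[~constant])
    if len(usable) < 3:
        raise ValueError(
            f"{gene_list.name}: only {len(usable)} usable genes; MEC needs >=3")
    sub = sub.loc[usable]

    if max_partners is not None and max_partners < len(usable) - 1:
        rng = np.random.default_rng(seed)
        values = sub.to_numpy(dtype=float)
        ranks = stats.rankdata(values, axis=1)
        mecs = np.empty(len(usable))
        for i in range(len(usable)):
            partners = rng.choice(
                [j for j in range(len(usable)) if j != i], size=max_partners, replace=False)
            rhos = [stats.pearsonr(ranks[i], ranks[j]).statistic for j in partners]
            mecs[i] = np.median(rhos)
        per_gene = pd.Series(mecs, index=usable, name="mec")
    else:
        corr = spearman_corr(sub)
        per_gene = pd.Series(mec_from_corr(corr.to_numpy()), index=usable, name="mec")

    return MECResult(list_name=gene_list.name, per_gene=per_gene,
                     median=float(per_gene.median()),
                     n_skipped_missing=n_missing, n_skipped_constant=n_constant)


def mec_vs_controls(expr: pd.DataFrame, gene_list: GeneList,
                    controls: ControlListSet | Iterable[GeneList]) -> ZTestResult:
    """z-test of a list's median MEC against control lists' median MECs."""
    control_lists = controls.lists if isinstance(controls, ControlListSet) else tuple(controls)
    observed = mec(expr, gene_list).median
    null = [mec(expr, cl).median for cl in control_lists]
    return ztest_vs_controls(observed, null)
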