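"""Cell-line invasiveness: CPM normalisation, EMT scoring and differential expression.

Cell lines are classified into highly and less invasive states from the
expression ratio of the epithelial marker E-cadherin (CDH1) to the sum of
the mesenchymal markers N-cadherin (CDH2), vimentin (VIM), ZEB1 and SNAI1:
a low ratio marks the mesenchymal, invasive state.  Differential expression
between the two classes is then called gene-wise on log2-CPM values with a
Welch test and Benjamini-Hochberg FDR, both pooled across tissues and within
each tissue, and genes are labelled by where their regulation holds.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import welch_de_table
from .errors import ConfigurationError, EmptyMatrixError
from .genelists import GeneList

logger = logging.getLogger(__name__)

HIGH_INVASIVE = "high_invasive"
LOW_INVASIVE = "low_invasive"

DEFAULT_EPITHELIAL_MARKER = "CDH1"
DEFAULT_MESENCHYMAL_MARKERS = ("CDH2", "VIM", "ZEB1", "SNAI1")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalisation (columns are samples)."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise EmptyMatrixError(f"samples with zero total counts: {bad}")
    return counts / libsize * 1e6


def cpm_filter(counts: pd.DataFrame, min_cpm: float = 0.5,
               min_samples: int = 100) -> pd.DataFrame:
    """Discard genes below ``min_cpm`` CPM in fewer than ``min_samples`` samples.

    A gene is retained when its CPM is >= ``min_cpm`` in at least
    ``min_samples`` samples.  ``min_cpm=0, min_samples=0`` is the identity.
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.shape[1]} samples present")
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise EmptyMatrixError("CPM filter removed every gene")
    return counts.loc[keep]


def log2cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(CPM + pseudocount) transform of a count matrix."""
    return np.log2(cpm(counts) + pseudocount)


@dataclass(frozen=True)
class EMTMarkers:
    epithelial: str = DEFAULT_EPITHELIAL_MARKER
    mesenchymal: tuple[str, ...] = DEFAULT_MESENCHYMAL_MARKERS


def emt_score(norm: pd.DataFrame, tissues: pd.Series,
              markers: EMTMarkers | None = None, eps: float = 1e-8) -> pd.DataFrame:
    """Per-sample EMT invasiveness score and class.

    ``norm`` holds linear-scale expression (e.g. CPM), genes x samples.
    score = expr(epithelial) / (sum of mesenchymal markers + eps); samples
    scoring below their tissue's median are classed ``high_invasive`` (the
    mesenchymal state), the rest ``low_invasive``.
    """
    markers = markers or EMTMarkers()
    needed = [markers.epithelial, *markers.mesenchymal]
    missing = [m for m in needed if m not in norm.index]
    if missing:
        raise ConfigurationError(f"EMT marker genes absent from matrix: {missing}")
    tissues = tissues.reindex(norm.columns)
    if tissues.isna().any():
        raise ConfigurationError("every sample needs a tissue label")
    epi = norm.loc[markers.epithelial]
    mes = norm.loc[list(markers.mesenchymal)].sum(axis=0)
    score = epi / (mes + eps)
    out = pd.DataFrame({"tissue": tissues, "score": score})
    out["emt_class"] = LOW_INVASIVE
    for _tissue, idx in out.groupby("tissue").groups.items():
        median = out.loc[idx, "score"].median()
        out.loc[idx[out.loc[idx, "score"] < median], "emt_class"] = HIGH_INVASIVE
    return out


def de_two_group(logexpr: pd.DataFrame, classes: pd.Series,
                 fdr_cut: float = 0.05, scope: str = "pooled") -> pd.DataFrame:
    """Welch differential expression, high- vs low-invasive, on log2 expression.

    ``classes`` maps sample -> ``high_invasive``/``low_invasive``.  logFC > 0
    means higher in the invasive class.  Direction is ``up``/``down`` when
    BH-FDR <= ``fdr_cut``, else ``ns``.
    """
    classes = classes.reindex(logexpr.columns).dropna()
    high = list(classes.index[classes == HIGH_INVASIVE])
    low = list(classes.index[classes == LOW_INVASIVE])
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"scope {scope!r}: need >=2 samples per class (got {len(high)} high, {len(low)} low)")
    table = welch_de_table(logexpr, high, low)
    sig = table["fdr"] <= fdr_cut
    table["direction"] = "ns"
    table.loc[sig & (table["logFC"] > 0), "direction"] = "up"
    table.loc[sig & (table["logFC"] < 0), "direction"] = "down"
    table["scope"] = scope
    return table


def de_per_tissue(logexpr: pd.DataFrame, scores: pd.DataFrame,
                  fdr_cut: float = 0.05) -> dict[str, pd.DataFrame]:
    """Run de_two_group within each tissue; tissues lacking a class are skipped."""
    results: dict[str, pd.DataFrame] = {}
    for tissue, sub in scores.groupby("tissue"):
        classes = sub["emt_class"]
        if (classes == HIGH_INVASIVE).sum() < 2 or (classes == LOW_INVASIVE).sum() < 2:
            logger.warning("tissue %s skipped: fewer than 2 samples in a class", tissue)
            continue
        results[str(tissue)] = de_two_group(
            logexpr.loc[:, sub.index], classes, fdr_cut=fdr_cut, scope=f"tissue:{tissue}")
    return results


REGULATION_LABELS = ("up_across", "down_across", "cancer_type_dependent_up",
                     "cancer_type_dependent_down", "mixed", "ns")


def classify_regulation(pooled: pd.DataFrame,
                        per_tissue: Mapping[str, pd.DataFrame],
                        query: GeneList | Sequence[str] | None = None) -> pd.Series:
    """Label each gene by where its invasiveness regulation holds.

    ``up_across``/``down_across``: significant in the pooled comparison.
    ``cancer_type_dependent_up``/``_down``: pooled ns but consistently
    significant in >=1 tissue and never the opposite way; ``mixed``: tissues
    disagree; ``ns`` otherwise.
    """
    genes = pooled.index
    if query is not None:
        wanted = set(query.genes) if isinstance(query, GeneList) else {g.upper() for g in query}
        genes = genes[genes.isin(wanted)]
    tissue_dirs = pd.DataFrame(
        {t: df["direction"].reindex(genes) for t, df in per_tissue.items()},
        index=genes,
    )
    n_up = (tissue_dirs == "up").sum(axis=1) if len(per_tissue) else pd.Series(0, index=genes)
    n_down = (tissue_dirs == "down").sum(axis=1) if len(per_tissue) else pd.Series(0, index=genes)
    pooled_dir = pooled["direction"].reindex(genes)

    labels = pd.Series("ns", index=genes, name="regulation")
    labels[pooled_dir == "up"] = "up_across"
    labels[pooled_dir == "down"] = "down_across"
    ns = pooled_dir == "ns"
    labels[ns & (n_up > 0) & (n_down > 0)] = "mixed"
    labels[ns & (n_up > 0) & (n_down == 0)] = "cancer_type_dependent_up"
    labels[ns & (n_down > 0) & (n_up == 0)] = "cancer_type_dependent_down"
    return labels
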