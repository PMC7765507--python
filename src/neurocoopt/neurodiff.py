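"""Neurodifferentiation-stage analysis of iPSC-to-neuron time courses.

Samples are assigned to the iPSC, neural-progenitor (NPC) or mature-neuron
stage — from supplier labels when available, otherwise by the strongest
mean z-scored marker-panel expression (pluripotency markers for iPSCs,
PAX6/SOX1/NES for NPCs and ENO2/GAP43/MAP2/NEFL/GAD1/BSN/SYP for neurons).
Stage-specific genes are called per dataset between consecutive stages at
|log2FC| >= 2 and BH-FDR <= 0.05, combined across datasets by a
union-minus-conflict rule, and split into NPC-specific, neuron-specific and
sustained ("both") sets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import welch_de_table
from .errors import ConfigurationError
from .genelists import GeneList
from .invasiveness import cpm_filter, log2cpm

logger = logging.getLogger(__name__)

STAGES = ("iPSC", "NPC", "neuron")
UNCLASSIFIED = "unclassified"

DEFAULT_MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "iPSC": ("POU5F1", "NANOG", "LIN28A"),
    "NPC": ("PAX6", "SOX1", "NES"),
    "neuron": ("ENO2", "GAP43", "MAP2", "NEFL", "GAD1", "BSN", "SYP"),
}

DEFAULT_LOGFC_CUT = 2.0
DEFAULT_FDR_CUT = 0.05


def rnaseq_filter(counts: pd.DataFrame, min_cpm: float = 0.5,
                  min_samples: int = 2) -> pd.DataFrame:
    """Low-expression filter for small RNA-seq series: CPM > min_cpm in >= 2 samples."""
    return cpm_filter(counts, min_cpm=min_cpm, min_samples=min_samples)


def stage_classify(expr: pd.DataFrame,
                   panels: Mapping[str, Sequence[str]] | None = None,
                   provided_labels: pd.Series | None = None,
                   tie_tol: float = 1e-9) -> pd.DataFrame:
    """Assign each sample a differentiation stage.

    ``expr`` is a log-scale matrix.  Supplier labels pass through unchanged
    where given; remaining samples get the stage whose marker panel has the
    highest mean z-scored expression.  An exact tie yields ``unclassified``.
    """
    panels = dict(panels or DEFAULT_MARKER_PANELS)
    zscores = {}
    for stage, markers in panels.items():
        present = [m for m in markers if m in expr.index]
        if not present:
            raise ConfigurationError(f"no marker genes of panel {stage!r} in matrix")
        sub = expr.loc[present].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        zscores[stage] = z.mean(axis=0)
    scores = pd.DataFrame(zscores, index=expr.columns)

    ranked = scores.to_numpy()
    order = np.argsort(ranked, axis=1)
    best = ranked[np.arange(len(scores)), order[:, -1]]
    second = ranked[np.arange(len(scores)), order[:, -2]]
    stage = pd.Series(
        [scores.columns[j] for j in order[:, -1]], index=scores.index, name="stage")
    stage[best - second <= tie_tol] = UNCLASSIFIED
    if (stage == UNCLASSIFIED).any():
        logger.warning("%d samples unclassified (tied marker scores)",
                       int((stage == UNCLASSIFIED).sum()))

    if provided_labels is not None:
        provided = provided_labels.reindex(scores.index)
        stage[provided.notna()] = provided[provided.notna()]
    out = scores.add_prefix("score_")
    out.insert(0, "stage", stage)
    return out


def stage_deg(logexpr: pd.DataFrame, labels: pd.Series,
              contrast: tuple[str, str],
              logfc_cut: float = DEFAULT_LOGFC_CUT,
              fdr_cut: float = DEFAULT_FDR_CUT) -> pd.DataFrame | None:
    """Two-group DEG calling for one stage contrast (target vs baseline).

    A gene is a DEG iff |logFC| >= ``logfc_cut`` and BH-FDR <= ``fdr_cut``
    (both thresholds are hard).  Returns None, with a warning, when either
    stage has fewer than two samples.
    """
    target, baseline = contrast
    labels = labels.reindex(logexpr.columns)
    tgt = list(labels.index[labels == target])
    base = list(labels.index[labels == baseline])
    if len(tgt) < 2 or len(base) < 2:
        logger.warning("contrast %s vs %s skipped: %d vs %d samples",
                       target, baseline, len(tgt), len(base))
        return None
    table = welch_de_table(logexpr, tgt, base)
    deg = (table["logFC"].abs() >= logfc_cut) & (table["fdr"] <= fdr_cut)
    table["direction"] = "ns"
    table.loc[deg & (table["logFC"] > 0), "direction"] = "up"
    table.loc[deg & (table["logFC"] < 0), "direction"] = "down"
    return table


@dataclass
class DatasetResult:
    """Per-dataset stage contrasts used by the cross-dataset consensus."""

    name: str
    npc_vs_ipsc: pd.DataFrame | None = None
    neuron_vs_npc: pd.DataFrame | None = None
    # mean log2 expression difference, neurons minus iPSCs (sustained-elevation check)
    neuron_minus_ipsc: pd.Series | None = None


def analyze_dataset(data: pd.DataFrame, sample_sheet: pd.DataFrame, name: str,
                    is_counts: bool = True,
                    panels: Mapping[str, Sequence[str]] | None = None,
                    logfc_cut: float = DEFAULT_LOGFC_CUT,
                    fdr_cut: float = DEFAULT_FDR_CUT,
                    min_cpm: float = 0.5, min_samples: int = 2) -> DatasetResult:
    """Filter, transform and run both stage contrasts for one dataset.

    ``sample_sheet`` has columns ``sample`` and optionally ``supplier_stage``;
    counts are CPM-filtered and log2-CPM transformed, array data are taken as
    log-intensity as-is.
    """
    sheet = sample_sheet.set_index("sample") if "sample" in sample_sheet.columns else sample_sheet
    if is_counts:
        logexpr = log2cpm(rnaseq_filter(data, min_cpm=min_cpm, min_samples=min_samples))
    else:
        logexpr = data
    provided = sheet["supplier_stage"] if "supplier_stage" in sheet.columns else None
    stages = stage_classify(logexpr, panels=panels, provided_labels=provided)["stage"]

    result = DatasetResult(name=name)
    result.npc_vs_ipsc = stage_deg(logexpr, stages, ("NPC", "iPSC"),
                                   logfc_cut=logfc_cut, fdr_cut=fdr_cut)
    result.neuron_vs_npc = stage_deg(logexpr, stages, ("neuron", "NPC"),
                                     logfc_cut=logfc_cut, fdr_cut=fdr_cut)
    neurons = list(stages.index[stages == "neuron"])
    ipscs = list(stages.index[stages == "iPSC"])
    if neurons and ipscs:
        result.neuron_minus_ipsc = (
            logexpr[neurons].mean(axis=1) - logexpr[ipscs].mean(axis=1))
    return result


def _consensus_direction(tables: list[pd.DataFrame]) -> tuple[set[str], set[str]]:
    """Union-minus-conflict: up if up in >=1 dataset and down in none (and vice versa)."""
    up_any: set[str] = set()
    down_any: set[str] = set()
    for table in tables:
        up_any |= set(table.index[table["direction"] == "up"])
        down_any |= set(table.index[table["direction"] == "down"])
    return up_any - down_any, down_any - up_any


@dataclass(frozen=True)
class ConsensusSets:
    npc_specific: GeneList
    neuron_specific: GeneList
    both: GeneList

    def all_up(self) -> GeneList:
        return self.npc_specific.union(self.neuron_specific).union(self.both, name="consensus_up")


def consensus_sets(results: Iterable[DatasetResult],
                   sustained_margin: float = 2.0) -> ConsensusSets:
    """Combine per-dataset stage DEGs into NPC-specific, neuron-specific and
    sustained ("both") gene sets.

    Per contrast, a gene is consensus-up when up-regulated in >=1 dataset and
    down-regulated in none.  ``both`` holds genes induced at the NPC stage
    whose elevation persists into neurons: consensus-up in NPC-vs-iPSC and
    either consensus-up again in neuron-vs-NPC, or not down there while the
    mean neuron-vs-iPSC log2 difference reaches ``sustained_margin`` in some
    dataset.  The NPC/neuron-specific sets are the remaining consensus-up
    genes of their contrast, so the three sets are pairwise disjoint.
    """
    results = list(results)
    npc_tables = [r.npc_vs_ipsc for r in results if r.npc_vs_ipsc is not None]
    neuron_tables = [r.neuron_vs_npc for r in results if r.neuron_vs_npc is not None]
    up_p, _ = _consensus_direction(npc_tables)
    up_n, down_n = _consensus_direction(neuron_tables)

    sustained: set[str] = set()
    for r in results:
        if r.neuron_minus_ipsc is not None:
            diff = r.neuron_minus_ipsc
            sustained |= set(diff.index[diff >= sustained_margin])

    both = (up_p & up_n) | (up_p - down_n) & sustained
    return ConsensusSets(
        npc_specific=GeneList("npc_specific", up_p - both),
        neuron_specific=GeneList("neuron_specific", up_n - both),
        both=GeneList("both", both),
    )


def overlap_report(sets: Mapping[str, GeneList] | Iterable[GeneList],
                   against: Mapping[str, GeneList] | Iterable[GeneList]) -> pd.DataFrame:
    """Pairwise overlap counts and percentages of gene sets against references.

    percentage = 100 * |set & reference| / |set|; undefined (NaN) for empty sets.
    """
    def as_list(obj):
        return list(obj.values()) if isinstance(obj, Mapping) else list(obj)

    rows = []
    for s in as_list(sets):
        for ref in as_list(against):
            overlap = len(s.genes & ref.genes)
            pct = 100.0 * overlap / len(s) if len(s) else np.nan
            rows.append({"set": s.name, "reference": ref.name, "set_size": len(s),
                         "reference_size": len(ref), "overlap": overlap, "pct": pct})
    return pd.DataFrame(rows)
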