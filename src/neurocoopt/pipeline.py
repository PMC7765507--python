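"""End-to-end orchestration on synthetic inputs.

Runs simulate -> gene lists -> driver enrichment -> invasiveness ->
survival -> co-expression -> neurodifferentiation in dependency order,
writes every stage's table under an output directory and aggregates the
headline statistics into a machine-readable JSON report.  The whole run is
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, enrichment, genelists, invasiveness, neurodiff, survival
from .errors import ConfigurationError
from .synthetic_data import (SimConfig, gene_universe, sim_annotations,
                             sim_cellline_counts, sim_coexpression,
                             sim_mutations, sim_stage_counts, sim_survival)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the pipeline, with the analysis' standard defaults."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_cpm: float = 0.5
    min_samples: int = 100
    alpha: float = 0.05
    logfc_cut: float = 2.0
    fdr_cut: float = 0.05
    horizon_days: float = 3650.0
    n_controls: int = 100

    @property
    def seed(self) -> int:
        return self.sim.seed

    def validate(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.fdr_cut < 1):
            raise ConfigurationError("alpha and fdr_cut must lie in (0, 1)")
        if self.min_cpm < 0 or self.min_samples < 0 or self.n_controls < 2:
            raise ConfigurationError("thresholds out of range")
        if self.horizon_days <= 0 or self.logfc_cut < 0:
            raise ConfigurationError("horizon_days must be positive, logfc_cut >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage on synthetic data and write outputs plus a report.

    Returns the report dict; the same content is written to
    ``outdir/report.json`` with sorted keys so reruns under the same seed are
    byte-identical.
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # --- gene lists from simulated annotations (round-tripped through files)
    ann = sim_annotations(config.sim)
    ann_path = outdir / "inputs" / "annotations.tsv"
    ann.table.to_csv(ann_path, sep="\t", index=False)
    orth_path = outdir / "inputs" / "orthologs.tsv"
    ann.orthologs.to_csv(orth_path, sep="\t", index=False)

    annot = genelists.parse_annotations(ann_path)
    orthologs = genelists.load_ortholog_map(orth_path)
    from .synthetic_data import BEHAVIORAL_KEYWORDS, NEU_DEV_KEYWORDS
    neu_dev = genelists.build_gene_list(annot, NEU_DEV_KEYWORDS, orthologs, "neu_dev")
    behavioral = genelists.build_gene_list(annot, BEHAVIORAL_KEYWORDS, orthologs,
                                           "behavioral")
    genelists.write_gmt([neu_dev, behavioral], outdir / "gene_lists.gmt")
    venn = genelists.venn_partition(neu_dev, behavioral)
    report["gene_lists"] = {
        "n_neu_dev": len(neu_dev), "n_behavioral": len(behavioral),
        "venn": {"neu_dev_only": venn.a_only, "behavioral_only": venn.b_only,
                 "both": venn.both},
        "parse_report": annot.report.to_dict(),
    }
    anatomy_index = genelists.build_anatomy_index(annot, neu_dev, orthologs)

    # --- driver enrichment + mutation burden
    universe = genelists.GeneList("universe", gene_universe(config.sim))
    muts = sim_mutations(config.sim, neu_dev)
    enr = enrichment.enrich(neu_dev, muts.drivers, universe,
                            n_lists=config.n_controls, seed=config.seed)
    burden = enrichment.patient_mutation_burden(muts.counts.to_dict(),
                                                muts.n_patients, neu_dev)
    enrichment.enrichment_report([enr]).to_csv(outdir / "enrichment.tsv",
                                               sep="\t", index=False)
    report["enrichment"] = {
        "observed_pct": enr.observed_pct, "control_mean_pct": enr.control_mean_pct,
        "control_sd_pct": enr.control_sd_pct, "z": enr.z, "p": enr.p,
        "expected_by_chance_pct": enr.expected_by_chance_pct,
        "mutation_burden_median": burden.median,
    }

    # --- invasiveness: plant part of the invasive up/down signal inside neu.dev
    rng = np.random.default_rng([config.seed, 99])
    neu_sorted = sorted(neu_dev.genes)
    n_up_neu = min(len(neu_sorted) // 3, config.sim.n_up_genes)
    n_down_neu = min(len(neu_sorted) // 6, config.sim.n_down_genes)
    planted_neu = list(rng.choice(neu_sorted, size=n_up_neu + n_down_neu, replace=False))
    other_pool = sorted(set(gene_universe(config.sim)) - neu_dev.genes
                        - set(ann.behavioral_truth.genes))
    other_pool = [g for g in other_pool if g.startswith("G")]
    n_up_other = config.sim.n_up_genes - n_up_neu
    n_down_other = config.sim.n_down_genes - n_down_neu
    planted_other = list(rng.choice(other_pool, size=n_up_other + n_down_other,
                                    replace=False))
    up_genes = planted_neu[:n_up_neu] + planted_other[:n_up_other]
    down_genes = planted_neu[n_up_neu:] + planted_other[n_up_other:]
    lines = sim_cellline_counts(config.sim, up_genes=up_genes, down_genes=down_genes)
    filtered = invasiveness.cpm_filter(lines.counts, min_cpm=config.min_cpm,
                                       min_samples=config.min_samples)
    cpm_mat = invasiveness.cpm(filtered)
    logexpr = invasiveness.log2cpm(filtered)
    scores = invasiveness.emt_score(cpm_mat, lines.meta["tissue"])
    scores.to_csv(outdir / "emt_scores.tsv", sep="\t")
    pooled = invasiveness.de_two_group(logexpr, scores["emt_class"],
                                       fdr_cut=config.fdr_cut)
    per_tissue = invasiveness.de_per_tissue(logexpr, scores, fdr_cut=config.fdr_cut)
    pd.concat([pooled, *per_tissue.values()]).to_csv(outdir / "de_results.tsv", sep="\t")
    neu_present = [g for g in neu_dev if g in pooled.index]
    regulation = invasiveness.classify_regulation(pooled, per_tissue, neu_present)
    regulation.to_csv(outdir / "regulation_labels.tsv", sep="\t")
    label_counts = regulation.value_counts().to_dict()
    report["invasiveness"] = {
        "n_genes_after_filter": int(filtered.shape[0]),
        "emt_class_counts": scores["emt_class"].value_counts().to_dict(),
        "regulation_label_counts": {k: int(v) for k, v in sorted(label_counts.items())},
    }

    # --- survival: plant the first anatomy's genes as poor-prognostic
    first_anatomy = sorted(anatomy_index)[0] if anatomy_index else None
    prognostic = (sorted(anatomy_index[first_anatomy].genes)
                  if first_anatomy else None)
    surv_sim = sim_survival(config.sim, prognostic_genes=prognostic)
    cox = survival.cox_screen(surv_sim.expression, surv_sim.surv,
                              alpha=config.alpha, horizon_days=config.horizon_days)
    cox.to_csv(outdir / "cox_results.tsv", sep="\t", index=False)
    summary = survival.cross_cancer_summary(cox)
    summary.per_gene.to_csv(outdir / "cross_cancer_summary.tsv", sep="\t")
    anatomy = survival.anatomy_enrichment(anatomy_index, cox) if anatomy_index else None
    if anatomy is not None:
        anatomy.to_csv(outdir / "anatomy_enrichment.tsv", sep="\t")
    report["survival"] = {
        "n_cancers": summary.n_cancers,
        "recurrence_threshold": summary.threshold,
        "n_recurrent_poor": len(summary.recurrent_poor),
        "class_counts": cox["class"].value_counts().to_dict(),
        "anatomy_max_ratio": (float(np.nanmax(anatomy.to_numpy()))
                              if anatomy is not None else None),
    }

    # --- co-expression (MEC)
    coex = sim_coexpression(config.sim)
    coex_universe = genelists.GeneList("coexpr_universe", coex.expression.index)
    controls = enrichment.draw_control_lists(coex_universe, coex.block_truth,
                                             n_lists=config.n_controls,
                                             seed=config.seed + 1)
    mec_result = coexpression.mec(coex.expression, coex.block_truth)
    mec_result.per_gene.to_csv(outdir / "mec_per_gene.tsv", sep="\t")
    mec_z, mec_p = coexpression.mec_vs_controls(coex.expression, coex.block_truth,
                                                controls)
    report["coexpression"] = {"median_mec": mec_result.median, "z": mec_z, "p": mec_p}

    # --- neurodifferentiation
    stages = sim_stage_counts(config.sim)
    ds_results = [
        neurodiff.analyze_dataset(ds.counts, ds.sample_sheet, ds.name,
                                  logfc_cut=config.logfc_cut, fdr_cut=config.fdr_cut)
        for ds in stages.datasets
    ]
    consensus = neurodiff.consensus_sets(ds_results)
    genelists.write_gmt([consensus.npc_specific, consensus.neuron_specific,
                         consensus.both], outdir / "consensus_sets.gmt")
    tumor_up = genelists.GeneList(
        "tumor_up", pooled.index[pooled["direction"] == "up"])
    overlaps = neurodiff.overlap_report(
        [consensus.npc_specific, consensus.neuron_specific, consensus.both],
        [neu_dev, behavioral, tumor_up])
    overlaps.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
    report["neurodiff"] = {
        "n_npc_specific": len(consensus.npc_specific),
        "n_neuron_specific": len(consensus.neuron_specific),
        "n_both": len(consensus.both),
        "overlaps": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in row.items()}
            for row in overlaps.to_dict(orient="records")
        ],
    }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return report
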