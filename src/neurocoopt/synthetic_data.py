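"""Synthetic inputs with planted ground truth for every pipeline stage.

Emulates the external resources the analysis normally consumes — mouse
genotype-phenotype annotations, cell-line RNA-seq count panels with an
EMT-driven invasive/non-invasive split, tumor expression with exponential
survival whose hazard depends log-linearly on planted prognostic genes, and
three-stage iPSC/NPC/neuron count series — all deterministic given a seed.
Truth objects (planted gene sets, labels, effect sizes) are returned
alongside the data so tests never re-derive them.

The count model is negative-binomial with gene-wise means drawn log-normally
and a common dispersion; library sizes vary log-normally across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genelists import GeneList
from .invasiveness import DEFAULT_EPITHELIAL_MARKER, DEFAULT_MESENCHYMAL_MARKERS
from .neurodiff import DEFAULT_MARKER_PANELS

EMT_MARKERS = (DEFAULT_EPITHELIAL_MARKER, *DEFAULT_MESENCHYMAL_MARKERS)
STAGE_MARKERS = tuple(g for panel in DEFAULT_MARKER_PANELS.values() for g in panel)

# sub-seeds so each generator has an independent, reproducible stream
_STREAM = {"annotations": 1, "mutations": 2, "celllines": 3, "survival": 4,
           "stages": 5, "coexpression": 6}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic inputs.

    Sizes are desk-scale stand-ins for the cohorts the analysis was designed
    around (thousands of cell lines / tens of thousands of genes), chosen so
    every stage has comfortable power at its documented effect sizes.
    """

    seed: int = 0
    n_genes: int = 2000                  # coding-gene universe

    # annotations (gene-phenotype-anatomy links)
    n_neu_dev: int = 60                  # planted nervous-system-development genes
    n_behavioral: int = 50               # planted neurological/behavioural genes
    n_shared_phenotype: int = 20         # genes carrying both phenotype classes
    n_other_annotated: int = 80          # genes with non-neuronal phenotypes only
    n_anatomies: int = 4
    genes_per_anatomy: int = 10

    # driver / mutation emulation
    n_drivers: int = 120
    driver_frac_in_neu_dev: float = 0.25
    n_patients: int = 500
    mutation_rate_background: float = 0.02
    mutation_rate_neuronal: float = 0.10

    # cell-line panel
    n_tissues: int = 4
    lines_per_tissue: int = 30           # half invasive, half not, per tissue
    marker_log2_separation: float = 6.0  # CDH1 vs mesenchymal-marker mean gap
    n_up_genes: int = 40                 # planted up in invasive lines
    n_down_genes: int = 20
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1           # 1/size of the negative binomial
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.0
    libsize_log_sd: float = 0.15

    # survival
    n_cancer_types: int = 4
    patients_per_cancer: int = 150
    n_prognostic: int = 10
    prognostic_beta: float = 0.7
    prognostic_correlation: float = 0.9  # corr of each planted gene with the hazard factor
    baseline_mean_days: float = 1500.0
    censoring_horizon_days: float = 6000.0  # uniform censoring bound; past the
                                            # ten-year cutoff so truncation bites

    # neurodifferentiation stages
    n_stage_datasets: int = 2
    samples_per_stage: int = 4
    # replicate-level biological dispersion of clonal differentiation cultures
    # (BCV ~ 0.17, i.e. ~0.3 SD on the log2 scale at moderate expression);
    # far below the across-line heterogeneity of the cell-line panel
    stage_nb_dispersion: float = 0.03
    n_npc_genes: int = 50
    n_neuron_genes: int = 50
    n_sustained_genes: int = 10
    stage_log2fc: int = 4                # 16-fold planted stage effects
    marker_stage_log2fc: float = 5.0

    # co-expression block
    block_size: int = 25
    block_loading: float = 0.8
    coexpr_samples: int = 60


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[stream]])


def gene_universe(cfg: SimConfig) -> list[str]:
    """Symbol universe: named marker genes plus generic G#### symbols."""
    special = list(dict.fromkeys([*EMT_MARKERS, *STAGE_MARKERS]))
    n_generic = cfg.n_genes - len(special)
    if n_generic < 0:
        raise ValueError("n_genes smaller than the named marker genes")
    return special + [f"G{i:04d}" for i in range(n_generic)]


def _generic_genes(cfg: SimConfig) -> list[str]:
    special = set(EMT_MARKERS) | set(STAGE_MARKERS)
    return [g for g in gene_universe(cfg) if g not in special]


# ---------------------------------------------------------------------------
# Annotations

NEURONAL_MP = [("MP:0003861", "abnormal nervous system development"),
               ("MP:0002882", "abnormal neuron morphology")]
BEHAVIORAL_MP = [("MP:0004924", "abnormal behavior"),
                 ("MP:0002064", "seizures")]
OTHER_MP = [("MP:0001560", "abnormal circulating insulin level"),
            ("MP:0000266", "abnormal heart morphology")]

NEU_DEV_KEYWORDS = ("nervous system", "neuron")
BEHAVIORAL_KEYWORDS = ("behavior", "seizure", "ataxia", "learning")


@dataclass(frozen=True)
class SimAnnotations:
    table: pd.DataFrame            # tab-delimited annotation rows (mouse symbols)
    orthologs: pd.DataFrame        # mouse_symbol, human_symbol
    neu_dev_truth: GeneList        # human symbols
    behavioral_truth: GeneList
    anatomy_truth: dict[str, GeneList]


def _mouse_symbol(human: str) -> str:
    return human.capitalize()


def sim_annotations(cfg: SimConfig) -> SimAnnotations:
    """Genotype-phenotype annotation table with planted neu.dev/behavioral sets.

    Planted neu.dev genes carry neuronal MP terms (and EMAPA anatomy links in
    round-robin blocks); behavioral genes carry behavioural MP terms; a shared
    block carries both; decoy genes carry unrelated phenotypes.
    """
    rng = _rng(cfg, "annotations")
    pool = _generic_genes(cfg)
    n_needed = (cfg.n_neu_dev + cfg.n_behavioral - cfg.n_shared_phenotype
                + cfg.n_other_annotated)
    chosen = list(rng.choice(pool, size=n_needed, replace=False))
    neu_dev = chosen[:cfg.n_neu_dev]
    shared = neu_dev[:cfg.n_shared_phenotype]
    behavioral = shared + chosen[cfg.n_neu_dev:
                                 cfg.n_neu_dev + cfg.n_behavioral - cfg.n_shared_phenotype]
    other = chosen[cfg.n_neu_dev + cfg.n_behavioral - cfg.n_shared_phenotype:]

    anatomies = [f"EMAPA:{17000 + i}" for i in range(cfg.n_anatomies)]
    anatomy_truth: dict[str, set[str]] = {a: set() for a in anatomies}

    rows = []
    for i, human in enumerate(neu_dev):
        mp_id, desc = NEURONAL_MP[i % len(NEURONAL_MP)]
        emapa = ""
        block = i // cfg.genes_per_anatomy
        if block < cfg.n_anatomies:
            emapa = anatomies[block]
            anatomy_truth[emapa].add(human)
        rows.append((_mouse_symbol(human), mp_id, desc, emapa))
    for i, human in enumerate(behavioral):
        mp_id, desc = BEHAVIORAL_MP[i % len(BEHAVIORAL_MP)]
        rows.append((_mouse_symbol(human), mp_id, desc, ""))
    for i, human in enumerate(other):
        mp_id, desc = OTHER_MP[i % len(OTHER_MP)]
        rows.append((_mouse_symbol(human), mp_id, desc, ""))

    table = pd.DataFrame(rows, columns=["gene_symbol", "mp_id", "mp_description",
                                        "emapa_ids"])
    annotated = sorted({r[0] for r in rows})
    orthologs = pd.DataFrame({"mouse_symbol": annotated,
                              "human_symbol": [m.upper() for m in annotated]})
    return SimAnnotations(
        table=table,
        orthologs=orthologs,
        neu_dev_truth=GeneList("neu_dev", neu_dev),
        behavioral_truth=GeneList("behavioral", behavioral),
        anatomy_truth={a: GeneList(a, g) for a, g in anatomy_truth.items()},
    )


@dataclass(frozen=True)
class SimMutations:
    counts: pd.Series              # gene -> patients mutated
    n_patients: int
    drivers: GeneList              # planted driver catalogue


def sim_mutations(cfg: SimConfig, neu_dev: GeneList) -> SimMutations:
    """Per-gene mutated-patient counts; neu.dev genes mutate at an elevated
    rate, and a planted driver catalogue is enriched for neu.dev genes."""
    rng = _rng(cfg, "mutations")
    universe = gene_universe(cfg)
    rates = pd.Series(cfg.mutation_rate_background, index=universe)
    rates[rates.index.isin(neu_dev.genes)] = cfg.mutation_rate_neuronal
    counts = pd.Series(rng.binomial(cfg.n_patients, rates.to_numpy()),
                       index=universe, name="n_patients_mutated")

    n_from_neu = int(round(cfg.n_drivers * cfg.driver_frac_in_neu_dev))
    neu_pool = sorted(neu_dev.genes)
    other_pool = sorted(set(universe) - neu_dev.genes)
    drivers = list(rng.choice(neu_pool, size=min(n_from_neu, len(neu_pool)), replace=False))
    drivers += list(rng.choice(other_pool, size=cfg.n_drivers - len(drivers), replace=False))
    return SimMutations(counts=counts, n_patients=cfg.n_patients,
                        drivers=GeneList("drivers", drivers))


# ---------------------------------------------------------------------------
# Cell-line counts

@dataclass(frozen=True)
class SimCellLines:
    counts: pd.DataFrame           # genes x samples, non-negative ints
    meta: pd.DataFrame             # sample, tissue
    invasive_truth: pd.Series      # sample -> bool (planted invasive state)
    up_truth: GeneList             # planted up in invasive lines
    down_truth: GeneList


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def sim_cellline_counts(cfg: SimConfig,
                        up_genes: list[str] | None = None,
                        down_genes: list[str] | None = None) -> SimCellLines:
    """Negative-binomial cell-line counts with a planted invasive split.

    Exactly half the lines of each tissue are invasive: their E-cadherin mean
    is lowered and the mesenchymal-marker means raised by
    ``marker_log2_separation`` log2 units, and planted DE genes are shifted
    by ``de_log2fc`` (up) or -``de_log2fc`` (down).
    """
    rng = _rng(cfg, "celllines")
    genes = gene_universe(cfg)
    pool = [g for g in _generic_genes(cfg)]
    if up_genes is None:
        chosen = list(rng.choice(pool, size=cfg.n_up_genes + cfg.n_down_genes, replace=False))
        up_genes = chosen[:cfg.n_up_genes]
        down_genes = chosen[cfg.n_up_genes:]
    down_genes = down_genes or []

    n_samples = cfg.n_tissues * cfg.lines_per_tissue
    samples = [f"CL{i:04d}" for i in range(n_samples)]
    tissues = np.repeat([f"tissue_{t}" for t in range(cfg.n_tissues)],
                        cfg.lines_per_tissue)
    invasive = np.tile(
        np.r_[np.ones(cfg.lines_per_tissue // 2, dtype=bool),
              np.zeros(cfg.lines_per_tissue - cfg.lines_per_tissue // 2, dtype=bool)],
        cfg.n_tissues)

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=len(genes))
    log2mu = np.tile(base[:, None], (1, n_samples))

    gi = {g: i for i, g in enumerate(genes)}
    half = cfg.marker_log2_separation / 2.0
    epi = gi[DEFAULT_EPITHELIAL_MARKER]
    log2mu[epi, :] = cfg.base_log2_mean + np.where(invasive, -half, half)
    for m in DEFAULT_MESENCHYMAL_MARKERS:
        log2mu[gi[m], :] = cfg.base_log2_mean + np.where(invasive, half, -half)
    for g in up_genes:
        log2mu[gi[g], invasive] += cfg.de_log2fc
    for g in down_genes:
        log2mu[gi[g], invasive] -= cfg.de_log2fc

    libfactor = np.exp(rng.normal(0.0, cfg.libsize_log_sd, size=n_samples))
    mu = (2.0 ** log2mu) * libfactor[None, :]
    counts = pd.DataFrame(_nb_counts(rng, mu, cfg.nb_dispersion),
                          index=genes, columns=samples)
    meta = pd.DataFrame({"sample": samples, "tissue": tissues}).set_index("sample")
    return SimCellLines(
        counts=counts, meta=meta,
        invasive_truth=pd.Series(invasive, index=samples, name="invasive"),
        up_truth=GeneList("planted_up", up_genes),
        down_truth=GeneList("planted_down", down_genes) if down_genes
        else GeneList("planted_down", []),
    )


# ---------------------------------------------------------------------------
# Survival

@dataclass(frozen=True)
class SimSurvival:
    expression: pd.DataFrame       # genes x patients, FPKM-like linear scale
    surv: pd.DataFrame             # patient_id, time_days, event, cancer_type
    prognostic_truth: GeneList
    true_beta: float


def sim_survival(cfg: SimConfig,
                 prognostic_genes: list[str] | None = None,
                 n_null_genes: int = 90) -> SimSurvival:
    """Survival tables with exponential event times and planted prognostic genes.

    Per cancer type, a latent hazard factor f ~ N(0,1) drives event times
    T ~ Exp(mean = baseline * exp(-beta f)); each planted gene's log2
    expression correlates with f at ``prognostic_correlation`` (1.0 makes the
    gene the hazard covariate itself).  Censoring times are uniform on
    (0, censoring_horizon_days]; times can exceed the ten-year horizon so
    administrative truncation is exercised.  Expression is emitted as
    2^(5 + x) - 1 so that log2(expr + 1) recovers the simulated covariate.
    """
    rng = _rng(cfg, "survival")
    pool = _generic_genes(cfg)
    if prognostic_genes is None:
        prognostic_genes = list(rng.choice(pool, size=cfg.n_prognostic, replace=False))
    null_pool = [g for g in pool if g not in set(prognostic_genes)]
    null_genes = list(rng.choice(null_pool, size=n_null_genes, replace=False))
    genes = list(prognostic_genes) + null_genes

    rho = cfg.prognostic_correlation
    frames, surv_rows = [], []
    for c in range(cfg.n_cancer_types):
        cancer = f"cancer_{c}"
        n = cfg.patients_per_cancer
        patients = [f"{cancer}_P{i:03d}" for i in range(n)]
        f = rng.normal(size=n)
        x = np.empty((len(genes), n))
        for i, g in enumerate(genes):
            if g in set(prognostic_genes):
                x[i] = rho * f + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=n)
            else:
                x[i] = rng.normal(size=n)
        event_time = rng.exponential(cfg.baseline_mean_days
                                     * np.exp(-cfg.prognostic_beta * f))
        censor_time = rng.uniform(1.0, cfg.censoring_horizon_days, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        frames.append(pd.DataFrame(2.0 ** (5.0 + x) - 1.0, index=genes, columns=patients))
        surv_rows.append(pd.DataFrame({"patient_id": patients,
                                       "time_days": time,
                                       "event": event,
                                       "cancer_type": cancer}))
    return SimSurvival(
        expression=pd.concat(frames, axis=1),
        surv=pd.concat(surv_rows, ignore_index=True),
        prognostic_truth=GeneList("planted_poor", prognostic_genes),
        true_beta=cfg.prognostic_beta,
    )


# ---------------------------------------------------------------------------
# Neurodifferentiation stages

@dataclass(frozen=True)
class SimStageDataset:
    name: str
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame     # sample, supplier_stage (may be all-NaN)


@dataclass(frozen=True)
class SimStages:
    datasets: list[SimStageDataset]
    npc_truth: GeneList
    neuron_truth: GeneList
    sustained_truth: GeneList


def sim_stage_counts(cfg: SimConfig) -> SimStages:
    """Three-stage (iPSC/NPC/neuron) count series with planted stage genes.

    Planted NPC genes rise ``stage_log2fc`` log2 units at the NPC stage and
    fall back in neurons; neuron genes rise only in neurons; sustained genes
    rise at the NPC stage and stay up.  Stage marker panels are elevated in
    their own stage and therefore belong to the stage-specific truth sets
    (the NPC panel to ``npc_truth``, the neuron panel to ``neuron_truth``).
    The first dataset carries supplier labels; the rest are left for
    marker-based classification.
    """
    rng = _rng(cfg, "stages")
    genes = gene_universe(cfg)
    pool = _generic_genes(cfg)
    n_planted = cfg.n_npc_genes + cfg.n_neuron_genes + cfg.n_sustained_genes
    chosen = list(rng.choice(pool, size=n_planted, replace=False))
    npc_genes = chosen[:cfg.n_npc_genes]
    neuron_genes = chosen[cfg.n_npc_genes:cfg.n_npc_genes + cfg.n_neuron_genes]
    sustained = chosen[cfg.n_npc_genes + cfg.n_neuron_genes:]

    gi = {g: i for i, g in enumerate(genes)}
    datasets = []
    for d in range(cfg.n_stage_datasets):
        n_per = cfg.samples_per_stage
        stages = np.repeat(["iPSC", "NPC", "neuron"], n_per)
        samples = [f"DS{d}_{s}_{i}" for s, i in zip(stages, np.tile(range(n_per), 3))]
        base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=len(genes))
        log2mu = np.tile(base[:, None], (1, len(samples)))

        is_npc = stages == "NPC"
        is_neuron = stages == "neuron"
        for g in npc_genes:
            log2mu[gi[g], is_npc] += cfg.stage_log2fc
        for g in neuron_genes:
            log2mu[gi[g], is_neuron] += cfg.stage_log2fc
        for g in sustained:
            log2mu[gi[g], is_npc | is_neuron] += cfg.stage_log2fc
        for stage, panel in DEFAULT_MARKER_PANELS.items():
            mask = stages == stage
            for m in panel:
                log2mu[gi[m], mask] += cfg.marker_stage_log2fc

        libfactor = np.exp(rng.normal(0.0, cfg.libsize_log_sd, size=len(samples)))
        mu = (2.0 ** log2mu) * libfactor[None, :]
        counts = pd.DataFrame(_nb_counts(rng, mu, cfg.stage_nb_dispersion),
                              index=genes, columns=samples)
        sheet = pd.DataFrame({"sample": samples,
                              "supplier_stage": stages if d == 0 else [None] * len(samples)})
        datasets.append(SimStageDataset(name=f"dataset_{d}", counts=counts,
                                        sample_sheet=sheet))
    return SimStages(
        datasets=datasets,
        npc_truth=GeneList("planted_npc",
                           [*npc_genes, *DEFAULT_MARKER_PANELS["NPC"]]),
        neuron_truth=GeneList("planted_neuron",
                              [*neuron_genes, *DEFAULT_MARKER_PANELS["neuron"]]),
        sustained_truth=GeneList("planted_sustained", sustained),
    )


# ---------------------------------------------------------------------------
# Co-expression

@dataclass(frozen=True)
class SimCoexpression:
    expression: pd.DataFrame       # genes x samples, continuous log-scale
    block_truth: GeneList          # planted co-regulated block


def sim_coexpression(cfg: SimConfig, n_genes: int | None = None) -> SimCoexpression:
    """Expression with a planted co-regulated block sharing one latent factor.

    Block genes are loading * factor + sqrt(1 - loading^2) * noise; the rest
    are independent standard normals.
    """
    rng = _rng(cfg, "coexpression")
    n_genes = n_genes or min(cfg.n_genes, 400)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    block = list(rng.choice(genes, size=cfg.block_size, replace=False))
    factor = rng.normal(size=cfg.coexpr_samples)
    lam = cfg.block_loading
    data = rng.normal(size=(n_genes, cfg.coexpr_samples))
    block_idx = [genes.index(g) for g in block]
    data[block_idx] = lam * factor[None, :] + np.sqrt(1 - lam ** 2) * data[block_idx]
    expr = pd.DataFrame(data, index=genes,
                        columns=[f"S{i:03d}" for i in range(cfg.coexpr_samples)])
    return SimCoexpression(expression=expr, block_truth=GeneList("coexpr_block", block))


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with only the seed replaced."""
    return replace(cfg, seed=seed)
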