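# Methods

This note documents the statistical procedures implemented in
`neurocoopt`, the defaults and why they were chosen, the synthetic-data
model, and the numerical and design decisions taken where the analysis
left choices open.

## Gene-list construction

Annotation rows are (mouse gene, MP phenotype id, description, optional
EMAPA anatomy ids). A row is kept iff its MP id matches `MP:<digits>`;
malformed rows are counted in a parse report, never silently dropped.
Term filters match either an exact MP id or a case-insensitive substring
of the phenotype description — the keyword mode exists because published
screens typically list their term sets in supplements that downstream
users may not have. Mouse→human mapping is an input table; many-to-many
entries collapse to the alphabetically first human symbol (logged), and
genes without an entry are dropped and counted. All symbols are
uppercased before set operations, so list algebra is on human HGNC-style
symbols. GMT is the interchange format; round-tripping preserves
membership exactly.

## Enrichment against random control lists

For query list Q, reference catalogue R and gene universe U:

* observed = 100·|Q∩R|/|Q|;
* null: n (default 100) lists of size |Q| drawn uniformly without
  replacement from U∖Q ("unrelated genes" — exclusion makes the null
  conservative);
* z = (observed − mean)/sd with the sample (n−1) standard deviation of
  the control percentages; p is the two-sided standard-normal tail
  (stricter than a one-sided report);
* expected-by-chance = 100·|R∩U|/|U| is reported alongside.

**Exact size of the test.** Two small effects make the true null
rejection rate at α = 0.05 slightly above 5%: (i) the empirical SD of 100
controls makes the statistic t-like rather than normal (≈ 5.2%); and
(ii) excluding the query from the control pool anti-correlates the
control mean with the observed overlap, inflating the numerator variance
by (1 + |Q|/|U∖Q|)². The second effect is negligible when |Q| ≪ |U| but
reaches ≈ 1.25× when the query is ~10% of the universe (measured: ~8–9%
rejection at that proportion). Calibration tests therefore use
|Q|/|U| = 1%, where the measured rate is ≈ 5–6%; with queries that are a
large fraction of the universe, nominal p-values near the threshold
should not be over-read (the screen's headline z-values are far from it).

Mutation burden is a pre-tabulated per-gene count of mutated patients;
query genes absent from the table count as frequency 0, and the list
statistic is the median per-gene frequency.

## EMT invasiveness score and differential expression

Counts are CPM normalised (columns sum to 1e6 before gene filtering).
Filtering keeps genes with CPM ≥ 0.5 in ≥ 100 samples (both thresholds
configurable; synthetic runs at smaller panel sizes lower `min_samples`).
The per-sample score is linear-scale
`CDH1 / (CDH2 + VIM + ZEB1 + SNAI1 + ε)`, ε = 1e-8 guarding empty
denominators; the ratio is scale-invariant per sample, so library size
cancels. The high/low-invasive split is at the per-tissue median — a
documented choice (the dichotomisation rule is not part of the published
description); median-within-tissue guarantees every tissue contributes
both classes.

Differential expression is a gene-wise Welch test on log2(CPM + 0.5),
BH-FDR within scope, significance at FDR ≤ 0.05, with logFC > 0 meaning
higher in the invasive class. This is an explicit reimplementation of
the moderated-model stage of the original pipeline (voom/limma); the
package's acceptance surface is planted-signal recovery, not equality
with empirical-Bayes moderation, and the Welch test is exactly calibrated
under label permutation (KS-uniform p-values, tested). Pooling across
tissues is naive concatenation — no batch correction, matching the
described procedure. Regulation labels: pooled-significant genes are
`up_across`/`down_across`; pooled-ns genes significant in ≥ 1 tissue and
never the opposite way are `cancer_type_dependent_*`; tissue
disagreement is `mixed`.

## Cox prognosis screening

Follow-up is administratively censored at 3650 days (time → horizon,
event → 0). The covariate is log2(expression + 1), standardised within
cancer type; continuous coding avoids an arbitrary cut-point (a
median-split Kaplan–Meier mode is deliberately out of scope of the
headline classes). The fit maximises the Breslow partial likelihood for
a scalar covariate by Newton–Raphson (tolerance 1e-8 on the step, max 50
iterations); ties share a risk set (Breslow approximation — the simplest
correct choice). Degenerate inputs (no events, constant covariate,
singular information, monotone likelihood/perfect separation,
non-convergence) yield flagged `ns` records with a reason code, never an
exception. Wald p comes from β/SE with SE = I(β)^{-1/2}.

The solver is verified three ways: against a brute-force grid search of
an independently coded O(n²) partial likelihood (agreement ≤ 2e-3 on
≤ 30-patient fixtures), against lifelines' `CoxPHFitter` on tie-free
cohorts (≤ 1e-4), and by parameter recovery (planted β = 0.7, n = 300:
mean absolute error ≈ 0.07 over 100 replicates). Type-I error of the
Wald test is ≈ 5% under null simulation.

Classes: poor iff HR > 1 and p ≤ α; favorable iff HR < 1 and p ≤ α;
α = 0.05 on the raw per-cancer p, mirroring per-cancer calls; BH-FDR
across genes within a cancer is computed and reported alongside but does
not drive the headline classes (no multiplicity rule is part of the
published per-cancer classification). Cross-cancer recurrence uses the
ceiling rule ⌈0.25·n_cancers⌉ (9 of 35). The anatomy statistic is, per
(region, cancer), the fraction of the region's development-essential
genes classed poor; regions with no genes report missing.

## Median expression correlation (MEC)

Spearman with average ranks; per gene of a list, the median correlation
with all other list genes; the list statistic is the median of per-gene
MECs, z-tested against control-list medians. Constant-expression genes
(undefined correlation) and genes absent from the matrix are skipped and
counted; fewer than 3 usable genes is an error. All-pairs computation is
the default; a seeded partner-subsampling mode bounds the O(n²) cost for
lists beyond ~2000 genes. Correlations are computed pan-cohort by
default (per-type slicing is a caller-side restriction of the matrix).

## Neurodifferentiation stages

Stage assignment: supplier labels pass through; otherwise the stage
whose marker panel (iPSC: POU5F1/NANOG/LIN28A; NPC: PAX6/SOX1/NES;
neuron: ENO2/GAP43/MAP2/NEFL/GAD1/BSN/SYP) has the highest mean
z-scored expression, with exact ties left unclassified. RNA-seq series
are filtered at CPM > 0.5 in ≥ 2 samples; array data enter as
log-intensity. Stage DEGs require |log2FC| ≥ 2 **and** FDR ≤ 0.05 —
both hard thresholds (a 2-fold gene is never called regardless of p).

Cross-dataset consensus is union-minus-conflict: up in ≥ 1 dataset and
down in none (the five public series pooled by the original analysis are
heterogeneous and no voting rule is published; the union rule is the
permissive documented choice). The sustained ("both") set is defined as:
consensus-up in NPC-vs-iPSC **and** (consensus-up again in neuron-vs-NPC,
**or** not down there while the mean neuron-minus-iPSC log2 difference
reaches 2 in some dataset). Forcing genes up in both contrasts into
`both` makes the three sets pairwise disjoint and their union equal to
all consensus-up genes — an invariant the tests enforce.

## Synthetic-data model

All generators are deterministic given the config seed (independent
sub-streams per generator) and emit truth objects alongside the data.

* **Counts** are negative-binomial with gene-wise log-normal baseline
  means (log2 mean 6, SD 1) and log-normal library-size factors
  (SD 0.15). The cell-line panel uses dispersion 0.1 — across-line
  biological heterogeneity (BCV ≈ 0.32). Stage datasets use dispersion
  0.03 — replicate-level variability of clonal differentiation cultures
  (BCV ≈ 0.17, i.e. ≈ 0.3 SD on the log2 scale at moderate expression),
  which is the noise scale the stage-DEG analysis is specified at.
* **Annotations**: planted neu.dev (60) and behavioral (50) gene sets
  with 20 shared, carrying neuronal/behavioural MP terms among unrelated
  decoys; neu.dev genes fall in round-robin EMAPA blocks of 10 across 4
  anatomies.
* **Cell lines**: 4 tissues × 30 lines, exactly half invasive per tissue
  (so the median split is aligned with the planted truth by design);
  epithelial/mesenchymal marker means separated by 6 log2 units; planted
  up/down genes shifted ±2 log2 units in invasive lines.
* **Survival**: per cancer type a latent hazard factor f ~ N(0,1) drives
  exponential event times with mean 1500·exp(−0.7·f) days; planted gene
  covariates correlate with f at 0.9 (1.0 makes the gene the covariate
  itself — used for clean parameter recovery); censoring is uniform on
  (0, 6000] days so ~30–40% of patients are censored and some follow-up
  exceeds the ten-year horizon, exercising truncation. Expression is
  2^(5+x) − 1 so log2(expr + 1) recovers the simulated covariate.
* **Stages**: 2 datasets × 3 stages × 4 samples; planted NPC-only,
  neuron-only (50 each) and sustained (10) genes at 16-fold; marker
  panels elevated 5 log2 units in their own stage (and therefore part of
  the stage-specific truth sets).
* **Co-expression**: a 25-gene block sharing one latent factor at
  loading 0.8 among independent genes.

**What passing tests do and do not show.** The generators plant clean,
well-separated signals in homogeneous noise: no batch effects, no
GC/length biases, no correlated null genes (outside the planted block),
no informative censoring, one-to-one orthologs, and marker panels that
are perfectly faithful to stage. Recovery rates near 100% on this data
certify the implementation (thresholds applied exactly, estimators
consistent, null calibrated) — they are not estimates of sensitivity or
error rates on real CCLE/TCGA/GEO data, whose marginal distributions the
generators do not attempt to match.

## Problem sizes and defaults

Default synthetic conditions (2000-gene universe, 120 cell lines, 4 × 150
patients, 2 × 12 stage samples, 100 control lists, 500-replicate
calibrations, 100-replicate Cox recovery) were chosen as the smallest
panels at which every planted effect is comfortably powered at its
documented effect size; the full pipeline runs in seconds and the
acceptance script in well under a minute on one CPU. Thresholds default
to the analysis' standard values: CPM 0.5, 100 samples, |logFC| ≥ 2,
FDR ≤ 0.05, α = 0.05, 3650-day horizon, 100 control lists.

## Known limitations

* The Welch-on-log2CPM DE stage does not shrink gene-wise variances; at
  very small n it is conservative relative to empirical-Bayes moderation.
* The Cox screen is univariate by design; no adjustment for age, stage
  or other covariates, and no frailty — estimates attenuate when several
  planted genes share a hazard factor (visible in the default survival
  panel, where per-gene coefficients recover ≈ ρ·β).
* The enrichment z-test's exact size exceeds the nominal α slightly
  (see above); conclusions should rest on large z, as the screen's do.
* Exact MEC is O(n²) in list size; the subsampling mode trades variance
  for memory/time and is seeded for reproducibility.
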