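"""Per-gene univariate Cox proportional-hazards prognosis screening.

Each gene's expression (log2(x+1), standardised within cancer type) is used
as a continuous covariate in a univariate Cox model fitted by
Newton-Raphson on the Breslow partial likelihood.  Genes are classed as
poor (HR > 1) or favorable (HR < 1) prognostic factors per cancer type at a
raw Wald p <= alpha, summarised across cancers, and aggregated per
anatomical region as the fraction of a region's development-essential genes
that are poor prognostic factors.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genelists import GeneList

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_DAYS = 3650.0


def truncate_followup(surv: pd.DataFrame, horizon_days: float = DEFAULT_HORIZON_DAYS,
                      time_col: str = "time_days", event_col: str = "event") -> pd.DataFrame:
    """Administratively censor follow-up beyond ``horizon_days``.

    Patients with time > horizon get time = horizon and event = 0.
    Non-positive times are invalid.
    """
    if (surv[time_col] <= 0).any():
        raise ValidationError("survival times must be positive")
    out = surv.copy()
    late = out[time_col] > horizon_days
    out.loc[late, event_col] = 0
    out.loc[late, time_col] = horizon_days
    return out


@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    z: float
    p: float
    hr: float
    n: int
    n_events: int
    converged: bool
    reason: str | None = None  # set when the fit was not attempted/failed

    @property
    def usable(self) -> bool:
        return self.converged and self.reason is None


def _breslow_quantities(beta: float, x: np.ndarray, event_pos: np.ndarray,
                        first_at_time: np.ndarray):
    """Log partial likelihood, score and information for a scalar covariate.

    Arrays are sorted by ascending time; ``first_at_time[i]`` is the index of
    the first row sharing row i's time, so tied events share one risk set
    (Breslow approximation).
    """
    w = np.exp(beta * x)
    # suffix sums: risk set of a time t is all rows with time >= t
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]
    f = first_at_time[event_pos]
    r0, r1, r2 = s0[f], s1[f], s2[f]
    ll = float(np.sum(beta * x[event_pos] - np.log(r0)))
    score = float(np.sum(x[event_pos] - r1 / r0))
    info = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
    return ll, score, info


def breslow_loglik(beta: float, times, events, covariate) -> float:
    """Breslow log partial likelihood at a given beta (exposed for oracles)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    order = np.argsort(t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    ll, _, _ = _breslow_quantities(beta, x, np.flatnonzero(d == 1), first)
    return ll


def cox_univariate(times, events, covariate, tol: float = 1e-8,
                   max_iter: int = 50) -> CoxFit:
    """Fit a univariate Cox model by Newton-Raphson on the Breslow partial likelihood.

    No events or a constant covariate yield a flagged (ns) record rather
    than an exception, as does non-convergence or a monotone likelihood
    (perfect separation, |beta| running away).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if t.shape != d.shape or t.shape != x.shape:
        raise ValueError("times, events and covariate must have equal length")
    if (t <= 0).any():
        raise ValidationError("survival times must be positive")
    n = len(t)
    n_events = int(d.sum())

    def flagged(reason: str) -> CoxFit:
        return CoxFit(beta=float("nan"), se=float("nan"), z=float("nan"),
                      p=float("nan"), hr=float("nan"), n=n, n_events=n_events,
                      converged=False, reason=reason)

    if n_events == 0:
        return flagged("no_events")
    if np.ptp(x) == 0:
        return flagged("constant_covariate")

    order = np.argsort(t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    event_pos = np.flatnonzero(d == 1)

    beta = 0.0
    info = float("nan")
    converged = False
    for _ in range(max_iter):
        _, score, info = _breslow_quantities(beta, x, event_pos, first)
        if not math.isfinite(score) or not math.isfinite(info) or info <= 0:
            return flagged("singular_information")
        step = score / info
        beta += step
        if abs(beta) > 50:
            return flagged("monotone_likelihood")
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        return flagged("no_convergence")
    _, _, info = _breslow_quantities(beta, x, event_pos, first)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(beta=float(beta), se=float(se), z=float(z), p=float(p),
                  hr=float(math.exp(beta)), n=n, n_events=n_events, converged=True)


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return values - values.mean()
    return (values - values.mean()) / sd


def cox_screen(expr: pd.DataFrame, surv: pd.DataFrame,
               genes: Iterable[str] | GeneList | None = None,
               alpha: float = 0.05,
               horizon_days: float | None = DEFAULT_HORIZON_DAYS,
               log_transform: bool = True) -> pd.DataFrame:
    """Univariate Cox screening of genes across cancer types.

    ``expr`` is genes x patients on a linear scale (e.g. FPKM-UQ); ``surv``
    has columns ``patient_id, time_days, event, cancer_type``.  The covariate
    is log2(expr+1) standardised within cancer type.  Returns one row per
    (gene, cancer_type) with beta/HR/p, a per-cancer BH-FDR column and the
    poor/favorable/ns class at raw p <= alpha.
    """
    from statsmodels.stats.multitest import multipletests

    if genes is None:
        wanted = list(expr.index)
    else:
        pool = genes.genes if isinstance(genes, GeneList) else {str(g).upper() for g in genes}
        wanted = [g for g in expr.index if g in pool]
    surv = surv.set_index("patient_id") if "patient_id" in surv.columns else surv
    if horizon_days is not None:
        surv = truncate_followup(surv, horizon_days)
    common = [p for p in surv.index if p in expr.columns]
    surv = surv.loc[common]

    rows = []
    for cancer, sub in surv.groupby("cancer_type"):
        patients = list(sub.index)
        t = sub["time_days"].to_numpy(dtype=float)
        d = sub["event"].to_numpy(dtype=int)
        block = expr.loc[wanted, patients].to_numpy(dtype=float)
        if log_transform:
            block = np.log2(block + 1.0)
        for gi, gene in enumerate(wanted):
            x = _standardize(block[gi])
            fit = cox_univariate(t, d, x)
            rows.append({"gene": gene, "cancer_type": cancer, "beta": fit.beta,
                         "hr": fit.hr, "se": fit.se, "p": fit.p,
                         "n_events": fit.n_events, "reason": fit.reason or ""})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr"] = np.nan
    for cancer, idx in table.groupby("cancer_type").groups.items():
        pvals = table.loc[idx, "p"]
        ok = pvals.notna()
        if ok.any():
            _, fdr, _, _ = multipletests(pvals[ok], method="fdr_bh")
            table.loc[pvals.index[ok], "fdr"] = fdr
    table["class"] = classify_prognosis(table, alpha=alpha)
    return table


def classify_prognosis(cox_table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """poor if HR > 1 and p <= alpha; favorable if HR < 1 and p <= alpha; else ns."""
    hr = cox_table["hr"]
    p = cox_table["p"]
    cls = pd.Series("ns", index=cox_table.index, name="class")
    sig = p.notna() & (p <= alpha)
    cls[sig & (hr > 1)] = "poor"
    cls[sig & (hr < 1)] = "favorable"
    return cls


def recurrence_threshold(n_cancers: int, fraction: float = 0.25) -> int:
    """Minimum number of cancer types for 'recurrent' status: ceil(fraction * n)."""
    if n_cancers < 1:
        raise ValueError("need at least one cancer type")
    return math.ceil(fraction * n_cancers)


@dataclass(frozen=True)
class CrossCancerSummary:
    per_gene: pd.DataFrame          # gene -> n_poor_cancers, n_favorable_cancers
    recurrent_poor: GeneList        # poor in >= ceil(fraction * n_cancers) cancers
    n_cancers: int
    threshold: int


def cross_cancer_summary(cox_table: pd.DataFrame,
                         fraction: float = 0.25) -> CrossCancerSummary:
    """Count, per gene, the cancer types where it is a poor/favorable factor."""
    n_cancers = cox_table["cancer_type"].nunique()
    if n_cancers < 1:
        raise ValueError("no cancer types in the Cox table")
    per_gene = (
        cox_table.assign(poor=cox_table["class"] == "poor",
                         favorable=cox_table["class"] == "favorable")
        .groupby("gene")[["poor", "favorable"]].sum()
        .rename(columns={"poor": "n_poor_cancers", "favorable": "n_favorable_cancers"})
        .astype(int)
    )
    threshold = recurrence_threshold(n_cancers, fraction)
    qualifying = per_gene.index[per_gene["n_poor_cancers"] >= threshold]
    recurrent = GeneList("recurrent_poor", qualifying)
    return CrossCancerSummary(per_gene=per_gene, recurrent_poor=recurrent,
                              n_cancers=n_cancers, threshold=threshold)


def anatomy_enrichment(index: Mapping[str, GeneList],
                       cox_table: pd.DataFrame) -> pd.DataFrame:
    """Anatomy-region enrichment: per (region, cancer), the fraction of the
    region's genes that are poor prognostic factors in that cancer.

    Regions with zero genes are reported as missing (NaN).
    """
    if not index:
        raise ValueError("anatomy index is empty")
    cancers = sorted(cox_table["cancer_type"].unique())
    poor = cox_table[cox_table["class"] == "poor"]
    poor_by_cancer = {c: set(g["gene"]) for c, g in poor.groupby("cancer_type")}
    data = {}
    for region, genes in index.items():
        denom = len(genes)
        row = {}
        for cancer in cancers:
            if denom == 0:
                row[cancer] = np.nan
            else:
                row[cancer] = len(genes.genes & poor_by_cancer.get(cancer, set())) / denom
        data[region] = row
    return pd.DataFrame(data).T.loc[sorted(index)]
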