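"""Driver-gene enrichment against a random-control-list null.

The observed fraction of a query gene list that falls in a reference set
(e.g. a cancer driver catalogue) is compared with the same fraction measured
on random control lists of equal size drawn from the gene universe, using a
z-test on the empirical null.  Patient mutation burden enters as a
pre-tabulated per-gene count table.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateNullError
from .genelists import GeneList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlListSet:
    """Random gene lists of the query's size, drawn outside the query."""

    lists: tuple[GeneList, ...]
    seed: int

    @property
    def n_lists(self) -> int:
        return len(self.lists)


def draw_control_lists(universe: GeneList, query: GeneList,
                       n_lists: int = 100, seed: int = 0) -> ControlListSet:
    """Sample ``n_lists`` control lists of size ``|query|`` without replacement
    from the universe excluding the query genes ("unrelated genes").

    Deterministic given ``seed``.
    """
    pool = sorted(universe.genes - query.genes)
    k = len(query)
    if len(pool) < k:
        raise ValueError(
            f"universe minus query has {len(pool)} genes; cannot draw lists of {k}")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool, dtype=object)
    lists = tuple(
        GeneList(f"control_{i:03d}", pool_arr[rng.choice(len(pool_arr), size=k, replace=False)])
        for i in range(n_lists)
    )
    return ControlListSet(lists=lists, seed=seed)


def pct_overlap(query: GeneList, reference: GeneList) -> float:
    """Percentage of query genes contained in the reference set."""
    if len(query) == 0:
        raise ValueError("query list is empty")
    return 100.0 * len(query.genes & reference.genes) / len(query)


def expected_by_chance(reference: GeneList, universe: GeneList) -> float:
    """By-chance percentage: reference genes (within the universe) over the universe."""
    if len(universe) == 0:
        raise ValueError("universe is empty")
    return 100.0 * len(reference.genes & universe.genes) / len(universe)


class ZTestResult(NamedTuple):
    z: float
    p: float


def ztest_vs_controls(observed: float, controls: Sequence[float]) -> ZTestResult:
    """z-test of an observed statistic against an empirical control distribution.

    z = (observed - mean(controls)) / sd(controls, ddof=1); p is the
    two-sided standard-normal tail.  Identical controls make the null
    degenerate and raise.
    """
    controls = np.asarray(controls, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least two control values")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise DegenerateNullError("control values are all identical; z undefined")
    z = (observed - controls.mean()) / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(float(z), float(p))


@dataclass(frozen=True)
class EnrichmentResult:
    query: str
    reference: str
    observed_pct: float
    control_mean_pct: float
    control_sd_pct: float
    z: float
    p: float
    expected_by_chance_pct: float
    n_controls: int


def enrich(query: GeneList, reference: GeneList, universe: GeneList,
           n_lists: int = 100, seed: int = 0,
           controls: ControlListSet | None = None) -> EnrichmentResult:
    """Full enrichment comparison of a query list against a reference set.

    Draws (or reuses) control lists, measures the per-list reference overlap
    percentage, and z-tests the query's percentage against that null.
    """
    if controls is None:
        controls = draw_control_lists(universe, query, n_lists=n_lists, seed=seed)
    observed = pct_overlap(query, reference)
    control_pcts = [pct_overlap(cl, reference) for cl in controls.lists]
    z, p = ztest_vs_controls(observed, control_pcts)
    return EnrichmentResult(
        query=query.name,
        reference=reference.name,
        observed_pct=observed,
        control_mean_pct=float(np.mean(control_pcts)),
        control_sd_pct=float(np.std(control_pcts, ddof=1)),
        z=z,
        p=p,
        expected_by_chance_pct=expected_by_chance(reference, universe),
        n_controls=controls.n_lists,
    )


@dataclass(frozen=True)
class MutationBurden:
    frequencies: pd.Series  # per query gene: fraction of patients mutated
    median: float
    n_missing: int


def patient_mutation_burden(mutation_counts: Mapping[str, int], n_patients: int,
                            query: GeneList) -> MutationBurden:
    """Per-gene patient mutation frequencies for a query list, and their median.

    ``mutation_counts`` maps gene symbol -> number of patients carrying a
    mutation in that gene.  Query genes absent from the table get frequency 0
    (counted and logged).
    """
    if n_patients <= 0:
        raise ValueError("cohort size must be positive")
    freqs = {}
    n_missing = 0
    for gene in sorted(query.genes):
        count = int(mutation_counts.get(gene, 0))
        if gene not in mutation_counts:
            n_missing += 1
        if count > n_patients:
            raise ValueError(f"{gene}: mutated-patient count {count} exceeds cohort {n_patients}")
        freqs[gene] = count / n_patients
    if n_missing:
        logger.info("%d query genes absent from mutation table; frequency 0", n_missing)
    series = pd.Series(freqs, name="mutation_frequency")
    return MutationBurden(series, float(series.median()), n_missing)


def enrichment_report(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate EnrichmentResult records for TSV export."""
    return pd.DataFrame([r.__dict__ for r in results])
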