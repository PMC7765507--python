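"""Phenotype-driven gene lists.

Builds nervous-system gene lists from mouse genotype-phenotype annotation
tables (MGI-style tab-delimited exports): genes whose knockout impairs
nervous-system development ("neu.dev") or causes neurological/behavioural
disorders ("behavioral").  Mouse symbols are translated to human symbols
through a supplied ortholog table, and genes are indexed by the EMAPA
anatomical structure their knockout impairs.  Gene sets are exchanged as
GMT files.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

MP_PATTERN = re.compile(r"^MP:\d+$")
EMAPA_PATTERN = re.compile(r"^EMAPA:\d+$")


class GeneList:
    """A named, unordered set of unique uppercase gene symbols.

    Symbols are normalised to uppercase on construction (human HGNC
    convention); duplicates collapse silently, empty symbols are rejected.
    """

    __slots__ = ("name", "genes")

    def __init__(self, name: str, genes: Iterable[str]):
        if not name:
            raise ValueError("GeneList name must be non-empty")
        normalised = set()
        for g in genes:
            g = str(g).strip().upper()
            if not g:
                raise ValueError(f"empty gene symbol in list {name!r}")
            normalised.add(g)
        self.name = name
        self.genes = frozenset(normalised)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return str(symbol).upper() in self.genes

    def __repr__(self) -> str:
        return f"GeneList({self.name!r}, n={len(self)})"

    def intersection(self, other: "GeneList | Iterable[str]", name: str | None = None) -> "GeneList":
        other_genes = other.genes if isinstance(other, GeneList) else {str(g).upper() for g in other}
        return GeneList(name or self.name, self.genes & other_genes)

    def union(self, other: "GeneList | Iterable[str]", name: str | None = None) -> "GeneList":
        other_genes = other.genes if isinstance(other, GeneList) else {str(g).upper() for g in other}
        return GeneList(name or self.name, self.genes | other_genes)

    def difference(self, other: "GeneList | Iterable[str]", name: str | None = None) -> "GeneList":
        other_genes = other.genes if isinstance(other, GeneList) else {str(g).upper() for g in other}
        return GeneList(name or self.name, self.genes - other_genes)

    def sorted(self) -> list[str]:
        return sorted(self.genes)


class VennPartition(NamedTuple):
    a_only: int
    b_only: int
    both: int


def venn_partition(a: GeneList, b: GeneList) -> VennPartition:
    """Two-set Venn counts: genes exclusive to each list and shared by both."""
    both = len(a.genes & b.genes)
    return VennPartition(len(a) - both, len(b) - both, both)


# ---------------------------------------------------------------------------
# GMT I/O

def read_gmt(path: str | Path) -> dict[str, GeneList]:
    """Read a GMT file into an ordered mapping of name -> GeneList.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    """
    lists: dict[str, GeneList] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, *genes = fields
            lists[name] = GeneList(name, [g for g in genes if g.strip()])
    return lists


def write_gmt(lists: Iterable[GeneList], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gl in lists:
            desc = descriptions.get(gl.name, "na")
            fh.write("\t".join([gl.name, desc, *gl.sorted()]) + "\n")


# ---------------------------------------------------------------------------
# Annotation parsing

@dataclass(frozen=True)
class AnnotationSchema:
    """Column names of a tab-delimited genotype-phenotype annotation file."""

    gene: str = "gene_symbol"
    mp_id: str = "mp_id"
    mp_description: str = "mp_description"
    emapa: str | None = "emapa_ids"


@dataclass(frozen=True)
class AnnotationRecord:
    gene_symbol: str
    mp_term_id: str
    mp_description: str
    emapa_ids: tuple[str, ...] = ()


@dataclass
class ParseReport:
    n_rows: int = 0
    n_kept: int = 0
    n_skipped_bad_mp: int = 0
    n_dropped_emapa_ids: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PhenotypeAnnotation:
    """Gene <-> MP phenotype term <-> EMAPA anatomy links."""

    records: list[AnnotationRecord]
    report: ParseReport = field(default_factory=ParseReport)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> set[str]:
        return {r.gene_symbol for r in self.records}


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return []
    return [tok.strip() for tok in re.split(r"[,|;]", str(value)) if tok.strip()]


def parse_annotations(path: str | Path,
                      schema: AnnotationSchema | None = None) -> PhenotypeAnnotation:
    """Parse a tab-delimited genotype-phenotype annotation file.

    One record is produced per row carrying a well-formed MP id
    (``MP:<digits>``); malformed rows are skipped and counted in the parse
    report rather than raising.  EMAPA anatomy ids may be absent or listed
    as a comma/pipe-separated field.
    """
    schema = schema or AnnotationSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in (schema.gene, schema.mp_id):
        if col not in table.columns:
            raise ConfigurationError(f"annotation file lacks required column {col!r}")
    has_desc = schema.mp_description in table.columns
    has_emapa = schema.emapa is not None and schema.emapa in table.columns

    report = ParseReport(n_rows=len(table))
    records: list[AnnotationRecord] = []
    for row in table.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        mp_id = str(row[schema.mp_id]).strip()
        gene = str(row[schema.gene]).strip()
        if not gene or not MP_PATTERN.match(mp_id):
            report.n_skipped_bad_mp += 1
            continue
        emapa: list[str] = []
        if has_emapa:
            for tok in _split_multi(row[schema.emapa]):
                if EMAPA_PATTERN.match(tok):
                    emapa.append(tok)
                else:
                    report.n_dropped_emapa_ids += 1
        desc = str(row[schema.mp_description]).strip() if has_desc else ""
        records.append(AnnotationRecord(gene, mp_id, desc, tuple(emapa)))
        report.n_kept += 1
    return PhenotypeAnnotation(records, report)


# ---------------------------------------------------------------------------
# Ortholog mapping

def load_ortholog_map(path: str | Path,
                      mouse_col: str = "mouse_symbol",
                      human_col: str = "human_symbol") -> dict[str, str]:
    """Load a two-column mouse->human ortholog TSV into a dict.

    Many-to-many mappings are reduced to the alphabetically first human
    symbol, with a logged warning.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).dropna()
    if mouse_col not in table.columns or human_col not in table.columns:
        raise ConfigurationError(
            f"ortholog table must have columns {mouse_col!r} and {human_col!r}")
    mapping: dict[str, str] = {}
    n_collapsed = 0
    for mouse, group in table.groupby(mouse_col):
        humans = sorted(h.strip().upper() for h in group[human_col])
        if len(set(humans)) > 1:
            n_collapsed += 1
        mapping[str(mouse).strip()] = humans[0]
    if n_collapsed:
        logger.warning("%d mouse symbols mapped to multiple human symbols; "
                       "kept the alphabetically first", n_collapsed)
    return mapping


def identity_orthologs(annot: PhenotypeAnnotation) -> dict[str, str]:
    """Ortholog map that sends every annotated symbol to its own uppercase form."""
    return {g: g.upper() for g in annot.genes()}


# ---------------------------------------------------------------------------
# List construction

def build_gene_list(annot: PhenotypeAnnotation,
                    term_filter: Iterable[str],
                    orthologs: Mapping[str, str],
                    name: str) -> GeneList:
    """Select genes annotated to >=1 matching phenotype term, as human symbols.

    A term matches when it equals the record's MP id exactly, or when it is a
    case-insensitive substring of the phenotype description.  Mouse genes with
    no entry in the ortholog map are dropped (counted in a logged warning).
    An empty result yields an empty GeneList with a warning, not an error.
    """
    terms = [str(t).strip() for t in term_filter if str(t).strip()]
    if not terms:
        raise ValueError("term_filter must be non-empty")
    mp_ids = {t for t in terms if MP_PATTERN.match(t)}
    keywords = [t.lower() for t in terms if t not in mp_ids]

    matched_mouse: set[str] = set()
    for rec in annot.records:
        if rec.mp_term_id in mp_ids or any(kw in rec.mp_description.lower() for kw in keywords):
            matched_mouse.add(rec.gene_symbol)

    human: set[str] = set()
    n_no_ortholog = 0
    for mouse in matched_mouse:
        if mouse in orthologs:
            human.add(orthologs[mouse].upper())
        else:
            n_no_ortholog += 1
    if n_no_ortholog:
        logger.warning("%s: %d matching genes had no ortholog entry and were dropped",
                       name, n_no_ortholog)
    if not human:
        logger.warning("%s: term filter matched no genes; returning empty list", name)
    return GeneList(name, human)


def build_anatomy_index(annot: PhenotypeAnnotation,
                        neu_dev: GeneList,
                        orthologs: Mapping[str, str]) -> dict[str, GeneList]:
    """Map each EMAPA anatomy id to the neu.dev genes whose knockout impairs it.

    Genes are translated to human symbols first; genes outside the supplied
    neu.dev list are excluded, so every indexed gene is a neu.dev member.
    """
    by_anatomy: dict[str, set[str]] = {}
    for rec in annot.records:
        human = orthologs.get(rec.gene_symbol)
        if human is None or human.upper() not in neu_dev.genes:
            continue
        for emapa in rec.emapa_ids:
            by_anatomy.setdefault(emapa, set()).add(human.upper())
    if not by_anatomy:
        logger.warning("annotation contains no EMAPA links for neu.dev genes; "
                       "anatomy index is empty")
    return {emapa: GeneList(emapa, genes) for emapa, genes in sorted(by_anatomy.items())}
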