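"""Aggregation of IMPC-style phenotype and lacZ data by predicted outcome.

Takes per-design outcome predictions together with a phenotype-hit export
(one significant Mammalian Phenotype term per hit) and a lacZ expression
export, and produces per-category, per-allele-group summaries: untested
genes, lines with no phenotype, lines with a lethality phenotype, and mean
phenotypes per tested line.  Genes whose designs fall in more than one
outcome category are excluded throughout, because the phenotype data do
not say which design a line carries.

Significance is taken from the input as given; this module never re-tests.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from en2splice.design_ingest import DesignPrediction
from en2splice.en2_core import OutcomeCategory

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleGroup",
    "PhenotypeRecord",
    "LaczRecord",
    "CategorySummary",
    "parse_phenotype_csv",
    "parse_lacz_csv",
    "allele_group_of",
    "is_lethal",
    "summarize",
    "lacz_silent_genes",
    "summaries_to_frame",
    "summaries_to_tidy_frame",
]


class AlleleGroup(enum.Enum):
    """Allele families pooled for phenotype aggregation."""

    KO_FIRST_AND_NONCOND = "knockout_first_and_targeted_noncond"  # tm*a + tm*e
    LACZ_DELETION = "lacz_deletion"  # tm*b

    @property
    def label(self) -> str:
        return (
            "Knockout-first and targeted non-conditional alleles"
            if self is AlleleGroup.KO_FIRST_AND_NONCOND
            else "LacZ-tagged deletion alleles"
        )


# tm<digits><letter> embedded in an allele superscript, e.g. Xyz<tm1a(EUCOMM)Wtsi>
_TM_RE = re.compile(r"tm\d+([a-z])", re.IGNORECASE)


def allele_group_of(allele_symbol: str) -> Optional[AlleleGroup]:
    """Map an allele symbol to its aggregation group.

    tm<n>a and tm<n>e alleles pool into KO_FIRST_AND_NONCOND, tm<n>b into
    LACZ_DELETION; conditional (tm<n>c) and unrecognised symbols return
    ``None`` and are excluded from aggregation.
    """
    m = _TM_RE.search(allele_symbol)
    if not m:
        return None
    letter = m.group(1).lower()
    if letter in ("a", "e"):
        return AlleleGroup.KO_FIRST_AND_NONCOND
    if letter == "b":
        return AlleleGroup.LACZ_DELETION
    return None


def is_lethal(
    mp_term_name: str, lethal_term_ids: Optional[FrozenSet[str]] = None,
    mp_term_id: Optional[str] = None,
) -> bool:
    """Whether an MP annotation counts as a lethality phenotype.

    Default criterion: the term name contains "lethal" case-insensitively,
    which captures the preweaning/embryonic lethality term families.  An
    explicit MP-id allowlist can be supplied for stricter ontology-based
    matching; when given, it replaces the substring rule.
    """
    if lethal_term_ids is not None:
        return mp_term_id is not None and mp_term_id in lethal_term_ids
    return "lethal" in mp_term_name.lower()


@dataclass(frozen=True)
class PhenotypeRecord:
    """One phenotyped mouse line with its significant MP hits."""

    gene_id: str
    line_id: str
    allele_symbol: str
    mp_terms: Tuple[Tuple[str, str], ...] = ()  # (term id, term name)

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.mp_terms]
        if len(ids) != len(set(ids)):
            raise ValueError(f"line {self.line_id}: duplicate MP term ids")

    @property
    def n_phenotypes(self) -> int:
        return len(self.mp_terms)


@dataclass(frozen=True)
class LaczRecord:
    gene_id: str
    tissue: str
    expressed: bool


@dataclass(frozen=True)
class CategorySummary:
    """Aggregate phenotype metrics for one outcome category x allele group."""

    category: OutcomeCategory
    allele_group: AlleleGroup
    genes_total: int
    genes_untested: int
    lines_tested: int
    lines_no_phenotype: int
    lines_lethal: int
    phenotypes_per_line: Optional[float]  # None when no lines were tested

    @property
    def pct_no_phenotype(self) -> Optional[float]:
        if self.lines_tested == 0:
            return None
        return 100.0 * self.lines_no_phenotype / self.lines_tested

    @property
    def pct_lethal(self) -> Optional[float]:
        if self.lines_tested == 0:
            return None
        return 100.0 * self.lines_lethal / self.lines_tested


DEFAULT_PHENO_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "gene_id": ("gene_accession_id", "marker_accession_id", "gene_id"),
    "line_id": ("colony_id", "line_id"),
    "allele_symbol": ("allele_symbol",),
    "mp_term_id": ("mp_term_id",),
    "mp_term_name": ("mp_term_name",),
}

DEFAULT_LACZ_COLUMNS: Dict[str, Tuple[str, ...]] = {
    "gene_id": ("gene_accession_id", "marker_accession_id", "gene_id"),
    "tissue": ("parameter_name", "tissue"),
    "expressed": ("expression", "expressed"),
}


def _resolve(df: pd.DataFrame, colmap: Mapping[str, Sequence[str]], field: str) -> str:
    for cand in colmap[field]:
        if cand in df.columns:
            return cand
    raise ValueError(
        f"phenotype/lacZ table is missing a column for {field!r} "
        f"(accepted headers: {', '.join(colmap[field])})"
    )


def parse_phenotype_csv(
    path, column_map: Optional[Mapping[str, Sequence[str]]] = None
) -> List[PhenotypeRecord]:
    """Parse a phenotype-hit CSV into one record per line.

    Two layouts are supported: one row per line x hit with ``mp_term_id`` /
    ``mp_term_name`` columns (a row with both empty contributes no term),
    or one row per line with a delimited ``mp_terms`` column holding
    ``id=name`` pairs joined by ``;``.  Rows for the same line are merged
    by the union of their MP terms.
    """
    colmap = dict(DEFAULT_PHENO_COLUMNS)
    if column_map:
        colmap.update({k: tuple(v) for k, v in column_map.items()})
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.empty:
        return []
    gene_c = _resolve(df, colmap, "gene_id")
    line_c = _resolve(df, colmap, "line_id")
    allele_c = _resolve(df, colmap, "allele_symbol")
    packed = "mp_terms" in df.columns
    if not packed:
        id_c = _resolve(df, colmap, "mp_term_id")
        name_c = _resolve(df, colmap, "mp_term_name")

    terms: Dict[str, Dict[str, str]] = defaultdict(dict)
    meta: Dict[str, Tuple[str, str]] = {}
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        line_id = str(row[line_c]).strip()
        gene_id = str(row[gene_c]).strip()
        allele = str(row[allele_c]).strip()
        if not line_id or line_id.lower() == "nan":
            logger.warning("phenotype row %d skipped: missing line id", row_no)
            continue
        meta.setdefault(line_id, (gene_id, allele))
        if packed:
            cell = row.get("mp_terms")
            if cell is None or pd.isna(cell):
                continue
            for token in str(cell).split(";"):
                token = token.strip()
                if not token:
                    continue
                term_id, _, term_name = token.partition("=")
                terms[line_id][term_id.strip()] = term_name.strip() or term_id.strip()
        else:
            tid, tname = row.get(id_c), row.get(name_c)
            if tid is None or pd.isna(tid) or not str(tid).strip():
                continue
            terms[line_id][str(tid).strip()] = (
                "" if tname is None or pd.isna(tname) else str(tname).strip()
            )
    return [
        PhenotypeRecord(
            gene_id=gene, line_id=line_id, allele_symbol=allele,
            mp_terms=tuple(sorted(terms.get(line_id, {}).items())),
        )
        for line_id, (gene, allele) in meta.items()
    ]


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in ("true", "1", "yes", "expressed", "expression"):
        return True
    if t in ("false", "0", "no", "not expressed", "no expression", "absent"):
        return False
    raise ValueError(f"unrecognised expression call {token!r}")


def parse_lacz_csv(
    path, column_map: Optional[Mapping[str, Sequence[str]]] = None
) -> List[LaczRecord]:
    """Parse a lacZ expression CSV (gene x tissue x call)."""
    colmap = dict(DEFAULT_LACZ_COLUMNS)
    if column_map:
        colmap.update({k: tuple(v) for k, v in column_map.items()})
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.empty:
        return []
    gene_c = _resolve(df, colmap, "gene_id")
    tissue_c = _resolve(df, colmap, "tissue")
    expr_c = _resolve(df, colmap, "expressed")
    records = []
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        try:
            records.append(
                LaczRecord(
                    gene_id=str(row[gene_c]).strip(),
                    tissue=str(row[tissue_c]).strip(),
                    expressed=_parse_bool(row[expr_c]),
                )
            )
        except ValueError as exc:
            logger.warning("lacZ row %d skipped: %s", row_no, exc)
    return records


def summarize(
    predictions: Iterable[DesignPrediction],
    phenotype_records: Iterable[PhenotypeRecord],
    multi_category: Optional[Set[str]] = None,
    lethal_term_ids: Optional[FrozenSet[str]] = None,
) -> List[CategorySummary]:
    """Aggregate phenotype metrics per outcome category and allele group.

    A gene's category comes from its design predictions; genes in
    ``multi_category`` are excluded from every count.  A line appearing
    with several allele symbols contributes to each matching group
    independently.  ``phenotypes_per_line`` is total MP terms divided by
    lines tested, or ``None`` for an untested category x group cell.
    """
    multi_category = multi_category or set()
    gene_category: Dict[str, OutcomeCategory] = {}
    for p in predictions:
        if p.gene_id in multi_category:
            continue
        gene_category[p.gene_id] = p.category

    # line-level tallies keyed by (category, allele group)
    lines: Dict[Tuple[OutcomeCategory, AlleleGroup], List[PhenotypeRecord]] = defaultdict(list)
    tested_genes: Dict[Tuple[OutcomeCategory, AlleleGroup], Set[str]] = defaultdict(set)
    for rec in phenotype_records:
        category = gene_category.get(rec.gene_id)
        if category is None:
            continue  # gene unpredicted or multi-category
        for group in _groups_of(rec.allele_symbol):
            lines[(category, group)].append(rec)
            tested_genes[(category, group)].add(rec.gene_id)

    genes_by_cat: Dict[OutcomeCategory, Set[str]] = defaultdict(set)
    for gene, cat in gene_category.items():
        genes_by_cat[cat].add(gene)

    summaries = []
    for category in OutcomeCategory:
        for group in AlleleGroup:
            key = (category, group)
            cat_genes = genes_by_cat.get(category, set())
            cell_lines = lines.get(key, [])
            n_terms = sum(r.n_phenotypes for r in cell_lines)
            n_lethal = sum(
                1
                for r in cell_lines
                if any(
                    is_lethal(name, lethal_term_ids, mp_term_id=tid)
                    for tid, name in r.mp_terms
                )
            )
            summaries.append(
                CategorySummary(
                    category=category,
                    allele_group=group,
                    genes_total=len(cat_genes),
                    genes_untested=len(cat_genes - tested_genes.get(key, set())),
                    lines_tested=len(cell_lines),
                    lines_no_phenotype=sum(1 for r in cell_lines if r.n_phenotypes == 0),
                    lines_lethal=n_lethal,
                    phenotypes_per_line=(n_terms / len(cell_lines)) if cell_lines else None,
                )
            )
    return summaries


def _groups_of(allele_symbol: str) -> List[AlleleGroup]:
    group = allele_group_of(allele_symbol)
    return [] if group is None else [group]


def lacz_silent_genes(
    lacz_records: Iterable[LaczRecord], min_tissues: int = 27
) -> Set[str]:
    """Genes with no lacZ expression in any of ``min_tissues``+ tissues.

    Tissue names compare case-insensitively after whitespace trimming;
    duplicated gene x tissue rows collapse by logical OR on the call.
    Genes assayed in fewer than ``min_tissues`` distinct tissues are never
    reported silent (insufficient coverage).
    """
    calls: Dict[str, Dict[str, bool]] = defaultdict(dict)
    for rec in lacz_records:
        tissue = rec.tissue.strip().lower()
        calls[rec.gene_id][tissue] = calls[rec.gene_id].get(tissue, False) or rec.expressed
    return {
        gene
        for gene, by_tissue in calls.items()
        if len(by_tissue) >= min_tissues and not any(by_tissue.values())
    }


def summaries_to_frame(summaries: Iterable[CategorySummary]) -> pd.DataFrame:
    """Wide summary table, one row per category x allele group, with raw
    numerators and denominators alongside every percentage."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "category": s.category.name,
                "allele_group": s.allele_group.value,
                "genes_total": s.genes_total,
                "genes_untested": s.genes_untested,
                "lines_tested": s.lines_tested,
                "lines_no_phenotype": s.lines_no_phenotype,
                "pct_no_phenotype": s.pct_no_phenotype,
                "lines_lethal": s.lines_lethal,
                "pct_lethal": s.pct_lethal,
                "phenotypes_per_line": s.phenotypes_per_line,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_tidy_frame(summaries: Iterable[CategorySummary]) -> pd.DataFrame:
    """Long-format (category, allele_group, metric, value) table for plotting."""
    rows = []
    for s in summaries:
        for metric, value in (
            ("genes_total", s.genes_total),
            ("genes_untested", s.genes_untested),
            ("lines_tested", s.lines_tested),
            ("lines_no_phenotype", s.lines_no_phenotype),
            ("lines_lethal", s.lines_lethal),
            ("phenotypes_per_line", s.phenotypes_per_line),
        ):
            rows.append(
                {
                    "category": s.category.name,
                    "allele_group": s.allele_group.value,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
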