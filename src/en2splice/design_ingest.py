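"""Reading exon-phase and allele-design tables and predicting outcomes.

This is the bulk-audit half of the pipeline: parse a BioMart-style exon
table and an IKMC-style design table, resolve the (start, end) phase pair
of each design's critical-exon block, and classify every design with the
cassette frame logic from :mod:`en2splice.en2_core`.

Designs whose critical exons cannot be found in the exon table are skipped
and counted (the "no phase information" attrition), never silently dropped.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from en2splice.en2_core import (
    DEFAULT_CASSETTE,
    En2Cassette,
    InsertionMode,
    OutcomeCategory,
    PhasePair,
    classify_design,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExonRecord",
    "AlleleClass",
    "AlleleDesign",
    "DesignPrediction",
    "PredictionReport",
    "MissingPhaseError",
    "parse_exon_table",
    "parse_design_table",
    "load_column_map",
    "resolve_critical_phases",
    "predict_all",
    "multi_category_genes",
    "category_totals",
    "predictions_to_frame",
    "summary_dict",
]

_VALID_PHASES = {-1, 0, 1, 2}

# Canonical field -> accepted column headers, first match wins.  The first
# entry of each list is the BioMart-export spelling; the plain snake_case
# names are what the synthetic generator emits.
DEFAULT_EXON_DIALECT: Dict[str, Tuple[str, ...]] = {
    "gene_id": ("Gene stable ID", "gene_id"),
    "transcript_id": ("Transcript stable ID", "transcript_id"),
    "exon_id": ("Exon stable ID", "exon_id"),
    "rank": ("Exon rank in transcript", "rank"),
    "start_phase": ("Start phase", "start_phase"),
    "end_phase": ("End phase", "end_phase"),
    "length_bp": ("Exon length", "length_bp"),
}


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one transcript, with Ensembl-style phases."""

    gene_id: str
    transcript_id: str
    exon_id: str
    rank: int
    start_phase: int
    end_phase: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if self.start_phase not in _VALID_PHASES or self.end_phase not in _VALID_PHASES:
            raise ValueError("phases must be in {-1, 0, 1, 2}")

    @property
    def phases(self) -> PhasePair:
        return PhasePair(self.start_phase, self.end_phase)


class AlleleClass(enum.Enum):
    """IKMC allele families relevant to the audit."""

    KNOCKOUT_FIRST = "knockout_first"     # tm1a / tm2a: cassette before the critical exon
    TARGETED_NONCOND = "targeted_noncond"  # tm1e: tm1a-like, no 3' loxP
    LACZ_DELETION = "lacz_deletion"        # tm1b: critical exon deleted, lacZ retained
    CONDITIONAL = "conditional"            # tm1c: cassette removed, function restored

    @classmethod
    def parse(cls, token: str) -> "AlleleClass":
        t = token.strip().lower()
        aliases = {
            "tm1a": cls.KNOCKOUT_FIRST, "tm2a": cls.KNOCKOUT_FIRST,
            "a": cls.KNOCKOUT_FIRST, "knockout_first": cls.KNOCKOUT_FIRST,
            "tm1e": cls.TARGETED_NONCOND, "e": cls.TARGETED_NONCOND,
            "targeted_noncond": cls.TARGETED_NONCOND,
            "tm1b": cls.LACZ_DELETION, "b": cls.LACZ_DELETION,
            "lacz_deletion": cls.LACZ_DELETION,
            "tm1c": cls.CONDITIONAL, "c": cls.CONDITIONAL,
            "conditional": cls.CONDITIONAL,
        }
        if t in aliases:
            return aliases[t]
        raise ValueError(f"unrecognised allele class {token!r}")


#: Default insertion mode per allele class.  tm1a-like alleles leave the
#: critical exon intact (insert lands before it); tm1b deletes it.  The
#: mapping is a default only: one documented tm1a line (Col4a3) carried the
#: insert in place of the critical exon, so callers may override.
DEFAULT_MODE: Dict[AlleleClass, Optional[InsertionMode]] = {
    AlleleClass.KNOCKOUT_FIRST: InsertionMode.BEFORE,
    AlleleClass.TARGETED_NONCOND: InsertionMode.BEFORE,
    AlleleClass.LACZ_DELETION: InsertionMode.REPLACES,
    AlleleClass.CONDITIONAL: None,  # gene function restored; nothing to classify
}


@dataclass(frozen=True)
class AlleleDesign:
    design_id: str
    gene_id: str
    allele_class: AlleleClass
    critical_exon_ids: Tuple[str, ...]
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.critical_exon_ids:
            raise ValueError("a design needs at least one critical exon id")


@dataclass(frozen=True)
class DesignPrediction:
    design_id: str
    gene_id: str
    mode: InsertionMode
    phases: PhasePair
    category: OutcomeCategory


@dataclass
class PredictionReport:
    """Predictions plus the attrition bookkeeping of a bulk run."""

    predictions: List[DesignPrediction] = field(default_factory=list)
    skipped: List[Tuple[str, str]] = field(default_factory=list)  # (design_id, reason)

    @property
    def n_classified(self) -> int:
        return len(self.predictions)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    def totals(self) -> Dict[OutcomeCategory, int]:
        return category_totals(self.predictions)


class MissingPhaseError(KeyError):
    """Raised when a design's critical exons cannot be resolved to phases."""


def load_column_map(path) -> Dict[str, Tuple[str, ...]]:
    """Read a ``canonical: column name`` mapping from a flat text file.

    Lines are ``key: value``; blank lines and ``#`` comments are ignored.
    Unlisted canonical fields fall back to the bundled default dialect.
    """
    mapping = dict(DEFAULT_EXON_DIALECT)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"malformed column-map line: {raw!r}")
        key, value = (s.strip() for s in line.split(":", 1))
        mapping[key] = (value,)
    return mapping


def _read_table(path) -> pd.DataFrame:
    """Read a TSV/CSV with an auto-detected delimiter; '#' lines are comments."""
    return pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str)


def _resolve_columns(
    df: pd.DataFrame, dialect: Mapping[str, Sequence[str]]
) -> Dict[str, str]:
    resolved = {}
    for canonical, candidates in dialect.items():
        for cand in candidates:
            if cand in df.columns:
                resolved[canonical] = cand
                break
        else:
            raise ValueError(
                f"exon table is missing a column for {canonical!r} "
                f"(accepted headers: {', '.join(candidates)})"
            )
    return resolved


def parse_exon_table(
    path, dialect: Optional[Mapping[str, Sequence[str]]] = None
) -> List[ExonRecord]:
    """Parse an exon-phase table (TSV or CSV; delimiter auto-detected).

    Rows whose phase, rank or length fields do not parse into their domains
    are rejected and logged with their row number; a missing mandatory
    column or a duplicate (transcript, rank) pair is a hard error.
    """
    df = _read_table(path)
    cols = _resolve_columns(df, dialect or DEFAULT_EXON_DIALECT)
    records: List[ExonRecord] = []
    seen: Set[Tuple[str, int]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        values = dict(zip(df.columns, row))
        try:
            rec = ExonRecord(
                gene_id=str(values[cols["gene_id"]]),
                transcript_id=str(values[cols["transcript_id"]]),
                exon_id=str(values[cols["exon_id"]]),
                rank=int(values[cols["rank"]]),
                start_phase=int(values[cols["start_phase"]]),
                end_phase=int(values[cols["end_phase"]]),
                length_bp=int(values[cols["length_bp"]]),
            )
        except (TypeError, ValueError) as exc:
            logger.warning("exon table row %d rejected: %s", row_no, exc)
            continue
        key = (rec.transcript_id, rec.rank)
        if key in seen:
            raise ValueError(
                f"duplicate exon rank {rec.rank} on transcript {rec.transcript_id}"
            )
        seen.add(key)
        records.append(rec)
    _check_rank_contiguity(records)
    return records


def _check_rank_contiguity(records: Iterable[ExonRecord]) -> None:
    by_tx: Dict[str, List[int]] = defaultdict(list)
    for rec in records:
        by_tx[rec.transcript_id].append(rec.rank)
    for tx, ranks in by_tx.items():
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError(f"transcript {tx}: exon ranks are not contiguous from 1")


def parse_design_table(path) -> List[AlleleDesign]:
    """Parse an allele-design CSV.

    Expected header: ``design_id,gene_id,allele_class,transcript_id,
    critical_exon_ids`` with the exon-id list semicolon-joined; the
    transcript column may be empty.
    """
    df = _read_table(path)
    required = ["design_id", "gene_id", "allele_class", "critical_exon_ids"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"design table is missing mandatory column {col!r}")
    designs: List[AlleleDesign] = []
    for row_no, values in enumerate(df.to_dict("records"), start=2):
        try:
            tx = values.get("transcript_id")
            tx = None if tx is None or pd.isna(tx) or not str(tx).strip() else str(tx)
            designs.append(
                AlleleDesign(
                    design_id=str(values["design_id"]),
                    gene_id=str(values["gene_id"]),
                    allele_class=AlleleClass.parse(str(values["allele_class"])),
                    critical_exon_ids=tuple(
                        t.strip() for t in str(values["critical_exon_ids"]).split(";") if t.strip()
                    ),
                    transcript_id=tx,
                )
            )
        except (TypeError, ValueError) as exc:
            logger.warning("design table row %d rejected: %s", row_no, exc)
    return designs


def _index_exons(exons: Iterable[ExonRecord]):
    by_tx: Dict[str, Dict[str, ExonRecord]] = defaultdict(dict)
    for rec in exons:
        by_tx[rec.transcript_id][rec.exon_id] = rec
    return by_tx


def _choose_transcript(design: AlleleDesign, by_tx) -> str:
    """Pick the reference transcript for a design's critical exons.

    Preference: the transcript named on the design row; failing that, any
    transcript containing all critical exon ids, ties broken by
    lexicographically smallest id (logged).
    """
    wanted = set(design.critical_exon_ids)
    if design.transcript_id is not None:
        tx_map = by_tx.get(design.transcript_id)
        if tx_map is not None and wanted <= set(tx_map):
            return design.transcript_id
        raise MissingPhaseError(
            f"design {design.design_id}: critical exons not on transcript "
            f"{design.transcript_id}"
        )
    hosts = sorted(tx for tx, tx_map in by_tx.items() if wanted <= set(tx_map))
    if not hosts:
        raise MissingPhaseError(
            f"design {design.design_id}: no transcript contains all critical exons"
        )
    if len(hosts) > 1:
        logger.warning(
            "design %s: %d transcripts host the critical exons; using %s",
            design.design_id, len(hosts), hosts[0],
        )
    return hosts[0]


def resolve_critical_phases(
    design: AlleleDesign, exons: Iterable[ExonRecord]
) -> PhasePair:
    """Phase pair of a design's critical-exon block.

    For a block of consecutive exons the pair is (start phase of the first,
    end phase of the last): the insert replaces the whole block, so interior
    boundaries are spliced away.  Raises :class:`MissingPhaseError` when the
    exons cannot be located (the caller skips and counts the design) and
    ``ValueError`` when the named exons are not consecutive ranks.
    """
    by_tx = exons if isinstance(exons, dict) else _index_exons(exons)
    tx = _choose_transcript(design, by_tx)
    recs = [by_tx[tx][eid] for eid in design.critical_exon_ids]
    recs.sort(key=lambda r: r.rank)
    ranks = [r.rank for r in recs]
    if ranks != list(range(ranks[0], ranks[0] + len(ranks))):
        raise ValueError(
            f"design {design.design_id}: critical exons are not consecutive "
            f"ranks on transcript {tx} (got {ranks})"
        )
    return PhasePair(recs[0].start_phase, recs[-1].end_phase)


def predict_all(
    designs: Iterable[AlleleDesign],
    exons: Iterable[ExonRecord],
    cassette: En2Cassette = DEFAULT_CASSETTE,
    mode_override: Optional[InsertionMode] = None,
    both_modes: bool = False,
    collapse_tm1a_stop: bool = False,
) -> PredictionReport:
    """Classify every resolvable design; count the rest.

    ``mode_override`` forces one insertion mode for all designs;
    ``both_modes`` emits one prediction per mode per design (mode is not
    fully determined by allele class in practice).  Designs with no phase
    information, and conditional designs (which restore gene function),
    are recorded in ``report.skipped`` with a reason.
    """
    by_tx = _index_exons(exons)
    report = PredictionReport()
    for design in designs:
        try:
            phases = resolve_critical_phases(design, by_tx)
        except MissingPhaseError as exc:
            reason = f"no phase information: {exc.args[0]}"
            logger.info("skipping %s", reason)
            report.skipped.append((design.design_id, reason))
            continue
        if both_modes:
            modes = [InsertionMode.BEFORE, InsertionMode.REPLACES]
        elif mode_override is not None:
            modes = [mode_override]
        else:
            default = DEFAULT_MODE[design.allele_class]
            if default is None:
                report.skipped.append(
                    (design.design_id, "conditional allele: gene function restored")
                )
                continue
            modes = [default]
        for mode in modes:
            category = classify_design(
                phases, mode, cassette, collapse_tm1a_stop=collapse_tm1a_stop
            )
            report.predictions.append(
                DesignPrediction(
                    design_id=design.design_id,
                    gene_id=design.gene_id,
                    mode=mode,
                    phases=phases,
                    category=category,
                )
            )
    return report


def category_totals(
    predictions: Iterable[DesignPrediction],
) -> Dict[OutcomeCategory, int]:
    totals = Counter(p.category for p in predictions)
    return {cat: totals.get(cat, 0) for cat in OutcomeCategory}


def multi_category_genes(predictions: Iterable[DesignPrediction]) -> Set[str]:
    """Genes whose designs land in two or more outcome categories.

    Phenotype aggregation excludes these genes: with several designs in
    different categories there is no way to tell which design a phenotyped
    line carries.
    """
    cats: Dict[str, Set[OutcomeCategory]] = defaultdict(set)
    for p in predictions:
        cats[p.gene_id].add(p.category)
    return {g for g, cs in cats.items() if len(cs) >= 2}


def predictions_to_frame(predictions: Iterable[DesignPrediction]) -> pd.DataFrame:
    """Tidy predictions table (one row per design x mode)."""
    rows = [
        {
            "design_id": p.design_id,
            "gene_id": p.gene_id,
            "mode": p.mode.value,
            "start_phase": p.phases.start_phase,
            "end_phase": p.phases.end_phase,
            "category": p.category.name,
        }
        for p in predictions
    ]
    return pd.DataFrame(
        rows,
        columns=["design_id", "gene_id", "mode", "start_phase", "end_phase", "category"],
    )


def summary_dict(report: PredictionReport) -> dict:
    """JSON-ready run summary: totals, per-gene category sets, attrition."""
    gene_cats: Dict[str, Set[str]] = defaultdict(set)
    for p in report.predictions:
        gene_cats[p.gene_id].add(p.category.name)
    return {
        "n_designs_classified": report.n_classified,
        "n_designs_skipped": report.n_skipped,
        "category_totals": {c.name: n for c, n in report.totals().items()},
        "genes_per_category": {
            c.name: sum(1 for cs in gene_cats.values() if c.name in cs)
            for c in OutcomeCategory
        },
        "multi_category_genes": sorted(multi_category_genes(report.predictions)),
        "skipped": [{"design_id": d, "reason": r} for d, r in report.skipped],
    }
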