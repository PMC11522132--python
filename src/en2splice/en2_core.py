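"""Frame arithmetic for the *En2* splice-acceptor insertion.

The IKMC knockout-first cassette carries the 158 bp *En2* splice-acceptor
sequence in front of the lacZ reporter.  A cryptic splice donor ("aggt")
inside that sequence causes the first 115 bp to be retained in the mature
transcript of many mutant lines, either inserted before the critical exon
(tm1a-like alleles) or replacing it (tm1b-like alleles).  Because
115 mod 3 == 1, the transcriptional outcome depends on the reading-frame
phase in which the retained insert is read:

* start phase 2 -- an in-frame TAA inside the insert truncates translation
  (the "*En2*-induced stop codon" outcome);
* start phase 0 or 1 -- the insert translates cleanly, so the outcome is
  readthrough when the critical exon's end phase matches the phase the
  insert ends in, and a frameshift otherwise.

This module holds the cassette constants and every primitive needed to
classify a design: phase-chain arithmetic, frame-aware translation of the
insert, boundary stop-codon detection, and the outcome classifier.

Phase convention (Ensembl semantics): the start phase of an exon is the
number of bases of the split codon contributed by the *previous* exon, so
an insert read at start phase 1 contributes 2 bases to complete that codon
and at phase 2 contributes 1 base; phase -1 marks an exon/intron boundary
that falls in non-coding sequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Tuple

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "En2Cassette",
    "PhasePair",
    "OutcomeCategory",
    "TranslationResult",
    "BoundaryContext",
    "InsertionMode",
    "DEFAULT_CASSETTE",
    "end_phase_after",
    "translate_insert",
    "boundary_stop_check",
    "classify_replacement",
    "classify_insertion_before",
    "classify_design",
    "cassette_fasta_path",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(c.lower() for c in _STANDARD_TABLE.stop_codons)

#: Full 158 bp En2 splice-acceptor sequence carried by the cassette.
EN2_FULL_SEQUENCE = (
    "gtcccaggtcccgaaaaccaaagaagaagaaccctaacaaagaggacaagcggcctcgca"
    "cagccttcactgctgagcagctccagaggctcaaggctgagtttcagaccaacaggtacc"
    "tgacagagcagcggcgccagagtctggcacaggagctc"
)

#: 115 bp fragment retained in the transcript when the cryptic donor is used:
#: the prefix of the full sequence ending at the "ag" of the "aggt" motif.
EN2_INSERT_SEQUENCE = EN2_FULL_SEQUENCE[:115]

#: 1-based position of the "aggt" cryptic-donor motif in the full sequence.
CRYPTIC_DONOR_START = 114

_VALID_PHASES = (-1, 0, 1, 2)


class OutcomeCategory(enum.Enum):
    """Predicted transcriptional outcome of the retained insert."""

    READTHROUGH = "Readthrough"
    FRAMESHIFT = "Frameshift"
    STOP_IN_INSERT = "En2-induced stop codon"
    OTHER = "Other"


class InsertionMode(enum.Enum):
    """How the insert relates to the critical exon."""

    BEFORE = "before"      # inserted upstream, critical exon intact (tm1a-like)
    REPLACES = "replaces"  # insert stands in place of the critical exon (tm1b-like)


@dataclass(frozen=True)
class En2Cassette:
    """Immutable record of the cassette sequences and the cryptic donor.

    Validated at construction: the insert must be the 115 bp prefix of the
    158 bp acceptor, terminating at the "ag" of the "aggt" donor motif, and
    its length mod 3 must be 1 (the basis of the always-frameshift behaviour
    when inserted before the critical exon).
    """

    full_sequence: str = EN2_FULL_SEQUENCE
    insert_sequence: str = EN2_INSERT_SEQUENCE
    cryptic_donor_start: int = CRYPTIC_DONOR_START

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_sequence", self.full_sequence.lower())
        object.__setattr__(self, "insert_sequence", self.insert_sequence.lower())
        full, ins = self.full_sequence, self.insert_sequence
        if set(full) - set("acgt"):
            raise ValueError("cassette sequence contains non-ACGT characters")
        if not ins or full[: len(ins)] != ins:
            raise ValueError("insert must be a prefix of the full sequence")
        d = self.cryptic_donor_start
        if not (1 <= d <= len(full) - 3):
            raise ValueError("cryptic donor position out of range")
        if full[d - 1 : d + 3] != "aggt":
            raise ValueError("no 'aggt' motif at the stated cryptic donor position")
        if len(ins) != d + 1 or not ins.endswith("ag"):
            raise ValueError("insert must end at the 'ag' of the cryptic donor")

    @property
    def insert_length(self) -> int:
        return len(self.insert_sequence)

    @property
    def frame_offset(self) -> int:
        """Net phase shift the insert introduces: length mod 3."""
        return len(self.insert_sequence) % 3


DEFAULT_CASSETTE = En2Cassette()


def cassette_fasta_path():
    """Path to the bundled FASTA with the 158 bp acceptor and 115 bp insert."""
    return resources.files("en2splice.data") / "en2_cassette.fasta"


@dataclass(frozen=True)
class PhasePair:
    """(start, end) phases of a critical-exon block; each in {-1, 0, 1, 2}."""

    start_phase: int
    end_phase: int

    def __post_init__(self) -> None:
        for name in ("start_phase", "end_phase"):
            v = getattr(self, name)
            if v not in _VALID_PHASES:
                raise ValueError(f"{name}={v!r} not in {{-1, 0, 1, 2}}")

    @property
    def is_coding(self) -> bool:
        return self.start_phase >= 0 and self.end_phase >= 0


@dataclass(frozen=True)
class BoundaryContext:
    """The 0-2 bases of the upstream exon belonging to the codon split
    across the insertion junction (length equals the start phase there)."""

    upstream_coding_suffix: str = ""

    def __post_init__(self) -> None:
        suffix = self.upstream_coding_suffix.lower()
        if len(suffix) > 2:
            raise ValueError("upstream coding suffix longer than 2 bases")
        if set(suffix) - set("acgt"):
            raise ValueError("suffix contains non-ACGT characters")
        object.__setattr__(self, "upstream_coding_suffix", suffix)


@dataclass(frozen=True)
class TranslationResult:
    """Outcome of reading the retained insert in a given frame.

    ``consumed_prefix`` holds the insert bases used to complete the codon
    split with the previous exon (0, 2 or 1 bases for start phases 0, 1, 2);
    ``stop_position`` is the 1-based inclusive base range of the first
    in-frame stop codon on the insert, or ``None`` when the frame is open.
    """

    start_phase: int
    consumed_prefix: str
    peptide: str
    remainder: str
    stop_position: Optional[Tuple[int, int]] = None

    @property
    def has_stop(self) -> bool:
        return self.stop_position is not None

    def table_notation(self) -> str:
        """Render as in the phase table: (gt)PRSR...(ag), stop as '*'."""
        out = ""
        if self.consumed_prefix:
            out += f"({self.consumed_prefix})"
        out += self.peptide
        if self.remainder:
            out += f"({self.remainder})"
        return out


def end_phase_after(start_phase: int, length_bp: int) -> int:
    """Phase at which a coding stretch of ``length_bp`` bases ends when it
    begins at ``start_phase``: ``(start_phase + length_bp) mod 3``.

    The end phase of one exon equals the start phase of the next, so this
    composes along an exon chain.
    """
    if start_phase not in (0, 1, 2):
        raise ValueError("start_phase must be 0, 1 or 2 (negative phases are non-coding)")
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    return (start_phase + length_bp) % 3


def _consumed_length(start_phase: int) -> int:
    # start phase = bases contributed by the previous exon, so the insert
    # donates (3 - phase) mod 3 bases to finish that codon.
    return (3 - start_phase) % 3


def translate_insert(
    cassette: En2Cassette = DEFAULT_CASSETTE, start_phase: int = 0
) -> TranslationResult:
    """Translate the retained insert in the frame set by ``start_phase``.

    Scans codons left to right with the standard nuclear code and halts at
    the first stop codon.  The consumed prefix (bases completing the codon
    split with the upstream exon) and the trailing partial codon are
    returned untranslated.
    """
    if start_phase not in (0, 1, 2):
        raise ValueError("start_phase must be 0, 1 or 2")
    seq = cassette.insert_sequence
    if set(seq) - set("acgt"):
        raise ValueError("insert contains non-ACGT characters")
    consumed = seq[: _consumed_length(start_phase)]
    body = seq[len(consumed) :]
    peptide = []
    stop: Optional[Tuple[int, int]] = None
    pos = len(consumed)  # 0-based offset of the next codon on the insert
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            peptide.append("*")
            stop = (pos + 1, pos + 3)  # 1-based inclusive
            break
        peptide.append(_STANDARD_TABLE.forward_table[codon.upper()])
        pos += 3
    remainder = "" if stop else seq[pos:]
    return TranslationResult(
        start_phase=start_phase,
        consumed_prefix=consumed,
        peptide="".join(peptide),
        remainder=remainder,
        stop_position=stop,
    )


def boundary_stop_check(
    context: BoundaryContext, cassette: En2Cassette = DEFAULT_CASSETTE
) -> bool:
    """True iff the codon straddling the insertion junction is a stop.

    The codon is formed by the upstream exon's coding suffix plus the
    leading bases of the insert.  With this insert (starting "gt...") only
    the suffix "ta" produces a stop (TAG); a phase-0 junction has no split
    codon and can never stop here.
    """
    suffix = context.upstream_coding_suffix
    if not suffix:
        return False
    codon = suffix + cassette.insert_sequence[: 3 - len(suffix)]
    return codon in STOP_CODONS


def classify_replacement(
    critical_phases: PhasePair, cassette: En2Cassette = DEFAULT_CASSETTE
) -> OutcomeCategory:
    """Outcome when the insert replaces the critical exon.

    Derived from the frame logic rather than hard-coded: a frame whose
    in-insert translation hits a stop yields STOP_IN_INSERT (start phase 2
    with this cassette, via the internal TAA); otherwise the outcome is
    READTHROUGH exactly when the critical exon's end phase equals the phase
    the insert ends in, else FRAMESHIFT.
    """
    start, end = critical_phases.start_phase, critical_phases.end_phase
    if start < 0 or end < 0:
        raise ValueError(
            "negative phases have no reading frame; route them through classify_design"
        )
    if translate_insert(cassette, start).has_stop:
        return OutcomeCategory.STOP_IN_INSERT
    if end == end_phase_after(start, cassette.insert_length):
        return OutcomeCategory.READTHROUGH
    return OutcomeCategory.FRAMESHIFT


def classify_insertion_before(
    critical_start_phase: int,
    cassette: En2Cassette = DEFAULT_CASSETTE,
    collapse_stop: bool = False,
) -> OutcomeCategory:
    """Outcome when the insert lands upstream of an intact critical exon.

    Because the insert length is not a multiple of 3 every coding start
    phase disrupts the frame; in phase 2 the disruption is an internal stop
    codon rather than a downstream frameshift.  ``collapse_stop=True``
    folds that case into FRAMESHIFT, matching the coarser blanket
    description of tm1a outcomes.
    """
    if critical_start_phase not in (0, 1, 2):
        raise ValueError("critical_start_phase must be 0, 1 or 2")
    if translate_insert(cassette, critical_start_phase).has_stop:
        return OutcomeCategory.FRAMESHIFT if collapse_stop else OutcomeCategory.STOP_IN_INSERT
    if cassette.frame_offset != 0:
        return OutcomeCategory.FRAMESHIFT
    return OutcomeCategory.READTHROUGH


def classify_design(
    critical_phases: PhasePair,
    mode: InsertionMode,
    cassette: En2Cassette = DEFAULT_CASSETTE,
    collapse_tm1a_stop: bool = False,
) -> OutcomeCategory:
    """Classify one allele design, routing negative (non-coding) phases.

    REPLACES mode: a critical exon starting in phase 2 but ending in a
    negative phase still hits the internal stop, so it is counted with
    STOP_IN_INSERT; any other negative start or end phase is OTHER; fully
    coding pairs delegate to :func:`classify_replacement`.  BEFORE mode:
    a negative start phase is OTHER; otherwise
    :func:`classify_insertion_before`.
    """
    if not isinstance(mode, InsertionMode):
        raise ValueError(f"invalid mode {mode!r}")
    start, end = critical_phases.start_phase, critical_phases.end_phase
    if mode is InsertionMode.REPLACES:
        if start == 2 and end < 0:
            return OutcomeCategory.STOP_IN_INSERT
        if start < 0 or end < 0:
            return OutcomeCategory.OTHER
        return classify_replacement(critical_phases, cassette)
    if start < 0:
        return OutcomeCategory.OTHER
    return classify_insertion_before(start, cassette, collapse_stop=collapse_tm1a_stop)
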