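"""Frame arithmetic, insert translation and outcome classification."""

import itertools

import pytest
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

from en2splice.en2_core import (
    DEFAULT_CASSETTE,
    BoundaryContext,
    En2Cassette,
    InsertionMode,
    OutcomeCategory,
    PhasePair,
    boundary_stop_check,
    cassette_fasta_path,
    classify_design,
    classify_insertion_before,
    classify_replacement,
    end_phase_after,
    translate_insert,
)

# ---------------------------------------------------------------------------
# Independent translation oracle: a hand-written codon table and a naive
# character-by-character scan, sharing no code with the implementation.

_BASES = "tcag"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_scan(seq, offset):
    """Translate seq starting at 0-based offset, halting at the first stop.

    Returns (peptide, stop_range) with a 1-based inclusive stop range.
    """
    peptide = ""
    for i in range(offset, len(seq) - 2, 3):
        aa = ORACLE_CODE[seq[i : i + 3]]
        peptide += aa
        if aa == "*":
            return peptide, (i + 1, i + 3)
    return peptide, None


# offset on the insert for each start phase: phase 1 consumes 2 bases,
# phase 2 consumes 1, phase 0 none.
PHASE_OFFSET = {0: 0, 1: 2, 2: 1}


class TestCassette:
    def test_sequence_invariants(self):
        c = DEFAULT_CASSETTE
        assert len(c.full_sequence) == 158
        assert len(c.insert_sequence) == 115
        assert c.full_sequence.startswith(c.insert_sequence)
        assert c.full_sequence[113:117] == "aggt"
        assert c.insert_sequence.endswith("accaacag")
        assert c.insert_sequence == c.full_sequence[: c.cryptic_donor_start + 1]
        assert len(c.insert_sequence) % 3 == 1

    def test_bundled_fasta_matches_constants(self):
        records = {r.id: str(r.seq).lower() for r in SeqIO.parse(
            str(cassette_fasta_path()), "fasta")}
        assert records["En2_splice_acceptor_full"] == DEFAULT_CASSETTE.full_sequence
        assert records["En2_retained_insert"] == DEFAULT_CASSETTE.insert_sequence

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"full_sequence": "acgtn" * 32},  # non-ACGT
            {"insert_sequence": "tttt"},  # not a prefix
            {"cryptic_donor_start": 50},  # no aggt there
        ],
    )
    def test_invalid_cassettes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            En2Cassette(**{**dict(
                full_sequence=DEFAULT_CASSETTE.full_sequence,
                insert_sequence=DEFAULT_CASSETTE.insert_sequence,
                cryptic_donor_start=DEFAULT_CASSETTE.cryptic_donor_start,
            ), **kwargs})

    def test_case_insensitive_input(self):
        c = En2Cassette(
            full_sequence=DEFAULT_CASSETTE.full_sequence.upper(),
            insert_sequence=DEFAULT_CASSETTE.insert_sequence.upper(),
        )
        assert c.insert_sequence == DEFAULT_CASSETTE.insert_sequence


class TestPhasePair:
    @pytest.mark.parametrize("bad", [(-2, 0), (0, 3), (5, 5)])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            PhasePair(*bad)

    def test_is_coding(self):
        assert PhasePair(0, 2).is_coding
        assert not PhasePair(-1, 2).is_coding


class TestEndPhaseAfter:
    @pytest.mark.parametrize("start,expected", [(0, 1), (1, 2), (2, 0)])
    def test_insert_length_shifts_phase_by_one(self, start, expected):
        assert end_phase_after(start, 115) == expected

    @pytest.mark.parametrize("p", [0, 1, 2])
    def test_multiple_of_three_preserves_phase(self, p):
        assert end_phase_after(p, 3) == p

    def test_negative_phase_rejected(self):
        with pytest.raises(ValueError):
            end_phase_after(-1, 10)
        with pytest.raises(ValueError):
            end_phase_after(0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        start=st.integers(0, 2),
        lengths=st.lists(st.integers(1, 500), min_size=1, max_size=8),
    )
    def test_phase_chain_composes(self, start, lengths):
        """Chaining exon by exon equals the closed form on the summed length."""
        phase = start
        for L in lengths:
            phase = end_phase_after(phase, L)
        assert phase == (start + sum(lengths)) % 3


class TestTranslateInsert:
    # Frozen expected peptides for the three reading frames of the insert.
    EXPECTED = {
        0: ("", "VPGPENQRRRTLTKRTSGLAQPSLLSSSRGSRLSFRPT", "g", None),
        1: ("gt", "PRSRKPKKKNPNKEDKRPRTAFTAEQLQRLKAEFQTN", "ag", None),
        2: ("g", "SQVPKTKEEEP*", "", (35, 37)),
    }

    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_frozen_peptides(self, phase):
        consumed, peptide, remainder, stop = self.EXPECTED[phase]
        r = translate_insert(DEFAULT_CASSETTE, phase)
        assert r.consumed_prefix == consumed
        assert r.peptide == peptide
        assert r.remainder == remainder
        assert r.stop_position == stop

    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_agrees_with_independent_oracle(self, phase):
        seq = DEFAULT_CASSETTE.insert_sequence
        peptide, stop = oracle_scan(seq, PHASE_OFFSET[phase])
        r = translate_insert(DEFAULT_CASSETTE, phase)
        assert r.peptide == peptide
        assert r.stop_position == stop

    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_base_accounting(self, phase):
        r = translate_insert(DEFAULT_CASSETTE, phase)
        if not r.has_stop:
            assert (
                len(r.consumed_prefix) + 3 * len(r.peptide) + len(r.remainder) == 115
            )
        assert ("*" in r.peptide) == r.has_stop
        if r.has_stop:
            assert r.peptide.endswith("*") and r.peptide.count("*") == 1

    def test_stop_unique_to_phase_two_frame(self):
        """Phases 0 and 1 are stop-free over the whole insert; the phase-2
        frame terminates at its first stop, the TAA at bases 35-37.

        (Two further TGA codons sit downstream in the phase-2 frame, at
        74-76 and 98-100; they are never reached because translation ends
        at the TAA, and the translated peptide carries exactly one stop.)
        """
        seq = DEFAULT_CASSETTE.insert_sequence
        for phase in (0, 1):
            offset = PHASE_OFFSET[phase]
            assert not any(
                ORACLE_CODE[seq[i : i + 3]] == "*"
                for i in range(offset, len(seq) - 2, 3)
            )
        first = next(
            i + 1
            for i in range(PHASE_OFFSET[2], len(seq) - 2, 3)
            if ORACLE_CODE[seq[i : i + 3]] == "*"
        )
        assert first == 35 and seq[34:37] == "taa"
        assert translate_insert(DEFAULT_CASSETTE, 2).peptide.count("*") == 1

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            translate_insert(DEFAULT_CASSETTE, 3)
        bad = En2Cassette.__new__(En2Cassette)
        object.__setattr__(bad, "insert_sequence", "acgtn")
        with pytest.raises(ValueError):
            translate_insert(bad, 0)

    def test_table_notation(self):
        assert translate_insert(DEFAULT_CASSETTE, 2).table_notation() == "(g)SQVPKTKEEEP*"


class TestBoundaryStop:
    @pytest.mark.parametrize(
        "suffix,expected",
        [("ta", True), ("ca", False), ("", False), ("t", False), ("a", False)],
    )
    def test_split_codon_outcomes(self, suffix, expected):
        # the insert starts "gt", so only suffix "ta" can complete a stop (TAG)
        assert boundary_stop_check(BoundaryContext(suffix)) is expected

    def test_long_suffix_rejected(self):
        with pytest.raises(ValueError):
            BoundaryContext("taa")


# The nine (start, end) phase combinations and their predicted effects when
# the insert replaces the critical exon.
TABLE_OF_NINE = {
    (0, 0): OutcomeCategory.FRAMESHIFT,
    (0, 1): OutcomeCategory.READTHROUGH,
    (0, 2): OutcomeCategory.FRAMESHIFT,
    (1, 0): OutcomeCategory.FRAMESHIFT,
    (1, 1): OutcomeCategory.FRAMESHIFT,
    (1, 2): OutcomeCategory.READTHROUGH,
    (2, 0): OutcomeCategory.STOP_IN_INSERT,
    (2, 1): OutcomeCategory.STOP_IN_INSERT,
    (2, 2): OutcomeCategory.STOP_IN_INSERT,
}


class TestClassifyReplacement:
    @pytest.mark.parametrize("pair,expected", sorted(TABLE_OF_NINE.items()))
    def test_all_nine_phase_pairs(self, pair, expected):
        assert classify_replacement(PhasePair(*pair)) is expected

    def test_category_census(self):
        from collections import Counter

        census = Counter(
            classify_replacement(PhasePair(s, e))
            for s, e in itertools.product(range(3), repeat=2)
        )
        assert census == {
            OutcomeCategory.READTHROUGH: 2,
            OutcomeCategory.FRAMESHIFT: 4,
            OutcomeCategory.STOP_IN_INSERT: 3,
        }

    @pytest.mark.parametrize("start", [0, 1])
    @pytest.mark.parametrize("end", [0, 1, 2])
    def test_readthrough_iff_end_phase_matches_insert(self, start, end):
        expected = (
            OutcomeCategory.READTHROUGH
            if end == end_phase_after(start, 115)
            else OutcomeCategory.FRAMESHIFT
        )
        assert classify_replacement(PhasePair(start, end)) is expected

    def test_negative_phase_rejected(self):
        with pytest.raises(ValueError, match="classify_design"):
            classify_replacement(PhasePair(-1, 0))


class TestClassifyInsertionBefore:
    @pytest.mark.parametrize(
        "start,expected",
        [
            (0, OutcomeCategory.FRAMESHIFT),
            (1, OutcomeCategory.FRAMESHIFT),
            (2, OutcomeCategory.STOP_IN_INSERT),
        ],
    )
    def test_insert_always_disrupts(self, start, expected):
        assert classify_insertion_before(start) is expected

    def test_collapse_flag_folds_stop_into_frameshift(self):
        assert (
            classify_insertion_before(2, collapse_stop=True)
            is OutcomeCategory.FRAMESHIFT
        )

    def test_negative_phase_rejected(self):
        with pytest.raises(ValueError):
            classify_insertion_before(-1)


class TestClassifyDesign:
    @pytest.mark.parametrize("end", [-1, 0, 1, 2])
    def test_phase_two_start_always_stop_in_replaces(self, end):
        """Start phase 2 hits the internal TAA whatever the end phase."""
        assert (
            classify_design(PhasePair(2, end), InsertionMode.REPLACES)
            is OutcomeCategory.STOP_IN_INSERT
        )

    @pytest.mark.parametrize(
        "pair",
        [p for p in itertools.product((-1, 0, 1, 2), repeat=2)
         if (p[0] < 0 or p[1] < 0) and not (p[0] == 2 and p[1] < 0)],
    )
    def test_other_negative_pairs_are_other(self, pair):
        assert (
            classify_design(PhasePair(*pair), InsertionMode.REPLACES)
            is OutcomeCategory.OTHER
        )

    @pytest.mark.parametrize("pair,expected", sorted(TABLE_OF_NINE.items()))
    def test_coding_pairs_delegate(self, pair, expected):
        assert classify_design(PhasePair(*pair), InsertionMode.REPLACES) is expected

    @pytest.mark.parametrize("end", [-1, 0, 1, 2])
    def test_before_mode_routes_negative_start_only(self, end):
        assert (
            classify_design(PhasePair(-1, end), InsertionMode.BEFORE)
            is OutcomeCategory.OTHER
        )
        assert (
            classify_design(PhasePair(0, end), InsertionMode.BEFORE)
            is OutcomeCategory.FRAMESHIFT
        )

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_design(PhasePair(0, 0), "replaces")
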