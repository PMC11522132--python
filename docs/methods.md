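# Methods

## Model

The object of study is the 158 bp *En2* splice-acceptor sequence at the 5'
end of the IKMC knockout-first disruption cassette, and specifically the
115 bp prefix of it that a cryptic splice donor ("aggt" at positions
114–117 of the acceptor; the donor's "gt" is cleaved off, leaving the
prefix ending "…accaacag") causes to be retained in mature mutant
transcripts. Both sequences are bundled as constants and as a FASTA file
and validated against each other at construction: the insert must be the
prefix of the acceptor terminating at the "ag" of the donor motif, and its
length mod 3 must be 1.

Phases follow Ensembl semantics: an exon's start phase is the number of
bases of the codon split across its 5' boundary that were contributed by
the *previous* exon, so the insert donates (3 − phase) mod 3 bases — 0, 2
or 1 for phases 0, 1, 2 — to complete that codon; phase −1 marks a
boundary inside non-coding sequence and never enters frame arithmetic.
The end phase after a coding stretch is the closed form
(start + length) mod 3, which composes associatively along an exon chain.

Translation of the insert uses the standard nuclear codon table
(Biopython's table 1; no mitochondrial variant), scanning codons left to
right and halting at the first stop. The three frames give:

* phase 0 — `VPGPENQRRRTLTKRTSGLAQPSLLSSSRGSRLSFRPT(g)`, open;
* phase 1 — `(gt)PRSRKPKKKNPNKEDKRPRTAFTAEQLQRLKAEFQTN(ag)`, open;
* phase 2 — `(g)SQVPKTKEEEP*`, terminated by an in-frame TAA.

The classifier derives outcomes from this frame logic rather than a
lookup: replacement of a critical exon with phases (s, e) is a stop-in-
insert whenever the frame set by s hits a stop during translation (phase 2
with this cassette), otherwise readthrough iff e equals
(s + 115) mod 3, else frameshift. Insertion before an intact critical
exon always disrupts: frameshift at phases 0–1 (115 is not a multiple of
3), the internal stop at phase 2. Design-level routing adds the
non-coding cases: in replacement mode a (2, negative) pair still meets the
internal stop and is counted with stop-in-insert, while any other negative
start or end phase is "Other"; in insertion-before mode a negative start
phase is "Other".

A boundary check covers the one junction effect the frame logic cannot
see: when the upstream exon ends in phase 2 with "TA", the insert's
leading "g" completes a TAG stop at the very start of the insertion. With
this insert, "ta" is the only suffix that can do so.

### Coordinate conventions and a known discrepancy

Stop positions are reported as 1-based inclusive base ranges on the 115 bp
insert. In the phase-2 frame the first stop is the TAA occupying bases
35–37; a description of this stop as "starting at base 37" circulates, but
37 is where the codon *ends*, and this package reports 35–37. Two further
TGA codons sit in the same frame at 74–76 and 98–100; they are never
reached because translation terminates at the TAA, so the biologically
meaningful statement — asserted by the tests — is that frames 0 and 1 are
stop-free over the whole insert and frame 2 terminates at a unique first
stop, not that the frame contains a single stop codon overall.

### Design choices where the design was open

* **Insertion-before at phase 2** is classified as stop-in-insert rather
  than folded into the blanket "frameshift" description of tm1a outcomes:
  it is the truthful consequence of the frame logic (the insert is read in
  the phase-2 frame and hits the TAA). Both are loss-of-frame outcomes;
  `--collapse-tm1a-stop` (or `collapse_stop=True`) restores the coarser
  labelling.
* **Multi-exon critical blocks** take the phase pair (first exon's start,
  last exon's end); the insert replaces the whole block and interior
  boundaries are spliced out. The rule is surfaced in the code and here
  because upstream conventions vary.
* **Allele class → insertion mode** defaults to tm1a/tm1e ⇒ before,
  tm1b ⇒ replaces, but is only a default (a tm1a allele has been observed
  carrying the insert in place of the critical exon); `--both-modes` emits
  both predictions per design.
* **Reference transcript**: the transcript named on the design row; else
  the transcript containing all critical exon ids, ties broken by
  lexicographic id with a logged warning.
* **Lethality criterion**: an MP term counts as lethal when its name
  contains "lethal" case-insensitively — this captures the preweaning and
  embryonic lethality term families without bundling the ontology. An
  explicit MP-id allowlist can be passed to `is_lethal`/`summarize` for
  ontology-based matching, and replaces the substring rule when given.
* **Untested genes** are genes with outcome predictions but no phenotype
  row in the matching allele group. A line appearing under several allele
  symbols contributes to each matching group independently.
* **Multi-category genes** (designs spanning ≥ 2 outcome categories) are
  excluded from every phenotype summary cell: the phenotype export does
  not identify which design a line carries.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_tissues` | 27 | distinct assayed tissues required before a gene can be called lacZ-silent |
| `fraction_untested` | 0.70 | probability a synthetic gene has no phenotype rows (≈ share of genes without phenotype data in the resource audited) |
| `no_phenotype_fraction` | 0.15 | probability a tested line has zero significant MP terms |
| `lethal_fraction` | 0.35 | marginal probability a tested line carries ≥ 1 lethality term |
| `mp_terms_per_line_mean` | 4.5 | Poisson mean of MP terms for phenotyped lines (truncated to ≥ 1) |
| `n_tissues` / `silent_gene_fraction` | 28 / 0.012 | lacZ tissues per gene and share of fully silent genes |
| `exon_length_range` | 40–300 bp | exon lengths; critical-exon lengths are drawn congruent to (end − start) mod 3, i.e. non-multiples of 3 except for same-phase pairs |
| `utr_flank_probability` | 0.8 | probability the first/last exon boundary carries phase −1 |
| `allele_class_mix` | 0.6 / 0.1 / 0.3 | tm1a-like : tm1e-like : tm1b-like proportions |

The phenotype defaults sit inside the ranges observed across outcome
categories in the phenotyping resource this pipeline is built to audit;
they are study conditions, not fitting knobs.

## The synthetic generator

`synthetic_data` emulates the statistical structure the analysis assumes:
one transcript per gene whose exon phases form a valid chain (end phase of
exon *i* = start phase of exon *i*+1; fully coding exons satisfy
end = (start + length) mod 3), an internal critical exon per gene whose
(start, end) pair follows a 9-component weight vector, allele designs with
a configurable class mix, a phenotype cohort, and a lacZ table. All
randomness flows through a single NumPy PCG64 generator seeded from the
config (sub-streams use seed, seed+1, seed+2), so bundles are
byte-reproducible across platforms.

Phase pairs are assigned by deterministic largest-remainder quota
allocation over the weight vector, then shuffled: uniform weights over a
gene count divisible by 9 give an exactly balanced composition, which is
what makes the 9,000-design audit split exactly 2,000/4,000/3,000 —
that ratio is forced by the 2:4:3 outcome mapping over the nine pairs,
so it doubles as an end-to-end correctness check of the pipeline.

Cohort generation draws, per tested line: zero terms with probability
`no_phenotype_fraction`, otherwise a truncated-Poisson count of terms; a
lethality term is injected with conditional probability
`lethal_fraction / (1 − no_phenotype_fraction)` among phenotyped lines so
the *marginal* lethal rate per tested line equals `lethal_fraction`
(validated: `lethal_fraction ≤ 1 − no_phenotype_fraction`, since a
zero-term line cannot carry one). The recovery estimator for the Poisson
mean is total terms over phenotyped lines; truncation biases it upward by
λ·e^(−λ)/(1 − e^(−λ)) ≈ 0.05 at λ = 4.5, an order of magnitude below the
3-standard-error band used by the tests. MP term names come from a small
bundled vocabulary of lethal and non-lethal names (term ids are synthetic
and unique per line), so the lethality criterion is exercised without
shipping the ontology. Non-silent lacZ genes are guaranteed at least one
positive tissue call, making configured silence exactly recoverable.

What the generator does **not** emulate: genomic coordinates or sequence
content beyond phases and lengths, ontology structure among MP terms,
correlated phenotypes within genes, multiple transcripts per gene (except
a targeted option for tie-break testing), and real attrition patterns in
the upstream exports. Passing tests therefore demonstrate the arithmetic,
plumbing and aggregation are correct under the stated statistical
structure — not that real exports are free of schema drift or annotation
error, which is why the parsers log and count every rejected row and
skipped design instead of dropping them.

## Numerical and procedural details

* Sequences are handled case-insensitively and canonicalised to lowercase;
  non-ACGT characters are rejected.
* Table parsing auto-detects comma/tab delimiters, treats `#` lines as
  comments, accepts BioMart-style or snake_case headers (remappable via a
  flat `key: value` column-map file), rejects and logs rows with
  out-of-domain phases, and hard-fails on missing columns, duplicate
  (transcript, rank) pairs, or non-contiguous ranks.
* A category × allele-group cell with zero tested lines reports
  `phenotypes_per_line` as undefined (empty/None), never 0.
* Tissue names compare case-insensitively after trimming; duplicate
  gene × tissue rows collapse by logical OR on the expression call.
* Problem sizes used by the test suite and acceptance script — 9,000
  designs for the balanced audit, 1,000 lines for cohort recovery, 2,909
  genes for the lacZ screen — were chosen to make quota allocation exact
  and sampling error small while keeping a full run in seconds.

## Known limitations

* The cryptic donor is taken as given; no splice-site strength prediction
  is attempted, and "leaky" correctly-spliced full-length transcription is
  out of scope.
* The classifier predicts transcript-level outcomes only; it says nothing
  about protein stability, nonsense-mediated decay efficiency, or
  reinitiation from downstream start codons.
* Statistical significance of phenotype calls is consumed as given from
  the input file; no re-testing and no between-category hypothesis tests
  are performed.
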