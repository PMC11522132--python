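"""Seeded generators for phase-consistent gene models, allele designs,
phenotype cohorts and lacZ tables.

The generators stand in for the Ensembl (exon phase) and IMPC (phenotype,
lacZ) bulk exports so that every pipeline stage can be exercised against
known ground truth.  Each gene gets one transcript whose exon phases form
a valid chain (the end phase of exon *i* is the start phase of exon
*i*+1, and fully coding exons satisfy end == (start + length) mod 3);
one internal exon per gene is designated the critical exon and its
(start, end) phase pair is drawn from a configurable weight vector.

Phase pairs are allocated by deterministic largest-remainder quotas over
the nine non-negative pairs, so a uniform weight vector over a gene count
divisible by nine yields an exactly balanced composition; the gene order
is then shuffled.  All randomness flows through one ``numpy`` PCG64
generator seeded from the config, so outputs are bit-reproducible across
platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from en2splice.design_ingest import (
    DEFAULT_MODE,
    AlleleClass,
    AlleleDesign,
    ExonRecord,
)
from en2splice.en2_core import (
    DEFAULT_CASSETTE,
    InsertionMode,
    OutcomeCategory,
    PhasePair,
    classify_design,
)

__all__ = [
    "SimulationConfig",
    "GeneModels",
    "generate_gene_models",
    "generate_designs",
    "generate_phenotype_cohort",
    "write_bundle",
    "NONLETHAL_MP_TERMS",
    "LETHAL_MP_TERMS",
]

#: Nine non-negative phase pairs in a fixed order (weight-vector order).
PHASE_PAIRS: Tuple[Tuple[int, int], ...] = tuple(
    itertools.product((0, 1, 2), repeat=2)
)

# Small MP-style vocabulary so the lethality criterion is exercised
# without shipping the ontology.  Names only need to be realistic enough
# for substring matching; ids are synthetic placeholders.
LETHAL_MP_TERMS: Tuple[Tuple[str, str], ...] = (
    ("MP:0011100", "preweaning lethality, complete penetrance"),
    ("MP:0011110", "preweaning lethality, incomplete penetrance"),
    ("MP:0008527", "embryonic lethality prior to organogenesis"),
    ("MP:0011092", "embryonic lethality, complete penetrance"),
)
NONLETHAL_MP_TERMS: Tuple[Tuple[str, str], ...] = (
    ("MP:0005560", "decreased circulating glucose level"),
    ("MP:0001556", "increased circulating HDL cholesterol level"),
    ("MP:0001399", "hyperactivity"),
    ("MP:0002644", "decreased heart rate"),
    ("MP:0001412", "abnormal locomotor activation"),
    ("MP:0002169", "no abnormal phenotype detected"),
    ("MP:0004738", "abnormal auditory brainstem response"),
    ("MP:0001262", "decreased body weight"),
    ("MP:0001261", "increased body weight"),
    ("MP:0002833", "increased heart weight"),
    ("MP:0000063", "decreased bone mineral density"),
    ("MP:0002834", "decreased heart weight"),
    ("MP:0000220", "increased monocyte cell number"),
    ("MP:0002590", "increased mean corpuscular volume"),
    ("MP:0005318", "decreased triglyceride level"),
    ("MP:0001870", "abnormal startle reflex"),
    ("MP:0003960", "increased lean body mass"),
    ("MP:0010025", "decreased total body fat amount"),
    ("MP:0000745", "tremors"),
    ("MP:0001486", "abnormal startle response"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study, with defaults matching the aggregate
    structure of the IMPC resource the pipeline is built to audit.

    ``fraction_untested`` defaults to 0.70 (roughly 70% of genes in each
    outcome category have no phenotype data); ``no_phenotype_fraction``,
    ``lethal_fraction`` and ``mp_terms_per_line_mean`` default to 0.15,
    0.35 and 4.5, inside the observed per-category ranges; lacZ defaults
    give 28 assayed tissues and about 1.2% fully silent genes.
    """

    seed: int = 0
    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (4, 9)
    exon_length_range: Tuple[int, int] = (40, 300)
    utr_flank_probability: float = 0.8
    phase_pair_weights: Optional[Tuple[float, ...]] = None  # None -> uniform over 9
    allele_class_mix: Tuple[float, float, float] = (0.6, 0.1, 0.3)  # tm1a, tm1e, tm1b
    second_design_fraction: float = 0.0
    fraction_untested: float = 0.70
    no_phenotype_fraction: float = 0.15
    lethal_fraction: float = 0.35
    mp_terms_per_line_mean: float = 4.5
    n_tissues: int = 28
    silent_gene_fraction: float = 0.012
    tissue_expression_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        lo, hi = self.exons_per_gene
        if not (3 <= lo <= hi):
            raise ValueError("exons_per_gene must satisfy 3 <= lo <= hi")
        llo, lhi = self.exon_length_range
        if not (4 <= llo <= lhi):
            raise ValueError("exon_length_range must satisfy 4 <= lo <= hi")
        if lhi - llo < 3:
            raise ValueError("exon_length_range must span at least 3 bp")
        for name in (
            "utr_flank_probability", "second_design_fraction", "fraction_untested",
            "no_phenotype_fraction", "lethal_fraction", "silent_gene_fraction",
            "tissue_expression_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lethal_fraction > 1.0 - self.no_phenotype_fraction + 1e-12:
            raise ValueError(
                "lethal_fraction cannot exceed 1 - no_phenotype_fraction "
                "(a line with zero MP terms cannot carry a lethality term)"
            )
        if self.phase_pair_weights is not None:
            w = tuple(float(x) for x in self.phase_pair_weights)
            if len(w) != 9 or any(x < 0 for x in w) or sum(w) <= 0:
                raise ValueError(
                    "phase_pair_weights must be 9 non-negative values, not all zero"
                )
            object.__setattr__(self, "phase_pair_weights", w)
        mix = tuple(float(x) for x in self.allele_class_mix)
        if len(mix) != 3 or any(x < 0 for x in mix) or sum(mix) <= 0:
            raise ValueError("allele_class_mix must be 3 non-negative proportions")
        object.__setattr__(self, "allele_class_mix", mix)
        if self.mp_terms_per_line_mean <= 0:
            raise ValueError("mp_terms_per_line_mean must be positive")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from a flat ``key: value`` text file."""
        raw: Dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split(":", 1))
            raw[key] = value
        kwargs = {}
        valid = {f.name: f for f in fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config parameter {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key: str, value: str):
    if key in ("seed", "n_genes", "n_tissues"):
        return int(value)
    if key in ("exons_per_gene", "exon_length_range"):
        lo, hi = (int(v) for v in value.split(","))
        return (lo, hi)
    if key == "phase_pair_weights":
        if not value or value.lower() in ("none", "uniform"):
            return None
        return tuple(float(v) for v in value.split(","))
    if key == "allele_class_mix":
        return tuple(float(v) for v in value.split(","))
    return float(value)


@dataclass
class GeneModels:
    """Generated exon records plus the designated critical exon per gene."""

    exons: List[ExonRecord]
    critical_exon: Dict[str, str]  # gene_id -> exon_id
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "transcript_id": e.transcript_id,
                    "exon_id": e.exon_id,
                    "rank": e.rank,
                    "start_phase": e.start_phase,
                    "end_phase": e.end_phase,
                    "length_bp": e.length_bp,
                }
                for e in self.exons
            ],
            columns=[
                "gene_id", "transcript_id", "exon_id", "rank",
                "start_phase", "end_phase", "length_bp",
            ],
        )


def _quota_allocation(weights: Sequence[float], n: int) -> List[int]:
    """Largest-remainder allocation of ``n`` items over ``weights``.

    Deterministic: exact expected counts rounded down, leftovers to the
    largest fractional remainders (ties to the lower index).  Uniform
    weights with ``n`` divisible by the weight count give exact balance.
    """
    total = float(sum(weights))
    exact = [n * w / total for w in weights]
    counts = [int(np.floor(e)) for e in exact]
    leftover = n - sum(counts)
    remainders = sorted(
        range(len(weights)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:leftover]:
        counts[i] += 1
    return counts


def _length_with_residue(rng, lo: int, hi: int, residue: int) -> int:
    """Random length in [lo, hi] congruent to ``residue`` mod 3."""
    first = lo + ((residue - lo) % 3)
    n_choices = (hi - first) // 3 + 1
    if n_choices < 1:
        raise ValueError("exon_length_range too narrow for requested residue")
    return int(first + 3 * rng.integers(0, n_choices))


def generate_gene_models(config: SimulationConfig) -> GeneModels:
    """Generate one phase-consistent transcript per gene.

    The designated critical exon of each gene is internal (never first or
    last) and its phase pair follows ``phase_pair_weights`` by quota
    allocation; its length is chosen congruent to (end - start) mod 3, so
    critical-exon lengths are non-multiples of 3 except for same-phase
    pairs, mirroring the design preference for frameshift-on-deletion.
    First and last exon boundaries carry phase -1 (boundary in the UTR)
    with probability ``utr_flank_probability``.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.phase_pair_weights or tuple([1.0] * 9)
    counts = _quota_allocation(weights, config.n_genes)
    pair_pool = np.array(
        [pair for pair, c in zip(PHASE_PAIRS, counts) for _ in range(c)], dtype=int
    ).reshape(-1, 2)
    rng.shuffle(pair_pool)
    lo_n, hi_n = config.exons_per_gene
    lo_l, hi_l = config.exon_length_range
    exons: List[ExonRecord] = []
    critical: Dict[str, str] = {}
    width = max(5, len(str(max(config.n_genes, 1))))
    for g in range(config.n_genes):
        gene_id = f"GENE{g + 1:0{width}d}"
        tx_id = f"TX{g + 1:0{width}d}"
        ps, pe = (int(pair_pool[g][0]), int(pair_pool[g][1]))
        n_exons = int(rng.integers(lo_n, hi_n + 1))
        k = int(rng.integers(2, n_exons))  # critical exon rank, internal
        first_start = -1 if rng.random() < config.utr_flank_probability else 0
        last_end_utr = rng.random() < config.utr_flank_probability

        starts = [0] * (n_exons + 1)  # 1-based start phases
        ends = [0] * (n_exons + 1)
        lengths = [0] * (n_exons + 1)
        starts[1] = first_start
        # chain exon 1 .. k-1 so that exon k starts in phase ps
        for i in range(1, k):
            target = ps if i == k - 1 else None
            if i == 1 and starts[1] == -1:
                # boundary in the 5' UTR: end phase is free of the length
                lengths[1] = int(rng.integers(lo_l, hi_l + 1))
                ends[1] = target if target is not None else int(rng.integers(0, 3))
            else:
                base = 0 if starts[i] == -1 else starts[i]
                if target is None:
                    lengths[i] = int(rng.integers(lo_l, hi_l + 1))
                    ends[i] = (base + lengths[i]) % 3
                else:
                    lengths[i] = _length_with_residue(
                        rng, lo_l, hi_l, (target - base) % 3
                    )
                    ends[i] = target
            if i + 1 <= n_exons:
                starts[i + 1] = ends[i]
        # critical exon: phases fixed by the drawn pair
        starts[k] = ps
        lengths[k] = _length_with_residue(rng, lo_l, hi_l, (pe - ps) % 3)
        ends[k] = pe
        if k + 1 <= n_exons:
            starts[k + 1] = pe
        # downstream exons
        for i in range(k + 1, n_exons + 1):
            lengths[i] = int(rng.integers(lo_l, hi_l + 1))
            if i == n_exons and last_end_utr:
                ends[i] = -1
            else:
                ends[i] = (starts[i] + lengths[i]) % 3
            if i + 1 <= n_exons:
                starts[i + 1] = ends[i]
        for i in range(1, n_exons + 1):
            exon_id = f"EX{g + 1:0{width}d}.{i}"
            exons.append(
                ExonRecord(
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    exon_id=exon_id,
                    rank=i,
                    start_phase=starts[i],
                    end_phase=ends[i],
                    length_bp=lengths[i],
                )
            )
            if i == k:
                critical[gene_id] = exon_id
    return GeneModels(exons=exons, critical_exon=critical, config=config)


_CLASS_ORDER = (
    AlleleClass.KNOCKOUT_FIRST,
    AlleleClass.TARGETED_NONCOND,
    AlleleClass.LACZ_DELETION,
)
_CLASS_TM = {
    AlleleClass.KNOCKOUT_FIRST: "tm1a",
    AlleleClass.TARGETED_NONCOND: "tm1e",
    AlleleClass.LACZ_DELETION: "tm1b",
}


def generate_designs(
    config: SimulationConfig, gene_models: GeneModels
) -> Tuple[List[AlleleDesign], Dict[str, OutcomeCategory]]:
    """One design per gene targeting its designated critical exon, plus the
    ground-truth outcome category of every design.

    Allele classes follow ``allele_class_mix``; each design's true category
    is computed from its phase pair and default insertion mode with the
    cassette classifier, so round-trip tests can compare pipeline output
    against stored truth.  With ``second_design_fraction`` > 0, some genes
    get a second design on a different internal exon (used to exercise
    multi-category exclusion).  Genes too short to host an internal
    critical exon never occur by construction (minimum 3 exons).
    """
    rng = np.random.default_rng(config.seed + 1)
    mix = np.asarray(config.allele_class_mix, dtype=float)
    mix = mix / mix.sum()
    by_gene: Dict[str, List[ExonRecord]] = {}
    for e in gene_models.exons:
        by_gene.setdefault(e.gene_id, []).append(e)
    designs: List[AlleleDesign] = []
    truth: Dict[str, OutcomeCategory] = {}
    for gene_id in sorted(by_gene):
        gene_exons = sorted(by_gene[gene_id], key=lambda e: e.rank)
        targets = [gene_models.critical_exon[gene_id]]
        if rng.random() < config.second_design_fraction:
            internal = [
                e.exon_id
                for e in gene_exons[1:-1]
                if e.exon_id != targets[0]
            ]
            if internal:
                targets.append(str(rng.choice(internal)))
        for j, exon_id in enumerate(targets):
            cls = _CLASS_ORDER[int(rng.choice(3, p=mix))]
            design_id = f"D{gene_id[4:]}.{j + 1}"
            design = AlleleDesign(
                design_id=design_id,
                gene_id=gene_id,
                allele_class=cls,
                critical_exon_ids=(exon_id,),
                transcript_id=gene_exons[0].transcript_id,
            )
            designs.append(design)
            exon = next(e for e in gene_exons if e.exon_id == exon_id)
            mode = DEFAULT_MODE[cls]
            truth[design_id] = classify_design(
                PhasePair(exon.start_phase, exon.end_phase), mode, DEFAULT_CASSETTE
            )
    return designs, truth


def _truncated_poisson(rng, mean: float) -> int:
    """Poisson(mean) conditioned on being >= 1 (rejection sampling)."""
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def generate_phenotype_cohort(
    config: SimulationConfig, designs: Sequence[AlleleDesign]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype-hit and lacZ tables for the generated designs.

    One mouse line per design.  A gene is untested (no phenotype rows for
    any of its lines) with probability ``fraction_untested``.  A tested
    line has zero MP terms with probability ``no_phenotype_fraction``;
    otherwise its term count is Poisson(``mp_terms_per_line_mean``)
    truncated to >= 1.  A lethality term is present with marginal
    probability ``lethal_fraction`` per tested line (realised as
    ``lethal_fraction / (1 - no_phenotype_fraction)`` among phenotyped
    lines, since a zero-term line cannot carry one).  The lacZ table has
    ``n_tissues`` calls per gene; silent genes are all-negative, others
    are guaranteed at least one positive call.
    """
    rng = np.random.default_rng(config.seed + 2)
    p_lethal_given_pheno = (
        config.lethal_fraction / (1.0 - config.no_phenotype_fraction)
        if config.no_phenotype_fraction < 1.0
        else 0.0
    )
    pheno_rows = []
    untested_gene: Dict[str, bool] = {}
    for design in designs:
        untested = untested_gene.setdefault(
            design.gene_id, bool(rng.random() < config.fraction_untested)
        )
        if untested:
            continue
        line_id = f"COL_{design.design_id}"
        allele = f"{design.gene_id}<{_CLASS_TM[design.allele_class]}(EUCOMM)Syn>"
        base = {
            "gene_id": design.gene_id,
            "line_id": line_id,
            "allele_symbol": allele,
        }
        if rng.random() < config.no_phenotype_fraction:
            pheno_rows.append({**base, "mp_term_id": "", "mp_term_name": ""})
            continue
        n_terms = _truncated_poisson(rng, config.mp_terms_per_line_mean)
        lethal = rng.random() < p_lethal_given_pheno
        names: List[Tuple[str, str]] = []
        if lethal:
            names.append(tuple(LETHAL_MP_TERMS[int(rng.integers(len(LETHAL_MP_TERMS)))]))
        while len(names) < n_terms:
            names.append(tuple(NONLETHAL_MP_TERMS[int(rng.integers(len(NONLETHAL_MP_TERMS)))]))
        for i, (tid, tname) in enumerate(names):
            # synthetic unique id per line x slot; name carries the semantics
            pheno_rows.append(
                {**base, "mp_term_id": f"{tid}.{line_id}.{i}", "mp_term_name": tname}
            )
    pheno_df = pd.DataFrame(
        pheno_rows,
        columns=["gene_id", "line_id", "allele_symbol", "mp_term_id", "mp_term_name"],
    )

    lacz_rows = []
    tissues = [f"tissue_{i + 1:02d}" for i in range(config.n_tissues)]
    for gene_id in sorted({d.gene_id for d in designs}):
        silent = rng.random() < config.silent_gene_fraction
        calls = (
            np.zeros(config.n_tissues, dtype=bool)
            if silent
            else rng.random(config.n_tissues) < config.tissue_expression_probability
        )
        if not silent and not calls.any():
            calls[int(rng.integers(config.n_tissues))] = True
        for tissue, call in zip(tissues, calls):
            lacz_rows.append(
                {"gene_id": gene_id, "tissue": tissue, "expressed": bool(call)}
            )
    lacz_df = pd.DataFrame(lacz_rows, columns=["gene_id", "tissue", "expressed"])
    return pheno_df, lacz_df


def _write_with_seed_header(df: pd.DataFrame, path: Path, seed: int, sep: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_bundle(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Generate and write a complete synthetic bundle.

    Emits ``exons.tsv``, ``designs.csv``, ``phenotypes.csv``, ``lacz.csv``
    and ``ground_truth.csv`` in exactly the dialects the parsers consume,
    each with the seed recorded in a leading comment line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = generate_gene_models(config)
    designs, truth = generate_designs(config, models)
    pheno_df, lacz_df = generate_phenotype_cohort(config, designs)
    design_df = pd.DataFrame(
        [
            {
                "design_id": d.design_id,
                "gene_id": d.gene_id,
                "allele_class": _CLASS_TM[d.allele_class],
                "transcript_id": d.transcript_id,
                "critical_exon_ids": ";".join(d.critical_exon_ids),
            }
            for d in designs
        ],
        columns=["design_id", "gene_id", "allele_class", "transcript_id", "critical_exon_ids"],
    )
    truth_df = pd.DataFrame(
        [{"design_id": d, "category": c.name} for d, c in sorted(truth.items())],
        columns=["design_id", "category"],
    )
    paths = {
        "exons": outdir / "exons.tsv",
        "designs": outdir / "designs.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "lacz": outdir / "lacz.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    _write_with_seed_header(models.to_frame(), paths["exons"], config.seed, "\t")
    _write_with_seed_header(design_df, paths["designs"], config.seed, ",")
    _write_with_seed_header(pheno_df, paths["phenotypes"], config.seed, ",")
    _write_with_seed_header(lacz_df, paths["lacz"], config.seed, ",")
    _write_with_seed_header(truth_df, paths["ground_truth"], config.seed, ",")
    return paths
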