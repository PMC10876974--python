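"""Synthetic fixtures with ground truth.

Everything the pipeline consumes can be generated here under a single seed:
a small taxonomy, species genomes at controlled divergence, long-read
samples (Kraken-style assignments plus PAF alignments) with a controllable
misassignment rate, short-read allele counts at chosen coverage and error
rate, mock communities with known composition, and leave-one-out
false-positive benchmarks with precision/recall evaluation.

The emitted alignments always reflect each read's TRUE source genome as
present in the emitted reference database.  A read whose *assignment* was
corrupted (misassignment, or a database species dropped in a leave-one-out
run) therefore has no useful alignment against its claimed taxon, which is
exactly the failure mode the mapping-based validation step is built to
catch.

Error model: uniform base substitutions, no indels — identity arithmetic
stays exact, which is what the 70/70 boundary tests need.  Long-read
lengths are log-normal with a configurable median (default 653 bp, a
realistic gut-metagenome Nanopore median).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignments import AlignmentRecord
from .strain import AlleleCounts
from .taxonomy import ReadAssignment, TaxonomyNode, TaxonomyTree
from .validation import ValidationConfig, ValidationResult, validate_sample

__all__ = [
    "SynthConfig",
    "CommunityFixture",
    "DetectionMetrics",
    "make_taxonomy",
    "make_genomes",
    "simulate_long_read_sample",
    "simulate_allele_counts",
    "make_mock_community",
    "leave_one_out_benchmark",
    "evaluate_detection",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator.

    Defaults: 653 bp median log-normal long reads with 5% substitution
    error, 100 kb genomes, no misassignment, 2 x 100 bp short-read model
    for allele counts.  ``n_decoy_species`` are species present in the
    taxonomy and reference database but absent from the community — the
    natural landing spots for misassigned reads, mirroring how a k-mer
    classifier confuses out-of-database reads with close relatives.
    """

    seed: int = 0
    n_species: int = 6
    n_decoy_species: int = 2
    genome_length: int = 100_000
    divergence: float = 0.0          # database-vs-sample strain divergence
    read_median_bp: int = 653
    read_sigma: float = 0.5          # log-normal shape of read lengths
    long_read_error: float = 0.05
    misassignment_rate: float = 0.0
    n_reads: int = 5_000
    short_read_length: int = 100     # one mate of the 2 x 100 bp pair
    short_read_error: float = 0.001
    composition: tuple[float, ...] | None = None

    def __post_init__(self):
        for name in (
            "divergence",
            "long_read_error",
            "misassignment_rate",
            "short_read_error",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.composition is not None:
            if len(self.composition) != self.n_species:
                raise ValueError("composition length must equal n_species")
            if abs(sum(self.composition) - 1) > 1e-9:
                raise ValueError("composition must sum to 1")


def make_taxonomy(n_species: int, *, n_genera: int | None = None) -> TaxonomyTree:
    """Minimal bacterial taxonomy: root → Bacteria → genera → species.

    Species taxids start at 1000, genus taxids at 100.  Domain-label clade
    roots reuse the standard NCBI ids so the default DomainConfig applies.
    """
    if n_genera is None:
        n_genera = max(1, n_species // 2)
    nodes = [
        TaxonomyNode(1, 1, "no rank", "root"),
        TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
    ]
    for g in range(n_genera):
        nodes.append(TaxonomyNode(100 + g, 2, "genus", f"Genus_{g}"))
    for s in range(n_species):
        genus = 100 + s % n_genera
        nodes.append(
            TaxonomyNode(1000 + s, genus, "species", f"Species_{s}")
        )
    return TaxonomyTree(nodes)


def species_taxid(index: int) -> int:
    return 1000 + index


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(
    rng: np.random.Generator, genome: np.ndarray, rate: float
) -> tuple[np.ndarray, int]:
    """Substitute each base independently with probability ``rate``.

    Substituted bases always change (shift by 1–3 mod 4), so the realized
    divergence equals the number of touched positions.
    """
    out = genome.copy()
    hits = np.flatnonzero(rng.random(genome.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size, dtype=np.int8)
        out[hits] = (out[hits] + shift) % 4
    return out, int(hits.size)


def genome_to_str(genome: np.ndarray) -> str:
    return _BASES[genome].tobytes().decode()


def make_genomes(
    cfg: SynthConfig,
) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """Independent random genomes per species, plus a database copy each.

    Returns (genomes, true_ani) where ``genomes`` maps species taxid to the
    *sample* strain genome and ``true_ani`` to the ANI between the sample
    strain and the database strain (1.0 at divergence 0).  The database
    strains are derived by mutating at ``cfg.divergence``.  Genomes are
    generated for community and decoy species alike.
    """
    if cfg.divergence > 0.5:
        raise ValueError("divergence above 0.5 is not meaningful")
    rng = np.random.default_rng(cfg.seed)
    genomes: dict[int, np.ndarray] = {}
    true_ani: dict[int, float] = {}
    for s in range(cfg.n_species + cfg.n_decoy_species):
        taxid = species_taxid(s)
        base = _random_genome(rng, cfg.genome_length)
        _, n_sub = _mutate(rng, base, cfg.divergence)
        genomes[taxid] = base
        true_ani[taxid] = 1.0 - n_sub / cfg.genome_length
    return genomes, true_ani


def write_fasta(genomes: Mapping[int | str, np.ndarray], path: str | Path) -> None:
    """Write genomes as FASTA via Biopython (ids: ``g<taxid>`` or given)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(genome_to_str(g)),
            id=str(k) if isinstance(k, str) else f"g{k}",
            description="",
        )
        for k, g in genomes.items()
    ]
    seqio_write(records, str(path), "fasta")


@dataclass
class LongReadSample:
    """One simulated long-read sample plus its ground truth."""

    assignments: list[ReadAssignment]
    alignments: dict[str, list[AlignmentRecord]]
    target_taxids: dict[str, int]
    true_taxon: dict[str, int]   # read id -> true source species
    composition: dict[int, float]


def _draw_lengths(
    rng: np.random.Generator, cfg: SynthConfig, n: int
) -> np.ndarray:
    lengths = rng.lognormal(
        mean=np.log(cfg.read_median_bp), sigma=cfg.read_sigma, size=n
    )
    return np.clip(lengths.astype(int), 100, cfg.genome_length)


def simulate_long_read_sample(
    genomes: Mapping[int, np.ndarray],
    cfg: SynthConfig,
    *,
    database_taxa: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> LongReadSample:
    """Simulate a classified long-read sample with PAF-style alignments.

    Reads are drawn from the composition over ``genomes``.  With
    probability ``misassignment_rate`` a read's *emitted assignment* is
    relabeled to a uniformly random other species; its alignment still
    points at its true source.  Species absent from ``database_taxa``
    (default: all) produce no alignments at all — their reads are
    out-of-database.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    taxa = sorted(genomes)
    community = [t for t in taxa if t < species_taxid(cfg.n_species)]
    probs = np.zeros(len(taxa))
    if cfg.composition is not None:
        if len(cfg.composition) != len(community):
            raise ValueError(
                "composition length must match community species count"
            )
        for t, f in zip(community, cfg.composition):
            probs[taxa.index(t)] = f
    else:
        for t in community:
            probs[taxa.index(t)] = 1 / len(community)
    database = set(taxa if database_taxa is None else database_taxa)
    target_taxids = {f"g{t}": t for t in database}

    sources = rng.choice(len(taxa), size=cfg.n_reads, p=probs)
    lengths = _draw_lengths(rng, cfg, cfg.n_reads)
    misassigned = rng.random(cfg.n_reads) < cfg.misassignment_rate

    assignments: list[ReadAssignment] = []
    alignments: dict[str, list[AlignmentRecord]] = {}
    true_taxon: dict[str, int] = {}
    for i in range(cfg.n_reads):
        read_id = f"r{i}"
        true_tax = taxa[sources[i]]
        length = int(lengths[i])
        true_taxon[read_id] = true_tax
        claimed = true_tax
        if misassigned[i] and len(taxa) > 1:
            others = [t for t in taxa if t != true_tax]
            claimed = others[rng.integers(len(others))]
        assignments.append(
            ReadAssignment(
                read_id=read_id,
                classified=True,
                taxid=claimed,
                read_length=length,
            )
        )
        if true_tax in database:
            # Sequencing error + strain-vs-database divergence both reduce
            # identity; mismatches are binomial over the read length.
            err = cfg.long_read_error
            div = cfg.divergence
            p_mismatch = err + div - err * div
            mismatches = int(rng.binomial(length, p_mismatch))
            alignments[read_id] = [
                AlignmentRecord(
                    query_id=read_id,
                    query_length=length,
                    query_start=0,
                    query_end=length,
                    target_id=f"g{true_tax}",
                    matches=length - mismatches,
                    block_length=length,
                    mapq=60,
                    is_primary=True,
                )
            ]
    return LongReadSample(
        assignments=assignments,
        alignments=alignments,
        target_taxids=target_taxids,
        true_taxon=true_taxon,
        composition={taxa[i]: float(probs[i]) for i in range(len(taxa))},
    )


def simulate_allele_counts(
    genome: np.ndarray,
    coverage: float,
    error_rate: float,
    *,
    sample_id: str = "synthetic",
    contig: str = "core_0",
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> AlleleCounts:
    """Allele counts for one sample: Poisson depth, uniform substitutions.

    Stands in for a 2 x 100 bp paired-end pileup: per-position depth is
    Poisson(coverage) and each observed base is the true base with
    probability 1 − error_rate, else uniform over the other three.  The
    pileup, not the reads, is the contract of the strain module.
    """
    rng = rng or np.random.default_rng(seed)
    length = genome.size
    depth = rng.poisson(coverage, size=length)
    errors = rng.binomial(depth, error_rate)
    correct = depth - errors
    counts = np.zeros((length, 4), dtype=np.int64)
    counts[np.arange(length), genome] = correct
    if errors.any():
        # Distribute error reads uniformly over the three other bases.
        e1 = rng.binomial(errors, 1 / 3)
        e2 = rng.binomial(errors - e1, 1 / 2)
        e3 = errors - e1 - e2
        for k, e in enumerate((e1, e2, e3)):
            counts[np.arange(length), (genome + 1 + k) % 4] += e
    return AlleleCounts(sample_id, {contig: counts})


@dataclass
class CommunityFixture:
    """A mock community: taxonomy, genomes, one long-read sample, truth."""

    tree: TaxonomyTree
    genomes: dict[int, np.ndarray]
    sample: LongReadSample
    cfg: SynthConfig

    @property
    def true_composition(self) -> dict[int, float]:
        return self.sample.composition


def make_mock_community(cfg: SynthConfig) -> CommunityFixture:
    """Generate a complete mock community under one seed."""
    if cfg.n_species < 2:
        raise ValueError("a community needs at least 2 species")
    rng = np.random.default_rng(cfg.seed)
    genomes, _ = make_genomes(cfg)
    sample = simulate_long_read_sample(genomes, cfg, rng=rng)
    return CommunityFixture(
        tree=make_taxonomy(cfg.n_species + cfg.n_decoy_species),
        genomes=genomes,
        sample=sample,
        cfg=cfg,
    )


@dataclass(frozen=True)
class DetectionMetrics:
    """Taxon- and read-level precision/recall of validation output."""

    taxon_precision: float
    taxon_recall: float
    read_precision: float
    read_recall: float
    fp_taxa_total: int
    fp_taxa_rejected: int
    true_taxa_total: int
    true_taxa_rejected: int

    @property
    def filter_fp_taxon_recall(self) -> float:
        """Fraction of false-positive taxa the filter rejected."""
        if self.fp_taxa_total == 0:
            return 1.0
        return self.fp_taxa_rejected / self.fp_taxa_total

    @property
    def filter_precision(self) -> float:
        """Fraction of filter rejections that hit false-positive taxa."""
        rejected = self.fp_taxa_rejected + self.true_taxa_rejected
        if rejected == 0:
            return 1.0
        return self.fp_taxa_rejected / rejected


def evaluate_detection(
    fixture: CommunityFixture,
    results: Sequence[ValidationResult],
    *,
    min_reads: int = 5,
) -> DetectionMetrics:
    """Score species-level validation output against the fixture truth.

    True species are those actually present in the community; a species
    counts as detected when >= ``min_reads`` reads were assigned to it.
    Read-level scores compare each read's claimed species (if validated)
    with its true source.
    """
    truth = {
        t for t, f in fixture.true_composition.items() if f > 0
    }
    species_results = [
        r
        for r in results
        if r.rank == "species" and r.n_assigned >= min_reads
    ]
    validated = {r.taxid for r in species_results if r.validated}
    rejected = {r.taxid for r in species_results if not r.validated}
    tp = len(validated & truth)
    fp = len(validated - truth)
    fn = len(truth & rejected)
    taxon_precision = tp / (tp + fp) if (tp + fp) else 1.0
    taxon_recall = tp / len(truth) if truth else 1.0

    read_tp = read_fp = read_fn = 0
    for a in fixture.sample.assignments:
        if not a.classified:
            continue
        correct = fixture.sample.true_taxon[a.read_id] == a.taxid
        if a.taxid in validated:
            if correct:
                read_tp += 1
            else:
                read_fp += 1
        elif correct:
            read_fn += 1  # discarding a misassigned read is not an error
    read_precision = (
        read_tp / (read_tp + read_fp) if (read_tp + read_fp) else 1.0
    )
    read_recall = (
        read_tp / (read_tp + read_fn) if (read_tp + read_fn) else 1.0
    )
    fp_taxa = {r.taxid for r in species_results} - truth
    return DetectionMetrics(
        taxon_precision=taxon_precision,
        taxon_recall=taxon_recall,
        read_precision=read_precision,
        read_recall=read_recall,
        fp_taxa_total=len(fp_taxa),
        fp_taxa_rejected=len(fp_taxa & rejected),
        true_taxa_total=len(truth),
        true_taxa_rejected=len(truth & rejected),
    )


@dataclass
class LeaveOneOutReport:
    dropped: int
    results: list[ValidationResult]
    metrics: DetectionMetrics


def leave_one_out_benchmark(
    cfg: SynthConfig,
    drop_index: int,
    *,
    validation: ValidationConfig | None = None,
    confusion: str = "decoy",
) -> LeaveOneOutReport:
    """Drop one species from the database and measure the filter.

    The dropped species' reads are re-labeled onto database species (the
    classifier must put them somewhere) while its genome is removed from
    the alignment database, so those reads carry no alignment evidence for
    their claimed taxon.  With ``confusion="decoy"`` (default) the reads
    land on decoy species — close relatives present in the database but
    absent from the community, which thereby become planted false-positive
    taxon calls; ``confusion="uniform"`` spreads them over all remaining
    database species instead.  Validation then runs as usual and is scored
    against ground truth.
    """
    if not 0 <= drop_index < cfg.n_species:
        raise ValueError("drop_index out of range")
    if cfg.n_species < 2:
        raise ValueError("cannot drop a species from a 1-species community")
    dropped = species_taxid(drop_index)
    rng = np.random.default_rng(cfg.seed)
    genomes, _ = make_genomes(cfg)
    database = [t for t in sorted(genomes) if t != dropped]
    if confusion == "decoy" and cfg.n_decoy_species > 0:
        recipients = [
            t for t in database if t >= species_taxid(cfg.n_species)
        ]
    elif confusion in ("decoy", "uniform"):
        recipients = database
    else:
        raise ValueError(f"unknown confusion model {confusion!r}")
    sample = simulate_long_read_sample(
        genomes, cfg, database_taxa=database, rng=rng
    )
    # Reassign reads claimed for the dropped (now out-of-database) species.
    relabeled = []
    for a in sample.assignments:
        if a.taxid == dropped:
            a = replace(
                a, taxid=recipients[rng.integers(len(recipients))]
            )
        relabeled.append(a)
    sample.assignments = relabeled

    vcfg = validation or ValidationConfig(seed=cfg.seed)
    tree = make_taxonomy(cfg.n_species + cfg.n_decoy_species)
    results = validate_sample(
        tree,
        sample.assignments,
        sample.alignments,
        vcfg,
        ranks=("species",),
        target_taxids=sample.target_taxids,
    )
    # Truth for scoring: the dropped species cannot be detected, and reads
    # re-labeled onto other species are misassignments by construction.
    fixture = CommunityFixture(
        tree=tree, genomes=genomes, sample=sample, cfg=cfg
    )
    fixture.sample.composition = {
        t: (f if t != dropped else 0.0)
        for t, f in sample.composition.items()
    }
    metrics = evaluate_detection(fixture, results)
    return LeaveOneOutReport(dropped=dropped, results=results, metrics=metrics)
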