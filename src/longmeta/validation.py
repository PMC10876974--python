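"""Mapping-based validation of k-mer taxonomic assignments.

A k-mer classifier (Kraken2-style) is sensitive but produces false-positive
taxon calls, especially for reads from genomes absent from its database.
The second step implemented here confirms each detected taxon by mapping its
reads back against that taxon's own reference genomes:

* a read is *mapping-validated* for node *n* if at least 70% of the read is
  covered by the union of its alignments (identity >= 70%) against the
  concatenated references of *n* and its descendants;
* a taxon is *validated* in a sample if at least 20% of the sample reads
  assigned to it achieve mapping-based validation.

For efficiency, validation runs on a seeded random subsample of 100,000
reads per sample (or the full sample when smaller).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import AlignmentRecord, alignment_identity
from .taxonomy import ReadAssignment, TaxonomyTree

__all__ = [
    "ValidationConfig",
    "ValidationResult",
    "subsample_assignments",
    "read_validated",
    "covered_query_length",
    "validate_taxon",
    "validate_sample",
    "results_to_frame",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Thresholds of the two-step validation rule.

    Defaults are the 70/70 read rule, the >=20% per-taxon rule and the
    100,000-read subsample.
    """

    min_read_coverage: float = 0.70
    min_identity: float = 0.70
    min_taxon_rate: float = 0.20
    subsample_size: int = 100_000
    seed: int = 0

    def __post_init__(self):
        for name in ("min_read_coverage", "min_identity", "min_taxon_rate"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.subsample_size < 1:
            raise ValueError("subsample_size must be >= 1")


@dataclass(frozen=True)
class ValidationResult:
    """Per-taxon, per-sample validation outcome."""

    taxid: int
    name: str
    rank: str
    n_assigned: int
    n_sampled: int
    n_validated: int
    rate: float
    validated: bool
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.n_validated <= self.n_sampled <= self.n_assigned):
            raise ValueError(
                f"taxid {self.taxid}: inconsistent counts "
                f"{self.n_validated}/{self.n_sampled}/{self.n_assigned}"
            )


def subsample_assignments(
    assignments: Sequence[ReadAssignment], config: ValidationConfig
) -> list[ReadAssignment]:
    """Uniform sample without replacement of min(n, subsample_size) reads.

    Deterministic given ``config.seed``; order of the retained reads follows
    the input order.
    """
    n = len(assignments)
    if n <= config.subsample_size:
        return list(assignments)
    rng = np.random.default_rng(config.seed)
    keep = rng.choice(n, size=config.subsample_size, replace=False)
    keep.sort()
    return [assignments[i] for i in keep]


def covered_query_length(
    alignments: Iterable[AlignmentRecord], min_identity: float
) -> int:
    """Total length of the union of query intervals with passing identity.

    Overlapping alignments are merged so that no read base counts twice.
    """
    spans = sorted(
        (a.query_start, a.query_end)
        for a in alignments
        if alignment_identity(a) >= min_identity
    )
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in spans:
        if cur_start is None or start > cur_end:
            if cur_start is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def read_validated(
    read_length: int,
    alignments: Iterable[AlignmentRecord],
    config: ValidationConfig,
) -> bool:
    """70/70 rule for one read against one node's concatenated reference.

    All alignments of the read (primary, secondary, supplementary) count;
    their query intervals are unioned.  A read with no passing alignments is
    simply not validated.
    """
    covered = covered_query_length(alignments, config.min_identity)
    return covered >= config.min_read_coverage * read_length


def _reads_for_node(
    tree: TaxonomyTree,
    taxid: int,
    assignments: Iterable[ReadAssignment],
) -> list[ReadAssignment]:
    clade = tree.descendants(taxid)
    return [a for a in assignments if a.classified and a.taxid in clade]


def validate_taxon(
    tree: TaxonomyTree,
    taxid: int,
    sampled_assignments: Sequence[ReadAssignment],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    config: ValidationConfig,
    *,
    target_taxids: Mapping[str, int] | None = None,
    n_assigned: int | None = None,
) -> ValidationResult:
    """Validate one taxon from subsampled reads and their alignments.

    ``alignments`` maps read id -> alignment records.  When
    ``target_taxids`` is given (target sequence id -> species taxid, the
    reference manifest), only alignments against references within the
    node's clade contribute — this reproduces mapping against the node's
    concatenated reference from a combined alignment file.
    """
    node = tree.node(taxid)
    reads = _reads_for_node(tree, taxid, sampled_assignments)
    n_sampled = len(reads)
    flags: list[str] = []
    if n_assigned is None:
        n_assigned = n_sampled
    if n_sampled == 0:
        return ValidationResult(
            taxid=taxid,
            name=node.name,
            rank=node.rank,
            n_assigned=n_assigned,
            n_sampled=0,
            n_validated=0,
            rate=0.0,
            validated=False,
            flags=("no-sampled-reads",),
        )
    clade = tree.descendants(taxid)
    n_validated = 0
    any_alignment = False
    for read in reads:
        alns = alignments.get(read.read_id, ())
        if target_taxids is not None:
            alns = [
                a
                for a in alns
                if target_taxids.get(a.target_id) in clade
            ]
        if alns:
            any_alignment = True
        if read_validated(read.read_length, alns, config):
            n_validated += 1
    if not any_alignment:
        flags.append("no-alignment-data")
    rate = n_validated / n_sampled
    return ValidationResult(
        taxid=taxid,
        name=node.name,
        rank=node.rank,
        n_assigned=n_assigned,
        n_sampled=n_sampled,
        n_validated=n_validated,
        rate=rate,
        validated=rate >= config.min_taxon_rate,
        flags=tuple(flags),
    )


def validate_sample(
    tree: TaxonomyTree,
    assignments: Sequence[ReadAssignment],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
    config: ValidationConfig,
    *,
    ranks: tuple[str, ...] = ("species", "genus"),
    target_taxids: Mapping[str, int] | None = None,
) -> list[ValidationResult]:
    """Two-step validation of every taxon detected in a sample.

    Detected taxa are the nodes at each requested rank with at least one
    classified read assigned to them or their descendants.  Genus-level
    validation is independent: it pools the reads of all species under the
    genus against the pooled reference set.
    """
    sampled = subsample_assignments(assignments, config)

    # Count full-sample assignments per clade for n_assigned bookkeeping.
    full_counts: dict[int, int] = {}
    sampled_counts: dict[int, int] = {}
    for a in assignments:
        if a.classified:
            full_counts[a.taxid] = full_counts.get(a.taxid, 0) + 1
    for a in sampled:
        if a.classified:
            sampled_counts[a.taxid] = sampled_counts.get(a.taxid, 0) + 1

    results = []
    for rank in ranks:
        for taxid in sorted(tree.nodes_at_rank(rank)):
            clade = tree.descendants(taxid)
            n_assigned = sum(full_counts.get(t, 0) for t in clade)
            if n_assigned == 0:
                continue
            if sum(sampled_counts.get(t, 0) for t in clade) == 0:
                # Detected in the full sample but absent from the subsample.
                node = tree.node(taxid)
                results.append(
                    ValidationResult(
                        taxid=taxid,
                        name=node.name,
                        rank=node.rank,
                        n_assigned=n_assigned,
                        n_sampled=0,
                        n_validated=0,
                        rate=0.0,
                        validated=False,
                        flags=("no-sampled-reads",),
                    )
                )
                continue
            results.append(
                validate_taxon(
                    tree,
                    taxid,
                    sampled,
                    alignments,
                    config,
                    target_taxids=target_taxids,
                    n_assigned=n_assigned,
                )
            )
    return results


def results_to_frame(results: Iterable[ValidationResult]):
    """Validation results as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "taxid": r.taxid,
                "name": r.name,
                "rank": r.rank,
                "n_assigned": r.n_assigned,
                "n_sampled": r.n_sampled,
                "n_validated": r.n_validated,
                "rate": r.rate,
                "validated": r.validated,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
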