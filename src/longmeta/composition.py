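"""Filtered compositional profiles.

Species tables pool low-evidence mass explicitly instead of dropping it:
species with fewer than 5 assigned reads go into a "not enough reads"
category, species that failed mapping-based validation into "not validated",
and reads classified above species rank into "unresolved-rank".  Whole-sample
domain profiles and longitudinal marker tracks (with exact binomial
confidence intervals) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stats import binomial_ci
from .taxonomy import (
    DomainConfig,
    DomainLabel,
    ReadAssignment,
    TaxonomyTree,
)
from .validation import ValidationResult

__all__ = [
    "NOT_ENOUGH_READS",
    "NOT_VALIDATED",
    "UNRESOLVED_RANK",
    "MarkerTrack",
    "build_species_table",
    "domain_fractions",
    "select_top_species",
    "track_markers",
]

NOT_ENOUGH_READS = "not_enough_reads"
NOT_VALIDATED = "not_validated"
UNRESOLVED_RANK = "unresolved_rank"
SPECIAL_COLUMNS = (NOT_ENOUGH_READS, NOT_VALIDATED, UNRESOLVED_RANK)


def _species_read_counts(
    assignments: Iterable[ReadAssignment],
    tree: TaxonomyTree,
    *,
    exclude_domains: frozenset[DomainLabel],
    domain_config: DomainConfig | None,
) -> tuple[dict[int, int], int, int]:
    """Per-species clade read counts plus (denominator, unresolved count).

    A read counts toward the species that is its assigned node's nearest
    ancestor (or self) at species rank; reads classified above species rank
    are "unresolved".  Reads in excluded domains (human, plant by default)
    do not enter the denominator.
    """
    species_counts: dict[int, int] = {}
    unresolved = 0
    denominator = 0
    for a in assignments:
        if not a.classified:
            continue
        label = tree.classify_domain(a.taxid, domain_config)
        if label in exclude_domains:
            continue
        denominator += 1
        sp = tree.ancestor_at_rank(a.taxid, "species")
        if sp is None:
            unresolved += 1
        else:
            species_counts[sp] = species_counts.get(sp, 0) + 1
    return species_counts, denominator, unresolved


def build_species_table(
    assignments_by_sample: Mapping[str, Sequence[ReadAssignment]],
    validation_by_sample: Mapping[str, Sequence[ValidationResult]],
    tree: TaxonomyTree,
    *,
    min_reads: int = 5,
    exclude_domains: Iterable[DomainLabel] = (
        DomainLabel.HUMAN,
        DomainLabel.PLANT,
        DomainLabel.UNCLASSIFIED,
    ),
    domain_config: DomainConfig | None = None,
) -> pd.DataFrame:
    """Filtered per-sample species relative abundances.

    Rows are samples; columns are species taxids plus the three pooled
    categories.  Per sample: species with fewer than ``min_reads`` assigned
    reads are pooled into ``not_enough_reads``; species at or above
    ``min_reads`` that failed mapping-based validation into
    ``not_validated``; remaining species are reported individually.  Rows
    sum to 1 exactly (denominator = classified reads outside the excluded
    domains).

    Raises if a species with >= ``min_reads`` reads has no validation
    record — silent validation is never assumed.
    """
    exclude = frozenset(exclude_domains)
    rows: dict[str, dict] = {}
    for sample, assignments in assignments_by_sample.items():
        counts, denom, unresolved = _species_read_counts(
            assignments,
            tree,
            exclude_domains=exclude,
            domain_config=domain_config,
        )
        validated = {
            r.taxid: r.validated
            for r in validation_by_sample.get(sample, ())
            if r.rank == "species"
        }
        row: dict = {c: 0.0 for c in SPECIAL_COLUMNS}
        row["total_reads"] = denom
        if denom == 0:
            rows[sample] = row
            continue
        row[UNRESOLVED_RANK] = unresolved / denom
        for sp, n in counts.items():
            frac = n / denom
            if n < min_reads:
                row[NOT_ENOUGH_READS] += frac
            elif sp not in validated:
                raise ValueError(
                    f"sample {sample}: species taxid {sp} has {n} reads "
                    "but no validation record"
                )
            elif not validated[sp]:
                row[NOT_VALIDATED] += frac
            else:
                row[sp] = frac
        rows[sample] = row
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table.index.name = "sample_id"
    meta = table.pop("total_reads")
    species_cols = sorted(
        c for c in table.columns if c not in SPECIAL_COLUMNS
    )
    table = table[species_cols + list(SPECIAL_COLUMNS)]
    table["total_reads"] = meta.astype(int)
    return table


def abundance_vectors(table: pd.DataFrame) -> pd.DataFrame:
    """Validated-species fractions renormalized to sum 1 per sample.

    This is the post-filtering compositional estimate used for dissimilarity
    analysis; pooled categories and read totals are dropped.
    """
    cols = [
        c
        for c in table.columns
        if c not in SPECIAL_COLUMNS and c != "total_reads"
    ]
    vec = table[cols].astype(float)
    sums = vec.sum(axis=1)
    if (sums == 0).any():
        empty = list(vec.index[sums == 0])
        raise ValueError(f"samples with no validated species: {empty}")
    return vec.div(sums, axis=0)


def domain_fractions(
    assignments: Sequence[ReadAssignment],
    tree: TaxonomyTree,
    domain_config: DomainConfig | None = None,
) -> dict[DomainLabel, float]:
    """Read-count fraction per domain label over ALL reads.

    Unclassified reads are included, so the fractions always sum to 1.
    """
    if not assignments:
        raise ValueError("no reads")
    counts = {label: 0 for label in DomainLabel}
    for a in assignments:
        counts[tree.classify_domain(a.taxid, domain_config)] += 1
    total = len(assignments)
    return {label: n / total for label, n in counts.items()}


def select_top_species(table: pd.DataFrame, n: int = 30) -> list[int]:
    """Species ranked by summed relative frequency across all samples.

    Ties break toward the smaller taxid; at most ``n`` species returned.
    """
    cols = [
        c
        for c in table.columns
        if c not in SPECIAL_COLUMNS and c != "total_reads"
    ]
    sums = table[cols].sum(axis=0)
    ranked = sorted(cols, key=lambda c: (-sums[c], int(c)))
    return [int(c) for c in ranked[:n]]


@dataclass(frozen=True)
class MarkerTrack:
    """Longitudinal abundance of one marker taxon in one sample."""

    taxid: int
    name: str
    sample_id: str
    timepoint: str
    marker_reads: int
    total_reads: int
    fraction: float
    ci_low: float
    ci_high: float


def track_markers(
    assignments_by_sample: Mapping[str, Sequence[ReadAssignment]],
    tree: TaxonomyTree,
    markers: Sequence[int | str],
    timepoints: Mapping[str, str] | None = None,
    *,
    level: float = 0.95,
) -> list[MarkerTrack]:
    """Marker-taxon fractions per sample with exact binomial CIs.

    Markers may be taxids or scientific names; the fraction denominator is
    all classified reads of the sample.  Unresolvable markers raise, listing
    every offender.
    """
    name_index = {tree.name(t): t for t in tree if tree.name(t)}
    resolved: list[int] = []
    missing: list[str] = []
    for m in markers:
        if isinstance(m, int):
            if m in tree:
                resolved.append(m)
            else:
                missing.append(str(m))
        elif m in name_index:
            resolved.append(name_index[m])
        else:
            missing.append(m)
    if missing:
        raise ValueError(f"unresolved marker taxa: {missing}")

    tracks = []
    for sample, assignments in assignments_by_sample.items():
        classified = [a for a in assignments if a.classified]
        total = len(classified)
        if total == 0:
            continue
        for taxid in resolved:
            clade = tree.descendants(taxid)
            k = sum(1 for a in classified if a.taxid in clade)
            low, high = binomial_ci(k, total, level)
            tracks.append(
                MarkerTrack(
                    taxid=taxid,
                    name=tree.name(taxid),
                    sample_id=sample,
                    timepoint=(timepoints or {}).get(sample, ""),
                    marker_reads=k,
                    total_reads=total,
                    fraction=k / total,
                    ci_low=low,
                    ci_high=high,
                )
            )
    return tracks


def tracks_to_frame(tracks: Iterable[MarkerTrack]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tracks])
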