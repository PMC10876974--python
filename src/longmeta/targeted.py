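"""Rule-based quantification against special-purpose reference sets.

Two independent screens applied to *all* reads of a sample, regardless of
classification outcome:

* antibiotic-resistance genes — a read carries an ARG if it aligns to the
  ARG sequence with block length >= 500 bp and fewer than 50 undefined 'N'
  characters in the aligned segment; sample burden is reported as
  ARG-carrying reads per 10,000 sample reads;
* crAssphage — a read counts toward crAssphage abundance if its primary
  alignment to the strain reference set reaches 70% query cover at 70%
  identity, and is assignable to an individual strain when that alignment
  has mapping quality >= 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .alignments import AlignmentRecord, alignment_identity, query_cover

__all__ = [
    "ArgCount",
    "CrassResult",
    "count_arg_reads",
    "crassphage_abundance",
    "crassphage_strain_counts",
    "crassphage_profile",
]


@dataclass(frozen=True)
class ArgCount:
    """ARG read counts and the per-10,000-read burden of a sample."""

    per_arg: dict[str, int]
    carrying_reads: int
    total_reads: int
    rate_per_10k: float


def count_arg_reads(
    alignments: Iterable[AlignmentRecord],
    total_reads: int,
    *,
    min_length: int = 500,
    max_n: int = 50,
) -> ArgCount:
    """Count ARG-carrying reads by the >=500 bp / <50 N alignment rule.

    A read appears in the tally of every distinct ARG it matches, but counts
    once toward the carrying-read rate.  Alignments lacking N information
    are treated as N-free (warned upstream at parse time if applicable).
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    hits: set[tuple[str, str]] = set()
    for a in alignments:
        if a.block_length >= min_length and a.query_n_count < max_n:
            hits.add((a.query_id, a.target_id))
    per_arg: dict[str, int] = {}
    reads: set[str] = set()
    for read_id, arg_id in hits:
        per_arg[arg_id] = per_arg.get(arg_id, 0) + 1
        reads.add(read_id)
    carrying = len(reads)
    if carrying > total_reads:
        raise ValueError("more ARG-carrying reads than total reads")
    return ArgCount(
        per_arg=dict(sorted(per_arg.items())),
        carrying_reads=carrying,
        total_reads=total_reads,
        rate_per_10k=10_000 * carrying / total_reads,
    )


@dataclass(frozen=True)
class CrassResult:
    """crAssphage abundance and strain-level assignment of a sample."""

    abundance: float
    crass_reads: int
    total_reads: int
    per_strain: dict[str, int]
    assignable_fraction: float


def crassphage_abundance(
    alignments: Iterable[AlignmentRecord],
    total_reads: int,
    *,
    min_query_cover: float = 0.70,
    min_identity: float = 0.70,
) -> tuple[float, set[str]]:
    """Fraction of sample reads with a passing primary crAssphage alignment.

    Query cover is computed per primary alignment (no interval union — a
    single alignment must cover 70% of the read at 70% identity).  Returns
    the abundance estimate and the passing read ids.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    passing: set[str] = set()
    for a in alignments:
        if (
            a.is_primary
            and query_cover(a) >= min_query_cover
            and alignment_identity(a) >= min_identity
        ):
            passing.add(a.query_id)
    return len(passing) / total_reads, passing


def crassphage_strain_counts(
    alignments: Iterable[AlignmentRecord],
    *,
    min_mapq: int = 5,
    eligible_reads: set[str] | None = None,
) -> tuple[dict[str, int], float]:
    """Per-strain read counts after mapping-quality filtering.

    Only primary alignments with MQ >= ``min_mapq`` assign a read to a
    strain (the target sequence id).  The assignable fraction is computed
    over ``eligible_reads`` when given (e.g. the abundance-qualifying
    reads), else over all primarily-aligned reads in the input.
    """
    assigned: dict[str, str] = {}
    seen: set[str] = set()
    for a in alignments:
        if not a.is_primary:
            continue
        if eligible_reads is not None and a.query_id not in eligible_reads:
            continue
        seen.add(a.query_id)
        if a.mapq >= min_mapq:
            assigned[a.query_id] = a.target_id
    per_strain: dict[str, int] = {}
    for strain in assigned.values():
        per_strain[strain] = per_strain.get(strain, 0) + 1
    fraction = len(assigned) / len(seen) if seen else 0.0
    return dict(sorted(per_strain.items())), fraction


def crassphage_profile(
    alignments: Sequence[AlignmentRecord],
    total_reads: int,
    *,
    min_query_cover: float = 0.70,
    min_identity: float = 0.70,
    min_mapq: int = 5,
) -> CrassResult:
    """Combined crAssphage abundance + strain assignment for one sample."""
    abundance, passing = crassphage_abundance(
        alignments,
        total_reads,
        min_query_cover=min_query_cover,
        min_identity=min_identity,
    )
    per_strain, fraction = crassphage_strain_counts(
        alignments, min_mapq=min_mapq, eligible_reads=passing
    )
    return CrassResult(
        abundance=abundance,
        crass_reads=len(passing),
        total_reads=total_reads,
        per_strain=per_strain,
        assignable_fraction=fraction,
    )


def arg_counts_to_frame(counts: ArgCount) -> pd.DataFrame:
    return pd.DataFrame(
        [{"arg_id": k, "reads": v} for k, v in counts.per_arg.items()]
    )
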