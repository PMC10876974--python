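"""Pairwise alignment records and PAF / SAM input.

A single lightweight record type serves taxon validation, ARG counting and
crAssphage quantification.  PAF is the canonical input (minimap2 default
output); SAM/BAM is accepted and converted via pysam, deriving the match
count from CIGAR + NM when available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "AlignmentRecord",
    "parse_paf",
    "write_paf",
    "parse_sam",
    "alignment_identity",
    "query_cover",
    "index_by_query",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise read-to-reference alignment.

    Query coordinates are 0-based half-open on the read.  ``matches`` is the
    number of matching bases in the block (PAF column 10) and
    ``block_length`` the alignment block length (PAF column 11).
    ``query_n_count`` counts undefined 'N' bases within the aligned query
    segment (carried in a ``nc:i:`` PAF tag; 0 when absent).
    """

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    target_id: str
    matches: int
    block_length: int
    mapq: int = 60
    is_primary: bool = True
    query_n_count: int = 0

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"{self.query_id}: bad query span "
                f"[{self.query_start},{self.query_end}) on length "
                f"{self.query_length}"
            )
        if self.block_length <= 0:
            raise ValueError(f"{self.query_id}: non-positive block length")
        if self.matches > self.block_length:
            raise ValueError(f"{self.query_id}: matches exceed block length")


def alignment_identity(aln: AlignmentRecord) -> float:
    """Alignment identity = matching bases / alignment block length."""
    if aln.block_length <= 0:
        raise ValueError("zero-length alignment block")
    return aln.matches / aln.block_length


def query_cover(aln: AlignmentRecord) -> float:
    """Fraction of the read covered by this single alignment."""
    return (aln.query_end - aln.query_start) / aln.query_length


def parse_paf(source: str | Path | IO[str]) -> list[AlignmentRecord]:
    """Parse minimap2-style PAF (12+ tab-separated columns plus tags)."""
    records = []
    close = isinstance(source, (str, Path))
    fh = open(source) if close else source
    try:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"PAF line {lineno}: fewer than 12 columns")
            is_primary = True
            n_count = 0
            for tag in f[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5] == "P"
                elif tag.startswith("nc:i:"):
                    n_count = int(tag[5:])
            records.append(
                AlignmentRecord(
                    query_id=f[0],
                    query_length=int(f[1]),
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    target_id=f[5],
                    matches=int(f[9]),
                    block_length=int(f[10]),
                    mapq=int(f[11]),
                    is_primary=is_primary,
                    query_n_count=n_count,
                )
            )
    finally:
        if close:
            fh.close()
    return records


def write_paf(
    records: Iterable[AlignmentRecord], dest: str | Path | IO[str]
) -> None:
    close = isinstance(dest, (str, Path))
    fh = open(dest, "w") if close else dest
    try:
        for r in records:
            tp = "P" if r.is_primary else "S"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.query_length,
                        r.query_start,
                        r.query_end,
                        "+",
                        r.target_id,
                        r.block_length,
                        0,
                        r.block_length,
                        r.matches,
                        r.block_length,
                        r.mapq,
                        f"tp:A:{tp}",
                        f"nc:i:{r.query_n_count}",
                    )
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def parse_sam(source: str | Path) -> list[AlignmentRecord]:
    """Convert SAM/BAM alignments via pysam.

    Matches are derived as aligned length minus NM edit distance when the
    NM tag is present, else from CIGAR '=' operations; without either, the
    aligned length is used and a warning is emitted.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(str(source), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            qlen = read.infer_read_length() or read.query_length
            aligned = read.query_alignment_length
            block = aligned
            if read.has_tag("NM"):
                nm = int(read.get_tag("NM"))
                # NM includes inserted/deleted bases; block spans them too.
                ins = sum(l for op, l in read.cigartuples if op == 1)
                dele = sum(l for op, l in read.cigartuples if op == 2)
                block = aligned + dele
                matches = max(block - nm, 0)
            else:
                eq = sum(l for op, l in read.cigartuples if op == 7)
                if eq:
                    matches = eq
                else:
                    warnings.warn(
                        f"{read.query_name}: no NM tag or '=' CIGAR ops; "
                        "treating all aligned bases as matches"
                    )
                    matches = aligned
            qstart = read.query_alignment_start
            qend = read.query_alignment_end
            if read.is_reverse and read.is_supplementary is False and qlen:
                # pysam query coords are on the stored (reverse-complemented)
                # sequence; flip to original read orientation.
                qstart, qend = qlen - qend, qlen - qstart
            seq = read.query_alignment_sequence
            records.append(
                AlignmentRecord(
                    query_id=read.query_name,
                    query_length=qlen,
                    query_start=qstart,
                    query_end=qend,
                    target_id=read.reference_name,
                    matches=min(matches, block),
                    block_length=block,
                    mapq=read.mapping_quality,
                    is_primary=not (read.is_secondary or read.is_supplementary),
                    query_n_count=seq.upper().count("N") if seq else 0,
                )
            )
    return records


def index_by_query(
    records: Iterable[AlignmentRecord],
) -> dict[str, list[AlignmentRecord]]:
    out: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        out.setdefault(r.query_id, []).append(r)
    return out
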