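"""Taxonomy handling: NCBI-style dump parsing, tree queries, domain labelling,
and Kraken2-style per-read assignment I/O.

The taxonomy is the scaffold for every downstream step: reads are assigned to
nodes of the tree by a k-mer classifier, and validation/composition operate on
a node together with all of its descendants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "TaxonomyNode",
    "TaxonomyTree",
    "ReadAssignment",
    "DomainLabel",
    "DomainConfig",
    "TaxonomyError",
    "load_taxonomy",
    "parse_kraken_assignments",
    "write_kraken_assignments",
]


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy dump or an unknown taxid lookup."""


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""


class DomainLabel(str, enum.Enum):
    """High-level read categories used for whole-sample profiles.

    ``nonfungal_eukaryote`` covers eukaryotes that are not fungi, plants or
    human; DNA viruses include bacteriophages.
    """

    BACTERIA = "bacteria"
    ARCHAEA = "archaea"
    FUNGI = "fungi"
    DNA_VIRUS = "dna_virus"
    NONFUNGAL_EUKARYOTE = "nonfungal_eukaryote"
    HUMAN = "human"
    PLANT = "plant"
    OTHER = "other"
    UNCLASSIFIED = "unclassified"


# Standard NCBI clade root taxids.
NCBI_BACTERIA = 2
NCBI_ARCHAEA = 2157
NCBI_EUKARYOTA = 2759
NCBI_FUNGI = 4751
NCBI_VIRUSES = 10239
NCBI_VIRIDIPLANTAE = 33090
NCBI_HOMO_SAPIENS = 9606
NCBI_CHORDATA = 7711


@dataclass(frozen=True)
class DomainConfig:
    """Clade root taxids used for domain labelling.

    Precedence when walking a node's ancestry: human before the generic
    eukaryote bucket, fungi and plants before the non-fungal-eukaryote
    fallback.  Defaults are the standard NCBI taxids; synthetic taxonomies
    supply their own roots.
    """

    bacteria: int = NCBI_BACTERIA
    archaea: int = NCBI_ARCHAEA
    fungi: int = NCBI_FUNGI
    viruses: int = NCBI_VIRUSES
    human: int = NCBI_HOMO_SAPIENS
    plants: int = NCBI_VIRIDIPLANTAE
    eukaryota: int = NCBI_EUKARYOTA


class TaxonomyTree:
    """Rooted taxonomy indexed by taxid.

    The root is its own parent; every other node's parent must exist.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[int, TaxonomyNode] = {}
        self._children: dict[int, list[int]] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        root = None
        for node in self._nodes.values():
            if node.parent_taxid == node.taxid:
                if root is not None:
                    raise TaxonomyError(
                        f"multiple roots: {root} and {node.taxid}"
                    )
                root = node.taxid
                continue
            if node.parent_taxid not in self._nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} references missing parent "
                    f"{node.parent_taxid}"
                )
            self._children.setdefault(node.parent_taxid, []).append(node.taxid)
        if root is None:
            raise TaxonomyError("no root node (self-parented) found")
        self.root = root

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[int]:
        return iter(self._nodes)

    def node(self, taxid: int) -> TaxonomyNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def children(self, taxid: int) -> list[int]:
        self.node(taxid)
        return list(self._children.get(taxid, ()))

    def descendants(self, taxid: int) -> set[int]:
        """All taxids at or below ``taxid`` (the node itself included)."""
        self.node(taxid)
        out = {taxid}
        stack = [taxid]
        while stack:
            for child in self._children.get(stack.pop(), ()):
                out.add(child)
                stack.append(child)
        return out

    def ancestors(self, taxid: int) -> list[int]:
        """Path from ``taxid`` up to and including the root."""
        node = self.node(taxid)
        path = [taxid]
        while node.taxid != self.root:
            node = self._nodes[node.parent_taxid]
            path.append(node.taxid)
        return path

    def is_descendant(self, taxid: int, ancestor: int) -> bool:
        return ancestor in self.ancestors(taxid)

    def nodes_at_rank(self, rank: str) -> list[int]:
        return [t for t, n in self._nodes.items() if n.rank == rank]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (or self) with the requested rank, if any."""
        for anc in self.ancestors(taxid):
            if self._nodes[anc].rank == rank:
                return anc
        return None

    def classify_domain(
        self, taxid: int, config: DomainConfig | None = None
    ) -> DomainLabel:
        """Map a taxid to its high-level domain label.

        Taxid 0 means the classifier left the read unclassified.  Fungi and
        plants take precedence over the generic eukaryote fallback, and the
        human taxid over other Metazoa.
        """
        if taxid == 0:
            return DomainLabel.UNCLASSIFIED
        cfg = config or DomainConfig()
        lineage = set(self.ancestors(taxid))
        if cfg.human in lineage:
            return DomainLabel.HUMAN
        if cfg.fungi in lineage:
            return DomainLabel.FUNGI
        if cfg.plants in lineage:
            return DomainLabel.PLANT
        if cfg.bacteria in lineage:
            return DomainLabel.BACTERIA
        if cfg.archaea in lineage:
            return DomainLabel.ARCHAEA
        if cfg.viruses in lineage:
            return DomainLabel.DNA_VIRUS
        if cfg.eukaryota in lineage:
            return DomainLabel.NONFUNGAL_EUKARYOTE
        return DomainLabel.OTHER


def _dump_fields(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]


def load_taxonomy(
    nodes_source: str | Path | IO[str],
    names_source: str | Path | IO[str] | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-style ``nodes.dmp`` / ``names.dmp`` dumps.

    The dumps are pipe-delimited (``taxid\\t|\\tparent\\t|\\trank\\t|...``);
    only scientific names are attached from the names file.
    """
    names: dict[int, str] = {}
    if names_source is not None:
        with _maybe_open(names_source) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _dump_fields(line)
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                names[int(fields[0])] = fields[1]
    nodes = []
    with _maybe_open(nodes_source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _dump_fields(line)
            if len(fields) < 3:
                raise TaxonomyError(
                    f"nodes dump line {lineno}: expected at least 3 fields"
                )
            taxid = int(fields[0])
            nodes.append(
                TaxonomyNode(
                    taxid=taxid,
                    parent_taxid=int(fields[1]),
                    rank=fields[2],
                    name=names.get(taxid, ""),
                )
            )
    return TaxonomyTree(nodes)


def _maybe_open(source: str | Path | IO[str]):
    if isinstance(source, (str, Path)):
        return open(source)
    import contextlib

    return contextlib.nullcontext(source)


@dataclass(frozen=True)
class ReadAssignment:
    """One classified read as reported by a Kraken2-style classifier."""

    read_id: str
    classified: bool
    taxid: int
    read_length: int

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError(f"read {self.read_id}: non-positive length")
        if self.classified != (self.taxid != 0):
            raise ValueError(
                f"read {self.read_id}: taxid {self.taxid} inconsistent with "
                f"classified={self.classified}"
            )


class KrakenParseError(ValueError):
    pass


def _parse_length(field: str) -> int:
    # Paired-end dialect reports "a|b"; the pair total is used.
    if "|" in field:
        return sum(int(p) for p in field.split("|"))
    return int(field)


def parse_kraken_assignments(
    source: str | Path | IO[str],
) -> list[ReadAssignment]:
    """Parse Kraken2 per-read output (``C/U  read_id  taxid  length  ...``)."""
    out = []
    with _maybe_open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4 or fields[0] not in ("C", "U"):
                raise KrakenParseError(f"line {lineno}: malformed record")
            try:
                out.append(
                    ReadAssignment(
                        read_id=fields[1],
                        classified=fields[0] == "C",
                        taxid=int(fields[2]),
                        read_length=_parse_length(fields[3]),
                    )
                )
            except ValueError as exc:
                raise KrakenParseError(f"line {lineno}: {exc}") from exc
    return out


def write_kraken_assignments(
    assignments: Iterable[ReadAssignment], dest: str | Path | IO[str]
) -> None:
    close = isinstance(dest, (str, Path))
    fh = open(dest, "w") if close else dest
    try:
        for a in assignments:
            flag = "C" if a.classified else "U"
            fh.write(f"{flag}\t{a.read_id}\t{a.taxid}\t{a.read_length}\t-\n")
    finally:
        if close:
            fh.close()


def count_classified(assignments: Iterable[ReadAssignment]) -> tuple[int, int]:
    """(classified, unclassified) read counts."""
    c = u = 0
    for a in assignments:
        if a.classified:
            c += 1
        else:
            u += 1
    return c, u
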