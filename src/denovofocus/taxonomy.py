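"""Taxonomic tree storage, canonical-rank lineages, and LCA queries.

The store holds an NCBI-style rooted taxonomy (every node points to its
parent; the root points to itself).  Lineages are reported at the seven
canonical ranks only; intermediate ``no rank`` / ``subspecies`` etc. nodes
are traversed but never reported, matching how rank-level composition
tables are built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .exceptions import EmptyInputError, FormatError, UnknownTaxonError

#: Canonical ranks, shallowest first.
CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_DEPTH = {r: i for i, r in enumerate(CANONICAL_RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identifier, parent link, rank label, and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass(frozen=True)
class Lineage:
    """Canonical-rank lineage of one taxon.

    ``ranks`` maps each canonical rank that occurs on the root-to-taxon
    path to ``(taxid, name)``; ranks not on the path are simply absent
    from the mapping.
    """

    taxid: int
    ranks: Mapping[str, tuple[int, str]]

    def taxid_at(self, rank: str) -> int | None:
        entry = self.ranks.get(rank)
        return entry[0] if entry else None

    def name_at(self, rank: str) -> str | None:
        entry = self.ranks.get(rank)
        return entry[1] if entry else None

    def has(self, rank: str) -> bool:
        return rank in self.ranks


class TaxonomyStore:
    """Rooted taxonomy with lineage and lowest-common-ancestor queries."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        roots = []
        for node in nodes:
            if node.taxid in self._nodes:
                raise FormatError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
            if node.parent_taxid == node.taxid:
                roots.append(node.taxid)
        if len(roots) != 1:
            raise FormatError(f"expected exactly one root, found {len(roots)}")
        self.root_taxid: int = roots[0]
        # sanity: every parent link resolves
        for node in self._nodes.values():
            if node.parent_taxid not in self._nodes:
                raise FormatError(
                    f"taxid {node.taxid} has unknown parent {node.parent_taxid}"
                )
        self._depth_cache: dict[int, int] = {}

    # -- basic access -------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self._nodes.values())

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None

    def rank_of(self, taxid: int) -> str:
        return self.node(taxid).rank

    def name_of(self, taxid: int) -> str:
        return self.node(taxid).name

    def taxids_at_rank(self, rank: str) -> set[int]:
        return {n.taxid for n in self._nodes.values() if n.rank == rank}

    # -- queries ------------------------------------------------------

    def ancestors(self, taxid: int) -> list[int]:
        """Root-to-self path of ``taxid`` (inclusive at both ends)."""
        path = [taxid]
        node = self.node(taxid)
        while node.taxid != self.root_taxid:
            node = self.node(node.parent_taxid)
            path.append(node.taxid)
        path.reverse()
        return path

    def _depth(self, taxid: int) -> int:
        cached = self._depth_cache.get(taxid)
        if cached is not None:
            return cached
        depth = len(self.ancestors(taxid)) - 1
        self._depth_cache[taxid] = depth
        return depth

    def lineage(self, taxid: int) -> Lineage:
        """Canonical-rank lineage obtained by walking parent links."""
        ranks: dict[str, tuple[int, str]] = {}
        for anc in self.ancestors(taxid):
            node = self._nodes[anc]
            if node.rank in _RANK_DEPTH:
                ranks[node.rank] = (node.taxid, node.name)
        ordered = {r: ranks[r] for r in CANONICAL_RANKS if r in ranks}
        return Lineage(taxid=taxid, ranks=ordered)

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node that is an ancestor-or-self of every input taxid."""
        taxids = set(taxids)
        if not taxids:
            raise EmptyInputError("lca of an empty taxid set is undefined")
        paths = [self.ancestors(t) for t in taxids]
        shortest = min(len(p) for p in paths)
        lca = self.root_taxid
        for i in range(shortest):
            level = {p[i] for p in paths}
            if len(level) > 1:
                break
            lca = level.pop()
        return lca

    # -- construction from NCBI-dialect dump files --------------------

    @classmethod
    def from_taxdump(cls, nodes_path: str | Path, names_path: str | Path) -> "TaxonomyStore":
        """Load from ``nodes.dmp`` / ``names.dmp`` (pipe-and-tab dialect).

        Only ``scientific name`` rows of names.dmp are used; taxa without
        one keep a placeholder name.
        """
        names: dict[int, str] = {}
        for lineno, row in _iter_dmp(names_path):
            if len(row) < 4:
                raise FormatError(f"{names_path}:{lineno}: expected >=4 fields")
            if row[3] == "scientific name":
                names[int(row[0])] = row[1]
        nodes = []
        for lineno, row in _iter_dmp(nodes_path):
            if len(row) < 3:
                raise FormatError(f"{nodes_path}:{lineno}: expected >=3 fields")
            taxid = int(row[0])
            nodes.append(
                TaxonNode(
                    taxid=taxid,
                    parent_taxid=int(row[1]),
                    rank=row[2],
                    name=names.get(taxid, f"taxid_{taxid}"),
                )
            )
        return cls(nodes)


def _iter_dmp(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            # field separator is "\t|\t"; lines end with "\t|"
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield lineno, [f.strip() for f in line.split("\t|\t")]
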