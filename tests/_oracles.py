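"""Independent brute-force oracles used to cross-check the implementation.

Every function here deliberately takes a different computational route
from the library code it checks (substring scans, pairwise comparisons,
exhaustive walks), so agreement is evidence of correctness rather than
repetition.
"""

from __future__ import annotations

from denovofocus.taxonomy import TaxonomyStore


def ancestor_set(store: TaxonomyStore, taxid: int) -> set[int]:
    """All ancestors-or-self by raw parent walking."""
    out = {taxid}
    node = store.node(taxid)
    while node.parent_taxid != node.taxid:
        node = store.node(node.parent_taxid)
        out.add(node.taxid)
    return out


def lca_by_intersection(store: TaxonomyStore, taxids) -> int:
    """LCA as the deepest member of the intersection of ancestor sets."""
    common = None
    for t in taxids:
        anc = ancestor_set(store, t)
        common = anc if common is None else (common & anc)
    assert common
    # deepest = largest ancestor-set size
    return max(common, key=lambda t: (len(ancestor_set(store, t)), t))


def digest_by_substring_scan(seq: str, mc: int, min_len: int, max_len: int) -> set[str]:
    """All tryptic products via an O(n^2) scan over contiguous substrings."""
    cuts = {
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    }
    boundaries = {0, len(seq)} | cuts
    products = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if i not in boundaries or j not in boundaries:
                continue
            internal = sum(1 for c in cuts if i < c < j)
            if internal <= mc and min_len <= j - i <= max_len:
                products.add(seq[i:j])
    return products


def hamming_scan(index_peptides: dict[str, set[str]], query: str) -> set[str]:
    """Exact plus distance-1 hits by linear scan over every indexed peptide."""
    hits = set()
    for pep, accs in index_peptides.items():
        if len(pep) != len(query):
            continue
        d = sum(1 for a, b in zip(pep, query) if a != b)
        if d <= 1:
            hits |= accs
    return hits


def group_by_pairwise_subsets(protein_peptides: dict[str, frozenset]) -> dict[str, frozenset]:
    """Map each protein to its group's peptide set via O(n^2) comparisons.

    Group sets are the maximal peptide sets (no strict superset among
    all observed sets, found by exhaustive pairwise comparison).  Every
    protein maps to the smallest maximal set containing its own (ties by
    sorted peptide tuple).
    """
    sets = set(protein_peptides.values())
    maximal = [s for s in sets if not any(s < other for other in sets)]
    assignment = {}
    for acc, pset in protein_peptides.items():
        containing = [s for s in maximal if pset <= s]
        assignment[acc] = min(containing, key=lambda s: (len(s), tuple(sorted(s))))
    return assignment
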