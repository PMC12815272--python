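"""Stage 4: protein grouping, unique-peptide accounting, and top-3 quantification.

Proteins indistinguishable at the observed peptide level are grouped:
identical peptide sets merge, and a protein whose peptide set is a
strict subset of another's is subsumed into that protein's group
(parsimony-style).  A peptide is *unique* when it occurs in exactly one
group's peptide set.  Protein abundance per sample is the sum of the
three most intense peptide areas (top-3 quantification), and the
post-identification filter keeps groups with at least ``min_unique``
unique peptides and an overall (across-sample) top-3 area strictly
above ``min_overall_area``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import CANONICAL_RANKS, TaxonomyStore

DEFAULT_MIN_UNIQUE = 2
DEFAULT_MIN_OVERALL_AREA = 5e5


@dataclass
class ProteinGroup:
    """A set of proteins sharing identical-or-subsumed peptide evidence."""

    group_id: int
    members: list[str]
    peptides: frozenset[str]
    member_peptides: dict[str, frozenset[str]]
    representative: str = ""
    n_unique: int = 0


def group_proteins(protein_peptides: Mapping[str, Iterable[str]]) -> list[ProteinGroup]:
    """Group proteins by identical or subsumed peptide sets.

    A non-maximal protein joins the group whose peptide set is its
    smallest strict superset; ties break on the lexicographically
    smallest sorted peptide tuple, making the result independent of
    input order.
    """
    psets = {acc: frozenset(peps) for acc, peps in protein_peptides.items()}
    for acc, peps in psets.items():
        if not peps:
            raise ValueError(f"protein {acc} has no peptides")

    distinct = set(psets.values())
    # maximal sets: not strict subsets of any other distinct set
    maximal = [
        s for s in distinct if not any(s < other for other in distinct)
    ]
    maximal.sort(key=lambda s: (-len(s), tuple(sorted(s))))

    groups: list[ProteinGroup] = [
        ProteinGroup(group_id=i, members=[], peptides=s, member_peptides={})
        for i, s in enumerate(maximal)
    ]
    by_set = {g.peptides: g for g in groups}

    for acc in sorted(psets):
        pset = psets[acc]
        g = by_set.get(pset)
        if g is None:
            supersets = [grp for grp in groups if pset < grp.peptides]
            g = min(supersets, key=lambda grp: (len(grp.peptides), tuple(sorted(grp.peptides))))
        g.members.append(acc)
        g.member_peptides[acc] = pset
    return groups


def count_unique_peptides(groups: Sequence[ProteinGroup]) -> dict[int, int]:
    """Per-group count of peptides occurring in exactly one group."""
    incidence: dict[str, int] = {}
    for g in groups:
        for pep in g.peptides:
            incidence[pep] = incidence.get(pep, 0) + 1
    counts = {}
    for g in groups:
        g.n_unique = sum(1 for pep in g.peptides if incidence[pep] == 1)
        counts[g.group_id] = g.n_unique
    return counts


def top3_area(areas: Iterable[float]) -> float:
    """Sum of the three largest peptide areas (all of them if fewer)."""
    areas = list(areas)
    if any(a < 0 for a in areas):
        raise ValueError("negative peptide area")
    return float(sum(sorted(areas, reverse=True)[:3]))


def build_quant_table(
    groups: Sequence[ProteinGroup],
    peptide_areas: Mapping[str, Mapping[str, float]],
    store: TaxonomyStore | None = None,
    taxid_of=None,
) -> pd.DataFrame:
    """Assemble the group-level quantification table.

    ``peptide_areas`` maps sample_id -> {canonical peptide: area}.  The
    group representative ("top hit") is the member whose own peptide set
    accumulates the largest overall top-3 area, ties broken by ascending
    accession.  Shared peptides contribute to every group containing
    them.  When a taxonomy store and a ``taxid_of(accession)`` callable
    are given, the representative's canonical-rank lineage is attached.
    """
    count_unique_peptides(groups)
    samples = sorted(peptide_areas)
    rows = []
    for g in groups:
        sample_tops = {
            s: top3_area(
                peptide_areas[s][p] for p in g.peptides if p in peptide_areas[s]
            )
            for s in samples
        }
        member_overall = {
            acc: sum(
                top3_area(
                    peptide_areas[s][p] for p in pset if p in peptide_areas[s]
                )
                for s in samples
            )
            for acc, pset in g.member_peptides.items()
        }
        g.representative = min(member_overall, key=lambda a: (-member_overall[a], a))
        row: dict = {
            "group_id": g.group_id,
            "representative": g.representative,
            "members": ";".join(sorted(g.members)),
            "n_members": len(g.members),
            "n_peptides": len(g.peptides),
            "n_unique": g.n_unique,
        }
        for s in samples:
            row[f"area:{s}"] = sample_tops[s]
        row["overall_area"] = float(sum(sample_tops.values()))
        if store is not None and taxid_of is not None:
            taxid = taxid_of(g.representative)
            row["taxid"] = taxid if taxid is not None else -1
            if taxid is not None and taxid in store:
                lin = store.lineage(taxid)
                for rank in CANONICAL_RANKS:
                    row[rank] = lin.name_at(rank) or ""
                    row[f"{rank}_taxid"] = lin.taxid_at(rank) or -1
            else:
                for rank in CANONICAL_RANKS:
                    row[rank] = ""
                    row[f"{rank}_taxid"] = -1
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["overall_area", "representative"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def apply_paper_filters(
    table: pd.DataFrame,
    min_unique: int = DEFAULT_MIN_UNIQUE,
    min_overall_area: float = DEFAULT_MIN_OVERALL_AREA,
) -> pd.DataFrame:
    """Post-identification filter on the quant table.

    Keeps rows with ``n_unique >= min_unique`` (inclusive) and
    ``overall_area > min_overall_area`` (strict), then retains only the
    representative ("top hit") of each group — the table is already one
    row per group, so this reduces the members column to the
    representative.  Idempotent.
    """
    if len(table) == 0:
        return table.copy()
    kept = table[
        (table["n_unique"] >= min_unique) & (table["overall_area"] > min_overall_area)
    ].copy()
    kept["members"] = kept["representative"]
    kept["n_members"] = 1
    return kept.reset_index(drop=True)
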