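"""Stage 1: taxonomic profiling of de novo peptide reads.

Reads passing the ALC confidence filter are matched (exact, canonical
form) against an index of the global reference.  Each matched peptide is
assigned the lowest common ancestor of the taxa of all matching records;
peptides whose LCA resolves to family level or below contribute one
distinct-peptide count (and their summed area) to that family.  Families
supported by enough distinct peptides are "identified" and drive the
focused database construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import DeNovoRead
from .peptides import PeptideIndex, canonicalize
from .taxonomy import TaxonomyStore

logger = logging.getLogger(__name__)

DEFAULT_ALC_THRESHOLD = 70.0
DEFAULT_MIN_FAMILY_PEPTIDES = 2


@dataclass(frozen=True)
class PeptideTaxon:
    """LCA assignment of one canonical peptide."""

    peptide: str
    lca_taxid: int
    n_proteins: int
    area: float


@dataclass
class FamilyProfile:
    """Per-sample family-level profile.

    ``families`` maps family taxid -> (distinct peptide count, summed
    area); only families meeting ``min_family_peptides`` are considered
    identified (see :meth:`identified_families`).
    """

    sample_id: str
    families: dict[int, tuple[int, float]]
    min_family_peptides: int
    n_reads: int = 0
    n_matched_peptides: int = 0
    n_unmatched_peptides: int = 0
    peptide_taxa: list[PeptideTaxon] = field(default_factory=list)

    def identified_families(self) -> set[int]:
        return {
            taxid
            for taxid, (count, _) in self.families.items()
            if count >= self.min_family_peptides
        }

    def to_frame(self, store: TaxonomyStore) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "family_taxid": taxid,
                "family_name": store.name_of(taxid),
                "peptide_count": count,
                "area": area,
            }
            for taxid, (count, area) in self.families.items()
        ]
        df = pd.DataFrame(
            rows,
            columns=["sample_id", "family_taxid", "family_name", "peptide_count", "area"],
        )
        return df.sort_values(
            ["peptide_count", "area", "family_taxid"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)


def filter_alc(reads: Sequence[DeNovoRead], threshold: float = DEFAULT_ALC_THRESHOLD) -> list[DeNovoRead]:
    """Keep reads with ALC >= threshold (inclusive); order preserved."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"ALC threshold {threshold} outside [0, 100]")
    return [r for r in reads if r.alc >= threshold]


def merge_reads(reads: Sequence[DeNovoRead]) -> dict[str, float]:
    """Collapse per-spectrum reads to canonical peptides with summed areas."""
    merged: dict[str, float] = {}
    for read in reads:
        pep = canonicalize(read.peptide)
        merged[pep] = merged.get(pep, 0.0) + read.area
    return merged


def profile_sample(
    reads: Sequence[DeNovoRead],
    index: PeptideIndex,
    store: TaxonomyStore,
    min_family_peptides: int = DEFAULT_MIN_FAMILY_PEPTIDES,
    sample_id: str | None = None,
) -> FamilyProfile:
    """Profile one sample's (ALC-filtered) reads at family level.

    Matching is exact on canonical peptides.  A peptide contributes to a
    family only when the family rank of its LCA lineage is defined, i.e.
    its LCA lies at family rank or below; peptides resolving above
    family are counted as matched but profile-silent.
    """
    sid = sample_id if sample_id is not None else (reads[0].sample_id if reads else "")
    profile = FamilyProfile(
        sample_id=sid,
        families={},
        min_family_peptides=min_family_peptides,
        n_reads=len(reads),
    )
    if not reads:
        logger.warning("sample %s: no reads to profile", sid)
        return profile

    for pep, area in merge_reads(reads).items():
        accessions = index.match(pep, max_subs=0)
        taxids = {
            t for t in (index.taxid_of(a) for a in accessions) if t is not None and t in store
        }
        if not taxids:
            profile.n_unmatched_peptides += 1
            continue
        profile.n_matched_peptides += 1
        lca = store.lca(taxids)
        profile.peptide_taxa.append(
            PeptideTaxon(peptide=pep, lca_taxid=lca, n_proteins=len(accessions), area=area)
        )
        family = store.lineage(lca).taxid_at("family")
        if family is not None:
            count, fam_area = profile.families.get(family, (0, 0.0))
            profile.families[family] = (count + 1, fam_area + area)
    return profile
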