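"""Stage 2: focused database construction.

Given the families identified by the profiler, select from the global
reference every entry whose lineage passes through one of them, yielding
a per-sample focused database.  Supplements (e.g. the human reference
proteome in round 2, or an entrapment set) are merged in with an explicit
tag so provenance stays distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .exceptions import ValidationError
from .io import ProteinRecord
from .taxonomy import TaxonomyStore

logger = logging.getLogger(__name__)


@dataclass
class FocusedDatabase:
    """A per-sample protein database with selection provenance.

    ``supplement_tags`` maps accession -> tag for records that were
    merged in rather than selected by family (e.g. ``human_UP000005640``
    or ``entrapment``).
    """

    sample_id: str
    records: list[ProteinRecord]
    provenance: set[int] = field(default_factory=set)
    supplement_tags: dict[str, str] = field(default_factory=dict)

    @property
    def accessions(self) -> set[str]:
        return {r.accession for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def record(self, accession: str) -> ProteinRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)


def select_by_family(
    global_records: Sequence[ProteinRecord],
    families: Iterable[int],
    store: TaxonomyStore,
    sample_id: str = "",
) -> FocusedDatabase:
    """Select all global entries whose lineage family is in ``families``.

    Records lacking a taxid (or carrying one unknown to the store) cannot
    be placed in a family and are excluded.  Input order is preserved.
    """
    families = set(families)
    for taxid in families:
        rank = store.rank_of(taxid)
        if rank != "family":
            raise ValidationError(f"taxid {taxid} has rank {rank!r}, not family")
    if not families:
        logger.warning("sample %s: empty family set, focused database is empty", sample_id)
    selected = []
    for rec in global_records:
        if rec.taxid is None or rec.taxid not in store:
            continue
        if store.lineage(rec.taxid).taxid_at("family") in families:
            selected.append(rec)
    return FocusedDatabase(sample_id=sample_id, records=selected, provenance=families)


def merge_databases(
    base: FocusedDatabase, supplement: Sequence[ProteinRecord], tag: str
) -> FocusedDatabase:
    """Union by accession; on collision the first occurrence wins."""
    seen = base.accessions
    merged_records = list(base.records)
    tags = dict(base.supplement_tags)
    n_dup = 0
    for rec in supplement:
        if rec.accession in seen:
            n_dup += 1
            continue
        seen.add(rec.accession)
        merged_records.append(rec)
        tags[rec.accession] = tag
    if n_dup:
        logger.info("merge %s: %d duplicate accessions skipped", tag, n_dup)
    return FocusedDatabase(
        sample_id=base.sample_id,
        records=merged_records,
        provenance=set(base.provenance),
        supplement_tags=tags,
    )
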