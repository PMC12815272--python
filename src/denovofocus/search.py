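"""Stage 3: the two-round database search with target-decoy FDR.

Round 1 matches the sample's peptides against the focused database
(one missed cleavage, exact matching, no score cut-off) purely to
collect candidate proteins.  The candidates plus the human reference
proteome form the round-2 database, which is searched allowing up to
three missed cleavages; peptide matches are filtered to a target-decoy
FDR at the match level, and proteins are called significant when their
protein group retains at least two unique peptides.  An entrapment
evaluation spikes the round-2 database with proteins from taxa known to
be absent and reports how many surviving matches hit them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .exceptions import EmptyDatabaseError, EmptyInputError, ValidationError
from .focusdb import FocusedDatabase, merge_databases
from .io import ProteinRecord
from .peptides import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    DigestionParams,
    PeptideIndex,
    canonicalize,
)
from . import quant

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"
HUMAN_TAG = "human_UP000005640"
ENTRAPMENT_TAG = "entrapment"

DEFAULT_FDR_ALPHA = 0.05
DEFAULT_MC_ROUND1 = 1
DEFAULT_MC_ROUND2 = 3


@dataclass(frozen=True)
class SamplePeptide:
    """One peptide observation entering the search: sequence, area, score.

    ``read_id`` is an opaque caller-side identifier carried through to
    the surviving matches, so results can be traced back to individual
    reads (e.g. for ground-truth evaluation on simulated data).
    """

    peptide: str
    area: float
    score: float
    read_id: int = -1


@dataclass(frozen=True)
class ScoredMatch:
    """One peptide-to-database match with its target/decoy/entrapment label."""

    peptide: str
    accessions: frozenset[str]
    label: str  # "target" | "decoy" | "entrapment"
    score: float
    area: float
    sample_id: str = ""
    read_id: int = -1


@dataclass
class SearchResult:
    """Outcome of a round-2 search for one sample."""

    sample_id: str
    matches: list[ScoredMatch]  # FDR-surviving, decoys removed
    threshold_score: float
    protein_peptides: dict[str, set[str]]
    groups: list[quant.ProteinGroup]
    significant: set[str]  # accessions in groups with >=2 unique peptides
    n_psms_total: int = 0
    n_decoy_psms: int = 0
    n_decoy_above_threshold: int = 0

    @property
    def estimated_fdr(self) -> float:
        """Decoy/target count ratio at the admitted threshold."""
        return self.n_decoy_above_threshold / max(1, len(self.matches))


@dataclass
class EntrapmentReport:
    """Entrapment spike-in evaluation alongside the FDR estimate."""

    sample_id: str
    n_surviving: int
    n_entrapment_hits: int
    entrapment_fraction: float
    estimated_fdr: float
    threshold_score: float


def as_sample_peptides(reads) -> list[SamplePeptide]:
    """Adapt de novo reads to search inputs; the ALC score doubles as the
    match score in this sequence-level engine."""
    return [
        SamplePeptide(r.peptide, r.area, r.alc, read_id=i)
        for i, r in enumerate(reads)
    ]


# ---------------------------------------------------------------------------
# round 1
# ---------------------------------------------------------------------------


def round1(
    sample_peptides: Sequence[SamplePeptide],
    focused: FocusedDatabase,
    missed_cleavages: int = DEFAULT_MC_ROUND1,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> set[str]:
    """Collect candidate accessions by exact matching, no score cut-off."""
    if not focused.records:
        raise EmptyDatabaseError("round 1 requires a non-empty focused database")
    index = PeptideIndex.build(
        focused.records, DigestionParams(missed_cleavages, min_len, max_len)
    )
    hits: set[str] = set()
    for sp in sample_peptides:
        hits |= index.match(canonicalize(sp.peptide), max_subs=0)
    if not hits:
        logger.warning("sample %s: round 1 matched no proteins", focused.sample_id)
    return hits


def build_round2_db(
    round1_hits: set[str],
    focused: FocusedDatabase,
    human: Sequence[ProteinRecord],
) -> FocusedDatabase:
    """Round-1 candidates plus the human reference proteome supplement."""
    unknown = round1_hits - focused.accessions
    if unknown:
        raise ValidationError(f"round-1 hits not in focused database: {sorted(unknown)[:5]}")
    base = FocusedDatabase(
        sample_id=focused.sample_id,
        records=[r for r in focused.records if r.accession in round1_hits],
        provenance=set(focused.provenance),
        supplement_tags={
            a: t for a, t in focused.supplement_tags.items() if a in round1_hits
        },
    )
    return merge_databases(base, list(human), HUMAN_TAG)


# ---------------------------------------------------------------------------
# decoys and FDR
# ---------------------------------------------------------------------------


def make_decoys(db: FocusedDatabase) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target record."""
    return [
        ProteinRecord(
            accession=DECOY_PREFIX + rec.accession,
            description="reversed decoy",
            taxid=None,
            sequence=rec.sequence[::-1],
        )
        for rec in db.records
        if not rec.accession.startswith(DECOY_PREFIX)
    ]


def add_decoys(db: FocusedDatabase) -> FocusedDatabase:
    return merge_databases(db, make_decoys(db), "decoy")


def is_decoy(accession: str) -> bool:
    return accession.startswith(DECOY_PREFIX)


def estimate_fdr(
    matches: Sequence[ScoredMatch], alpha: float = DEFAULT_FDR_ALPHA
) -> tuple[float, list[ScoredMatch]]:
    """Target-decoy FDR thresholding at match level.

    For a score threshold ``s``, FDR(s) = #decoy(score>=s) / max(1,
    #target(score>=s)), capped at 1.  Returns the lowest observed score ``s`` with
    FDR(s) <= alpha and the non-decoy matches at or above it (ties at
    the threshold are all admitted).  Uses the plain decoy/target count
    ratio without a +1 correction.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha {alpha} outside (0, 1]")
    targets = [m for m in matches if m.label != "decoy"]
    decoys = [m for m in matches if m.label == "decoy"]
    if not targets:
        raise EmptyInputError("no target matches to threshold")

    scores = sorted({m.score for m in matches}, reverse=True)
    n_t = n_d = 0
    it_t = iter(sorted(targets, key=lambda m: -m.score))
    it_d = iter(sorted(decoys, key=lambda m: -m.score))
    next_t = next(it_t, None)
    next_d = next(it_d, None)
    threshold = float("inf")
    for s in scores:
        while next_t is not None and next_t.score >= s:
            n_t += 1
            next_t = next(it_t, None)
        while next_d is not None and next_d.score >= s:
            n_d += 1
            next_d = next(it_d, None)
        if min(1.0, n_d / max(1, n_t)) <= alpha:
            threshold = s
    survivors = [m for m in targets if m.score >= threshold]
    return threshold, survivors


# ---------------------------------------------------------------------------
# round 2
# ---------------------------------------------------------------------------


def score_matches(
    sample_peptides: Sequence[SamplePeptide],
    index: PeptideIndex,
    max_subs: int = 0,
    entrapment_accessions: set[str] | None = None,
    sample_id: str = "",
) -> list[ScoredMatch]:
    """Match each peptide observation and label it target/decoy/entrapment."""
    entrapment_accessions = entrapment_accessions or set()
    out = []
    for sp in sample_peptides:
        accs = index.match(canonicalize(sp.peptide), max_subs=max_subs)
        if not accs:
            continue
        non_decoy = {a for a in accs if not is_decoy(a)}
        if not non_decoy:
            label = "decoy"
        elif non_decoy <= entrapment_accessions:
            label = "entrapment"
        else:
            label = "target"
        out.append(
            ScoredMatch(
                peptide=canonicalize(sp.peptide),
                accessions=frozenset(accs),
                label=label,
                score=sp.score,
                area=sp.area,
                sample_id=sample_id,
                read_id=sp.read_id,
            )
        )
    return out


def round2(
    sample_peptides: Sequence[SamplePeptide],
    db2: FocusedDatabase,
    missed_cleavages: int = DEFAULT_MC_ROUND2,
    max_subs: int = 0,
    alpha: float = DEFAULT_FDR_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    entrapment_accessions: set[str] | None = None,
    min_unique: int = 2,
) -> SearchResult:
    """Second-round search with FDR filtering and protein-level calls.

    ``db2`` must already contain its decoys (see :func:`add_decoys`).
    """
    if not db2.records:
        raise EmptyDatabaseError("round 2 requires a non-empty database")
    if not any(is_decoy(r.accession) for r in db2.records):
        raise ValidationError("round-2 database carries no decoys; call add_decoys first")
    index = PeptideIndex.build(
        db2.records, DigestionParams(missed_cleavages, min_len, max_len)
    )
    all_matches = score_matches(
        sample_peptides, index, max_subs, entrapment_accessions, db2.sample_id
    )
    n_decoy = sum(1 for m in all_matches if m.label == "decoy")
    if not any(m.label != "decoy" for m in all_matches):
        return SearchResult(
            sample_id=db2.sample_id,
            matches=[],
            threshold_score=float("inf"),
            protein_peptides={},
            groups=[],
            significant=set(),
            n_psms_total=len(all_matches),
            n_decoy_psms=n_decoy,
        )
    threshold, survivors = estimate_fdr(all_matches, alpha)
    n_decoy_above = sum(
        1 for m in all_matches if m.label == "decoy" and m.score >= threshold
    )

    protein_peptides: dict[str, set[str]] = {}
    for m in survivors:
        for acc in m.accessions:
            if not is_decoy(acc):
                protein_peptides.setdefault(acc, set()).add(m.peptide)

    groups = quant.group_proteins(protein_peptides) if protein_peptides else []
    quant.count_unique_peptides(groups)
    significant = {
        acc for g in groups if g.n_unique >= min_unique for acc in g.members
    }
    return SearchResult(
        sample_id=db2.sample_id,
        matches=survivors,
        threshold_score=threshold,
        protein_peptides=protein_peptides,
        groups=groups,
        significant=significant,
        n_psms_total=len(all_matches),
        n_decoy_psms=n_decoy,
        n_decoy_above_threshold=n_decoy_above,
    )


def two_round_search(
    sample_peptides: Sequence[SamplePeptide],
    focused: FocusedDatabase,
    human: Sequence[ProteinRecord],
    mc_round1: int = DEFAULT_MC_ROUND1,
    mc_round2: int = DEFAULT_MC_ROUND2,
    max_subs: int = 0,
    alpha: float = DEFAULT_FDR_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> SearchResult:
    """Convenience driver: round 1 -> round-2 database -> round 2."""
    hits = round1(sample_peptides, focused, mc_round1, min_len, max_len)
    db2 = add_decoys(build_round2_db(hits, focused, human))
    return round2(
        sample_peptides, db2, mc_round2, max_subs, alpha, min_len, max_len
    )


def single_round_search(
    sample_peptides: Sequence[SamplePeptide],
    focused: FocusedDatabase,
    missed_cleavages: int = DEFAULT_MC_ROUND1,
    max_subs: int = 0,
    alpha: float = DEFAULT_FDR_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> SearchResult:
    """Baseline: one FDR-controlled search against the focused database only.

    Used to quantify the benefit of the two-round design (candidate
    narrowing plus human supplement and relaxed missed cleavages).
    """
    db = add_decoys(focused)
    return round2(
        sample_peptides, db, missed_cleavages, max_subs, alpha, min_len, max_len
    )


# ---------------------------------------------------------------------------
# entrapment
# ---------------------------------------------------------------------------


def entrapment_eval(
    sample_peptides: Sequence[SamplePeptide],
    db2: FocusedDatabase,
    entrapment_records: Sequence[ProteinRecord],
    missed_cleavages: int = DEFAULT_MC_ROUND2,
    max_subs: int = 0,
    alpha: float = DEFAULT_FDR_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> EntrapmentReport:
    """Run round 2 on ``db2`` spiked with foreign-taxa proteins.

    ``db2`` is the *pre-decoy* round-2 database; decoys are generated
    over the spiked union so entrapment records compete on equal terms.
    Reports the count and fraction of surviving matches that hit only
    entrapment accessions, next to the search's own FDR estimate.
    """
    spiked = merge_databases(db2, list(entrapment_records), ENTRAPMENT_TAG)
    entrapment_accs = {r.accession for r in entrapment_records} & spiked.accessions
    spiked = add_decoys(spiked)
    result = round2(
        sample_peptides,
        spiked,
        missed_cleavages,
        max_subs,
        alpha,
        min_len,
        max_len,
        entrapment_accessions=entrapment_accs,
    )
    n_surv = len(result.matches)
    n_trap = sum(1 for m in result.matches if m.label == "entrapment")
    return EntrapmentReport(
        sample_id=db2.sample_id,
        n_surviving=n_surv,
        n_entrapment_hits=n_trap,
        entrapment_fraction=(n_trap / n_surv) if n_surv else 0.0,
        estimated_fdr=result.estimated_fdr,
        threshold_score=result.threshold_score,
    )
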