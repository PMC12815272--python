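"""In silico tryptic digestion and the peptide-to-protein index.

Peptides are compared in *canonical* form: modification annotations such
as ``(+15.99)`` are stripped and isoleucine/leucine — indistinguishable
by mass, hence in de novo calls — are both rewritten to the unused
letter ``J``.  The index supports exact lookup and an error-tolerant
mode admitting a single amino-acid substitution, which models the
dominant de novo sequencing error at the sequence level.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import ValidationError
from .io import ProteinRecord

_ANNOTATION_RE = re.compile(r"\([^)]*\)")
_VALID_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO]+$")

DEFAULT_MIN_LEN = 6
DEFAULT_MAX_LEN = 50


def canonicalize(peptide: str) -> str:
    """Strip modification annotations, uppercase, and map I/L to J."""
    if not peptide:
        raise ValidationError("empty peptide")
    seq = _ANNOTATION_RE.sub("", peptide).upper()
    seq = re.sub(r"[^A-Z]", "", seq)
    if not seq:
        raise ValidationError(f"peptide {peptide!r} has no residues")
    return seq.replace("I", "J").replace("L", "J")


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts: after K or R, not before P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Tryptic digestion products with up to ``missed_cleavages`` missed sites.

    Returns the deduplicated peptides (original residue alphabet, not
    canonicalized) whose lengths fall within ``[min_len, max_len]``, in
    order of first occurrence along the sequence.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if not _VALID_SEQ_RE.match(sequence):
        bad = sorted(set(re.sub(r"[A-Z]", "", sequence.upper()) or sequence))
        raise ValidationError(f"non-amino-acid characters in sequence: {bad}")
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    out: list[str] = []
    seen: set[str] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = sequence[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len and pep not in seen:
                seen.add(pep)
                out.append(pep)
    return out


@dataclass(frozen=True)
class DigestionParams:
    missed_cleavages: int = 1
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN


class PeptideIndex:
    """Canonical peptide -> protein accessions, from in silico digestion.

    Also records each accession's taxid so downstream LCA assignment
    needs no second lookup structure.
    """

    def __init__(self, params: DigestionParams):
        self.params = params
        self._exact: dict[str, set[str]] = defaultdict(set)
        self._taxids: dict[str, int | None] = {}
        self._masked: dict[str, set[str]] | None = None

    # -- construction --------------------------------------------------

    @classmethod
    def build(
        cls, records: Iterable[ProteinRecord], params: DigestionParams | None = None
    ) -> "PeptideIndex":
        index = cls(params or DigestionParams())
        for rec in records:
            index.add_record(rec)
        return index

    def add_record(self, rec: ProteinRecord) -> None:
        self._taxids[rec.accession] = rec.taxid
        p = self.params
        for pep in digest(rec.sequence, p.missed_cleavages, p.min_len, p.max_len):
            self._exact[canonicalize(pep)].add(rec.accession)
        self._masked = None  # invalidate substitution buckets

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._exact)

    def __contains__(self, canonical_peptide: str) -> bool:
        return canonical_peptide in self._exact

    @property
    def accessions(self) -> set[str]:
        return set(self._taxids)

    def taxid_of(self, accession: str) -> int | None:
        return self._taxids[accession]

    def peptides(self) -> Iterable[str]:
        return self._exact.keys()

    def items(self) -> Iterable[tuple[str, set[str]]]:
        return self._exact.items()

    # -- matching -------------------------------------------------------

    def match(self, canonical_peptide: str, max_subs: int = 0) -> set[str]:
        """Accessions whose digest contains the peptide.

        ``max_subs=0``: exact lookup.  ``max_subs=1``: union of the exact
        hits and all indexed peptides of identical length at Hamming
        distance exactly 1, found via single-wildcard buckets.
        """
        if max_subs not in (0, 1):
            raise ValidationError("max_subs must be 0 or 1")
        hits = set(self._exact.get(canonical_peptide, ()))
        if max_subs == 1:
            if self._masked is None:
                self._build_masked()
            assert self._masked is not None
            for i in range(len(canonical_peptide)):
                key = f"{canonical_peptide[:i]}*{canonical_peptide[i + 1:]}"
                for other in self._masked.get(key, ()):
                    if other != canonical_peptide:
                        hits |= self._exact[other]
        return hits

    def _build_masked(self) -> None:
        masked: dict[str, set[str]] = defaultdict(set)
        for pep in self._exact:
            for i in range(len(pep)):
                masked[f"{pep[:i]}*{pep[i + 1:]}"].add(pep)
        self._masked = masked

    # -- serialization ----------------------------------------------------

    def to_pairs(self) -> list[tuple[str, str]]:
        """(peptide, accession) pairs, sorted, for TSV export."""
        return sorted(
            (pep, acc) for pep, accs in self._exact.items() for acc in accs
        )


def build_index(
    records: Sequence[ProteinRecord],
    missed_cleavages: int = 1,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PeptideIndex:
    """Convenience wrapper around :meth:`PeptideIndex.build`."""
    return PeptideIndex.build(
        records, DigestionParams(missed_cleavages, min_len, max_len)
    )
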