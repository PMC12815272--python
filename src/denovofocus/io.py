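"""Readers and writers for the pipeline's file formats.

Formats handled here:

* reference proteome FASTA in the UniRef header dialect
  (``>UniRef90_P12345 Description n=1 Tax=... TaxID=9606 RepID=...``),
* de novo peptide read CSV as exported by de novo sequencing engines
  (columns ``Peptide``, ``ALC``, ``Area``, optionally ``Sample``),
* annotation lists as TSV (``list_name``, ``level``, ``member``),
* tab-separated report tables with reproducible formatting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError, IOFailure, ValidationError

logger = logging.getLogger(__name__)

_TAXID_RE = re.compile(r"\bTaxID=(\d+)\b")

#: Standard residues plus X for ambiguous positions.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One reference protein sequence with UniRef-style annotation.

    ``taxid`` is ``None`` for records whose header lacks a ``TaxID=``
    token; such records are kept in databases but excluded from any
    taxonomy-dependent step.
    """

    accession: str
    description: str
    taxid: int | None
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")


@dataclass(frozen=True)
class DeNovoRead:
    """One de novo peptide call.

    ``peptide`` is the sequence as called, possibly carrying modification
    annotations in parentheses, e.g. ``M(+15.99)PEPTIDEK``.  ``alc`` is
    the average local confidence in percent.
    """

    peptide: str
    alc: float
    area: float
    sample_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.alc <= 100.0:
            raise ValidationError(f"ALC {self.alc} outside [0, 100]")
        if self.area < 0:
            raise ValidationError(f"negative area {self.area}")


@dataclass(frozen=True)
class AnnotationList:
    """A named membership list used for categorisation.

    ``level`` says what the members are: taxon names at ``genus`` or
    ``family`` rank, or bare protein accessions.
    """

    list_name: str
    level: str
    members: frozenset[str]

    def __post_init__(self):
        if self.level not in {"genus", "family", "protein_accession"}:
            raise ValidationError(f"unknown annotation level: {self.level}")
        if not self.members:
            raise ValidationError(f"annotation list {self.list_name} is empty")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_uniref_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a UniRef-dialect FASTA into protein records, order preserved."""
    records: list[ProteinRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    for i, rec in enumerate(seq_records):
        if not rec.id:
            raise FormatError(f"{path}: entry {i + 1} has no accession")
        m = _TAXID_RE.search(rec.description)
        taxid = int(m.group(1)) if m else None
        if taxid is None:
            logger.warning("%s: %s has no TaxID= token", path, rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=desc,
                taxid=taxid,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_uniref_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records in the UniRef header dialect, 60-residue lines."""
    seq_records = []
    for rec in records:
        desc = rec.description
        if rec.taxid is not None and "TaxID=" not in desc:
            desc = f"{desc} TaxID={rec.taxid}".strip()
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.accession, description=desc)
        )
    try:
        SeqIO.write(seq_records, str(path), "fasta")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# de novo read CSV
# ---------------------------------------------------------------------------


def parse_denovo_csv(path: str | Path, sample_id: str | None = None) -> list[DeNovoRead]:
    """Parse a de novo read export.

    Requires columns ``Peptide``, ``ALC`` and ``Area`` (case sensitive).
    A ``Sample`` column, if present, overrides the ``sample_id`` argument
    row-wise.
    """
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    for col in ("Peptide", "ALC", "Area"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    default_sample = sample_id if sample_id is not None else Path(path).stem
    reads = []
    for row in df.itertuples(index=False):
        sid = str(getattr(row, "Sample", default_sample))
        reads.append(
            DeNovoRead(
                peptide=str(row.Peptide),
                alc=float(row.ALC),
                area=float(row.Area),
                sample_id=sid,
            )
        )
    return reads


def write_denovo_csv(reads: Sequence[DeNovoRead], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "Peptide": [r.peptide for r in reads],
            "ALC": [r.alc for r in reads],
            "Area": [r.area for r in reads],
            "Sample": [r.sample_id for r in reads],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# annotation lists
# ---------------------------------------------------------------------------


def parse_annotation_tsv(path: str | Path) -> dict[str, AnnotationList]:
    """Read annotation lists from a 3-column TSV (list_name, level, member)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    for col in ("list_name", "level", "member"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    lists: dict[str, AnnotationList] = {}
    for (name, level), grp in df.groupby(["list_name", "level"], sort=False):
        if name in lists:
            raise FormatError(f"{path}: list {name!r} appears at two levels")
        lists[name] = AnnotationList(
            list_name=name, level=level, members=frozenset(grp["member"])
        )
    return lists


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def write_report_tsv(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
    ascending: Sequence[bool] | bool = True,
) -> None:
    """Write a report table as TSV with 6-significant-digit floats.

    Output is deterministic: an explicit sort key gives a stated row
    order; without one the incoming row order is kept.
    """
    out = table.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), ascending=ascending, kind="mergesort")
    try:
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
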