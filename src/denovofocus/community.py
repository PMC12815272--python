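"""Stage 5: dataset splits, taxonomic composition, diversity, and categorisation.

The quantification table is split into a *microbial* dataset (rows with
a superkingdom annotation other than Eukaryota) and a *human* dataset
(rows with genus Homo).  Rank-level compositions are abundance
proportions of each taxon within a sample; alpha diversity uses the
Shannon index H' = -sum p_i ln p_i, beta diversity the Bray-Curtis
dissimilarity with classical PCoA ordination.  Microbial taxa are
categorised against pathogen and gut annotation lists, and the human
dataset is intersected with disease-association accession lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .exceptions import ValidationError
from .io import AnnotationList
from .taxonomy import CANONICAL_RANKS

UNCLASSIFIED = "__unclassified__"


# ---------------------------------------------------------------------------
# dataset splits
# ---------------------------------------------------------------------------


def split_datasets(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a lineage-annotated quant table into microbial and human parts.

    Microbial: superkingdom annotated and not Eukaryota.  Human: genus
    annotated as Homo.  Rows with missing superkingdom fall in neither;
    no row can fall in both.
    """
    sk = table.get("superkingdom", pd.Series("", index=table.index)).fillna("")
    genus = table.get("genus", pd.Series("", index=table.index)).fillna("")
    microbial = table[(sk != "") & (sk != "Eukaryota")].reset_index(drop=True)
    human = table[genus == "Homo"].reset_index(drop=True)
    return microbial, human


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("area:")]


def composition(
    table: pd.DataFrame, rank: str, weight: str = "area"
) -> pd.DataFrame:
    """Per-sample proportional abundance at a canonical rank.

    ``weight="area"`` aggregates per-sample top-3 areas; ``"count"``
    counts retained protein groups.  Proportions are normalised over
    rows classified at the rank; the unclassified mass fraction is
    reported in its own ``__unclassified__`` column, excluded from the
    normalisation.  Returns a samples x taxa DataFrame.
    """
    if rank not in CANONICAL_RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    if weight not in ("area", "count"):
        raise ValidationError(f"weight must be 'area' or 'count', got {weight!r}")
    cols = sample_columns(table)
    samples = [c[len("area:") :] for c in cols]
    taxa = sorted({t for t in table.get(rank, pd.Series(dtype=str)).fillna("") if t})
    out = pd.DataFrame(0.0, index=samples, columns=taxa + [UNCLASSIFIED])
    for col, sample in zip(cols, samples):
        weights = table[col] if weight == "area" else (table[col] > 0).astype(float)
        labels = table.get(rank, pd.Series("", index=table.index)).fillna("")
        totals = weights.groupby(labels.values).sum()
        classified = totals.drop("", errors="ignore")
        total_classified = classified.sum()
        total_all = totals.sum()
        if total_classified > 0:
            for taxon, value in classified.items():
                out.loc[sample, taxon] = value / total_classified
        out.loc[sample, UNCLASSIFIED] = (
            (total_all - total_classified) / total_all if total_all > 0 else 0.0
        )
    return out


def drop_unclassified(comp: pd.DataFrame) -> pd.DataFrame:
    return comp.drop(columns=[UNCLASSIFIED], errors="ignore")


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def shannon(proportions: Sequence[float] | pd.Series) -> float:
    """Shannon index H' = -sum p_i ln p_i, with 0 ln 0 = 0."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative proportion")
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_per_sample(comp: pd.DataFrame) -> pd.Series:
    comp = drop_unclassified(comp)
    return pd.Series(
        {sample: shannon(comp.loc[sample]) for sample in comp.index}, name="shannon"
    )


def bray_curtis(comp: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity on a common taxon universe."""
    comp = drop_unclassified(comp)
    samples = list(comp.index)
    values = comp.to_numpy(dtype=float)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if values[i].sum() == 0 and values[j].sum() == 0:
                d = 0.0
            else:
                d = float(braycurtis(values[i], values[j]))
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=samples, columns=samples)


@dataclass
class OrdinationResult:
    """PCoA coordinates with the underlying eigenvalues."""

    coordinates: pd.DataFrame  # samples x k axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray


def pcoa(dissimilarity: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Classical (Torgerson) principal coordinate analysis.

    Keeps the top-``k`` axes with non-negative eigenvalues; axes with
    negative eigenvalues (non-Euclidean input) are reported in the
    eigenvalue vector but never embedded.
    """
    n = len(dissimilarity)
    if k >= n:
        raise ValidationError(f"k={k} must be < number of samples ({n})")
    dm = DistanceMatrix(dissimilarity.to_numpy(dtype=float), ids=[str(s) for s in dissimilarity.index])
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=n)
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    keep = min(k, int((eig > -1e-12).sum()))
    axes = [f"PC{i + 1}" for i in range(keep)]
    coordinates = pd.DataFrame(
        coords[:, :keep], index=dissimilarity.index, columns=axes
    )
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.to_numpy(),
    )


# ---------------------------------------------------------------------------
# categorisation
# ---------------------------------------------------------------------------

CATEGORIES = ("pathogen", "gut", "both", "other")


def categorize_microbes(
    comp: pd.DataFrame,
    pathogen_list: AnnotationList,
    gut_list: AnnotationList,
) -> pd.DataFrame:
    """Abundance-weighted pathogen/gut/both/other fractions per sample.

    Each taxon is assigned to exactly one category; taxa in both lists
    are "both" (checked first).  Fractions are over classified mass and
    sum to 1 per sample.
    """
    comp = drop_unclassified(comp)
    assignment = {}
    for taxon in comp.columns:
        in_p = taxon in pathogen_list.members
        in_g = taxon in gut_list.members
        if in_p and in_g:
            assignment[taxon] = "both"
        elif in_p:
            assignment[taxon] = "pathogen"
        elif in_g:
            assignment[taxon] = "gut"
        else:
            assignment[taxon] = "other"
    out = pd.DataFrame(0.0, index=comp.index, columns=list(CATEGORIES))
    for taxon, cat in assignment.items():
        out[cat] += comp[taxon]
    # renormalise in case the composition rows do not sum exactly to 1
    sums = out.sum(axis=1)
    nonzero = sums > 0
    out.loc[nonzero] = out.loc[nonzero].div(sums[nonzero], axis=0)
    return out


def strip_cluster_prefix(accession: str) -> str:
    """UniRef90_P12345 -> P12345; bare accessions pass through."""
    return accession.split("_", 1)[1] if accession.startswith("UniRef") else accession


def disease_associations(
    human: pd.DataFrame, disease_lists: Sequence[AnnotationList]
) -> pd.Series:
    """Per-disease count of retained human groups whose representative is listed.

    One protein may count toward several diseases.  Accessions are
    compared after stripping any UniRef cluster prefix.
    """
    accs = {strip_cluster_prefix(a) for a in human.get("representative", pd.Series(dtype=str))}
    counts = {}
    for lst in disease_lists:
        if lst.level != "protein_accession":
            raise ValidationError(f"list {lst.list_name} is not accession-level")
        members = {strip_cluster_prefix(m) for m in lst.members}
        counts[lst.list_name] = len(accs & members)
    return pd.Series(counts, name="n_proteins", dtype=int)


def normalize_heatmap(
    human: pd.DataFrame, reference_sample: str | None = None
) -> pd.DataFrame:
    """Per-sample percent-of-total matrix of human protein abundances.

    Each column (sample) is normalised to 100%; rows (proteins, keyed by
    representative accession) are sorted by ascending abundance in the
    reference sample (the first sample column by default).
    """
    if len(human) == 0:
        raise ValidationError("human table is empty")
    cols = sample_columns(human)
    mat = human.set_index("representative")[cols]
    mat.columns = [c[len("area:") :] for c in cols]
    sums = mat.sum(axis=0)
    mat = mat.div(sums.where(sums > 0, 1.0), axis=1) * 100.0
    ref = reference_sample if reference_sample is not None else mat.columns[0]
    if ref not in mat.columns:
        raise ValidationError(f"reference sample {ref!r} not in table")
    return mat.sort_values(ref, ascending=True, kind="mergesort")
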