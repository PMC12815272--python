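"""Seeded synthetic fixtures with known ground truth.

The generator emulates the study design the pipeline targets: influent
wastewater from two sites sampled at five time points in duplicate, a
community of microbial families (gut and environmental) plus plant and
animal food-residue families and free human proteins, and de novo
peptide reads carrying ALC confidence noise and occasional single-residue
sequence errors.

Everything is deterministic under the configured seed: the taxonomy dump,
the reference FASTA files, every per-sample read CSV, and the ground
truth that records each read's source protein.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import yaml

from .exceptions import ConfigError
from .io import (
    AnnotationList,
    DeNovoRead,
    ProteinRecord,
    write_denovo_csv,
    write_uniref_fasta,
)
from .peptides import digest
from .taxonomy import TaxonNode, TaxonomyStore

# K/R boosted so tryptic peptides of useful length exist; J never occurs
# in the standard alphabet, so canonicalization cannot collide with it.
_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_WEIGHTS = np.array(
    [1.0 if aa not in "KR" else 2.2 for aa in _ALPHABET]
)
_AA_PROBS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 20 taxonomic families across
    bacteria, plants, food animals and Hominidae; two sites sampled at
    five time points in duplicate; reads drawn from tryptic peptides
    with ALC scores from a high-confidence distribution for correct
    calls and a lower, wider one for errorful calls.
    """

    seed: int = 0
    n_families: int = 20
    n_plant_families: int = 3
    n_animal_families: int = 2
    proteins_per_family: tuple[int, int] = (5, 15)
    n_human_proteins: int = 30
    protein_length: tuple[int, int] = (100, 600)
    community_mu: float = 0.0
    community_sigma: float = 1.0
    timepoint_sigma: float = 0.3
    reads_per_sample: int = 600
    area_scale: float = 1e9
    area_noise_sigma: float = 0.5
    alc_correct: tuple[float, float] = (85.0, 5.0)
    alc_incorrect: tuple[float, float] = (65.0, 10.0)
    error_rate: float = 0.0
    n_sites: int = 2
    n_timepoints: int = 5
    n_replicates: int = 2
    n_entrapment_families: int = 5
    sites: tuple[str, ...] = ("HP", "UT")

    def __post_init__(self):
        if self.n_families < self.n_plant_families + self.n_animal_families + 2:
            raise ConfigError("n_families too small for the plant/animal/Homo layout")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigError("error_rate must be in [0, 1]")
        for name in ("n_families", "n_human_proteins", "reads_per_sample",
                     "n_sites", "n_timepoints", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.sites) < self.n_sites:
            object.__setattr__(
                self, "sites",
                tuple(self.sites) + tuple(
                    f"S{i}" for i in range(len(self.sites), self.n_sites)
                ),
            )

    def sample_ids(self) -> list[str]:
        return [
            f"{self.sites[s]}{t + 1}-{r + 1}"
            for s in range(self.n_sites)
            for t in range(self.n_timepoints)
            for r in range(self.n_replicates)
        ]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("proteins_per_family", "protein_length", "alc_correct",
                    "alc_incorrect", "sites"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-sample truth: community, protein abundances, read provenance."""

    family_composition: dict[str, dict[int, float]] = field(default_factory=dict)
    protein_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    # per sample: list of (emitted peptide, source accession, is_error)
    read_provenance: dict[str, list[tuple[str, str, bool]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

ROOT_TAXID = 1
BACTERIA_TAXID = 2
EUKARYOTA_TAXID = 3


def make_taxonomy(config: SimulationConfig) -> TaxonomyStore:
    """Balanced synthetic taxonomy covering the configured families.

    Bacteria carries the microbial families (spread over phyla of about
    four families each); Eukaryota carries plant families under a
    Streptophyta-like phylum and animal families (including Hominidae
    with genus Homo and species Homo sapiens) under a Chordata-like
    phylum.  Exactly ``n_families`` family-rank nodes are created.
    """
    nodes = [
        TaxonNode(ROOT_TAXID, ROOT_TAXID, "no_rank", "root"),
        TaxonNode(BACTERIA_TAXID, ROOT_TAXID, "superkingdom", "Bacteria"),
        TaxonNode(EUKARYOTA_TAXID, ROOT_TAXID, "superkingdom", "Eukaryota"),
    ]
    next_id = 10

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        taxid = next_id
        next_id += 1
        nodes.append(TaxonNode(taxid, parent, rank, name))
        return taxid

    n_microbial = config.n_families - config.n_plant_families - config.n_animal_families - 1

    def add_family_chain(phylum: int, fam_name: str, genus_names: list[str],
                         species_per_genus: int = 1) -> int:
        cls = add(phylum, "class", f"{fam_name}_class")
        order = add(cls, "order", f"{fam_name}_order")
        fam = add(order, "family", fam_name)
        for gname in genus_names:
            genus = add(fam, "genus", gname)
            for s in range(species_per_genus):
                add(genus, "species", f"{gname} species{s + 1}")
        return fam

    # bacteria: phyla of up to 4 families
    fam_idx = 0
    while fam_idx < n_microbial:
        phylum = add(BACTERIA_TAXID, "phylum", f"Phylum_B{fam_idx // 4 + 1:02d}")
        for _ in range(min(4, n_microbial - fam_idx)):
            fam_idx += 1
            name = f"Bacterifamily_{fam_idx:02d}"
            add_family_chain(
                phylum, name,
                [f"{name}_genus{g}" for g in (1, 2)],
                species_per_genus=2,
            )

    plant_phylum = add(EUKARYOTA_TAXID, "phylum", "Streptophyta")
    for i in range(config.n_plant_families):
        name = f"Plantfamily_{i + 1:02d}"
        add_family_chain(plant_phylum, name, [f"{name}_genus1"], species_per_genus=1)

    animal_phylum = add(EUKARYOTA_TAXID, "phylum", "Chordata")
    for i in range(config.n_animal_families):
        name = f"Animalfamily_{i + 1:02d}"
        add_family_chain(animal_phylum, name, [f"{name}_genus1"], species_per_genus=1)

    # Hominidae under the animal phylum
    cls = add(animal_phylum, "class", "Mammalia")
    order = add(cls, "order", "Primates")
    fam = add(order, "family", "Hominidae")
    genus = add(fam, "genus", "Homo")
    add(genus, "species", "Homo sapiens")

    return TaxonomyStore(nodes)


def write_taxdump(store: TaxonomyStore, nodes_path: str | Path, names_path: str | Path) -> None:
    """Write the store in the NCBI pipe-and-tab dump dialect."""
    ordered = sorted(store, key=lambda n: n.taxid)
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for n in ordered:
            fh.write(f"{n.taxid}\t|\t{n.parent_taxid}\t|\t{n.rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for n in ordered:
            fh.write(f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# reference proteome
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, config: SimulationConfig) -> str:
    """One random sequence guaranteed to yield >=2 tryptic peptides >=6 aa."""
    lo, hi = config.protein_length
    while True:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_ALPHABET, size=length, p=_AA_PROBS))
        if len(digest(seq, 0, 6, 50)) >= 2:
            return seq


def _family_species(store: TaxonomyStore, family_taxid: int) -> list[int]:
    return sorted(
        t
        for t in store.taxids_at_rank("species")
        if store.lineage(t).taxid_at("family") == family_taxid
    )


@dataclass
class Reference:
    """Generated global reference plus the human supplement subset."""

    records: list[ProteinRecord]
    human_records: list[ProteinRecord]
    family_of: dict[str, int]  # accession -> family taxid


def make_reference(config: SimulationConfig, store: TaxonomyStore) -> Reference:
    """Random proteins for every community family, with UniRef headers.

    Human proteins (accessions ``UniRef90_HUMnnnn``, species Homo
    sapiens) are part of the global reference and also returned
    separately as the human-proteome supplement used in round 2.
    """
    rng = np.random.default_rng([config.seed, 1])
    records: list[ProteinRecord] = []
    family_of: dict[str, int] = {}
    families = sorted(store.taxids_at_rank("family"))
    lo, hi = config.proteins_per_family
    counter = 0
    human_records: list[ProteinRecord] = []
    for fam in families:
        fam_name = store.name_of(fam)
        species = _family_species(store, fam)
        if fam_name == "Hominidae":
            n = config.n_human_proteins
        else:
            n = int(rng.integers(lo, hi + 1))
        for i in range(n):
            counter += 1
            taxid = int(species[int(rng.integers(len(species)))])
            if fam_name == "Hominidae":
                acc = f"UniRef90_HUM{i + 1:04d}"
            else:
                acc = f"UniRef90_P{counter:05d}"
            rec = ProteinRecord(
                accession=acc,
                description=(
                    f"Synthetic protein {counter} n=1 "
                    f"Tax={store.name_of(taxid)} TaxID={taxid} RepID=SYN{counter}"
                ),
                taxid=taxid,
                sequence=_random_protein(rng, config),
            )
            records.append(rec)
            family_of[acc] = fam
            if fam_name == "Hominidae":
                human_records.append(rec)
    return Reference(records=records, human_records=human_records, family_of=family_of)


def make_entrapment(config: SimulationConfig, store: TaxonomyStore) -> list[ProteinRecord]:
    """Proteins from families guaranteed absent from every community.

    Entrapment records carry reserved taxids (>= 900000) that are not in
    the taxonomy store at all, so no focused or community computation
    can ever select them; they enter searches only as tagged spike-ins.
    """
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.proteins_per_family
    records = []
    counter = 0
    for f in range(config.n_entrapment_families):
        taxid = 900000 + f
        assert taxid not in store
        for _ in range(int(rng.integers(lo, hi + 1))):
            counter += 1
            records.append(
                ProteinRecord(
                    accession=f"UniRef90_TRAP{counter:04d}",
                    description=(
                        f"Entrapment protein {counter} n=1 "
                        f"Tax=Trapfamily_{f + 1:02d} TaxID={taxid} RepID=TRP{counter}"
                    ),
                    taxid=taxid,
                    sequence=_random_protein(rng, config),
                )
            )
    return records


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------


def _truncnorm(rng: np.random.Generator, mu: float, sigma: float,
               lo: float = 0.0, hi: float = 100.0) -> float:
    while True:
        x = rng.normal(mu, sigma)
        if lo <= x <= hi:
            return float(x)


def simulate_sample(
    config: SimulationConfig,
    reference: Reference,
    store: TaxonomyStore,
    site_idx: int,
    timepoint: int,
    replicate: int,
    site_family_logabund: dict[int, float],
    truth: GroundTruth,
) -> list[DeNovoRead]:
    """Emit one sample's de novo reads and record their ground truth.

    The community is shared between the duplicates of one site x time
    point (they model aliquots of the same influent); read sampling and
    noise are independent per replicate.
    """
    sample_id = f"{config.sites[site_idx]}{timepoint + 1}-{replicate + 1}"
    families = sorted(site_family_logabund)

    # community for this site x timepoint (replicates share it)
    rng_comm = np.random.default_rng([config.seed, 3, site_idx, timepoint])
    log_abund = np.array(
        [
            site_family_logabund[f] + rng_comm.normal(0.0, config.timepoint_sigma)
            for f in families
        ]
    )
    fam_abund = np.exp(log_abund)
    fam_abund /= fam_abund.sum()

    by_family: dict[int, list[ProteinRecord]] = {f: [] for f in families}
    for rec in reference.records:
        by_family[reference.family_of[rec.accession]].append(rec)

    prot_records: list[ProteinRecord] = []
    prot_abund: list[float] = []
    for f, p_fam in zip(families, fam_abund):
        members = by_family[f]
        within = rng_comm.dirichlet(np.ones(len(members)))
        for rec, w in zip(members, within):
            prot_records.append(rec)
            prot_abund.append(p_fam * w)
    prot_abund_arr = np.array(prot_abund)
    prot_abund_arr /= prot_abund_arr.sum()

    truth.family_composition[sample_id] = dict(zip(families, map(float, fam_abund)))
    truth.protein_abundance[sample_id] = {
        rec.accession: float(a) for rec, a in zip(prot_records, prot_abund_arr)
    }

    # per-replicate read sampling
    rng = np.random.default_rng([config.seed, 4, site_idx, timepoint, replicate])
    peptide_pools = [digest(rec.sequence, 1, 6, 50) for rec in prot_records]
    choices = rng.choice(len(prot_records), size=config.reads_per_sample, p=prot_abund_arr)
    reads: list[DeNovoRead] = []
    provenance: list[tuple[str, str, bool]] = []
    for idx in choices:
        rec = prot_records[idx]
        pool = peptide_pools[idx]
        pep = pool[int(rng.integers(len(pool)))]
        is_error = bool(rng.random() < config.error_rate)
        if is_error:
            pos = int(rng.integers(len(pep)))
            current = pep[pos]
            # I<->L swaps are invisible after canonicalization, so they
            # would not constitute a sequence error; exclude them.
            forbidden = "IL" if current in "IL" else current
            options = [aa for aa in _ALPHABET if aa not in forbidden]
            pep = pep[:pos] + options[int(rng.integers(len(options)))] + pep[pos + 1 :]
            alc = _truncnorm(rng, *config.alc_incorrect)
        else:
            alc = _truncnorm(rng, *config.alc_correct)
        area = (
            prot_abund_arr[idx]
            * config.area_scale
            * float(np.exp(rng.normal(0.0, config.area_noise_sigma)))
        )
        reads.append(DeNovoRead(peptide=pep, alc=alc, area=area, sample_id=sample_id))
        provenance.append((pep, rec.accession, is_error))
    truth.read_provenance[sample_id] = provenance
    return reads


def simulate_study(
    config: SimulationConfig,
    reference: Reference,
    store: TaxonomyStore,
) -> tuple[dict[str, list[DeNovoRead]], GroundTruth]:
    """All samples of the configured design (sites x time points x replicates)."""
    families = sorted(store.taxids_at_rank("family"))
    truth = GroundTruth()
    samples: dict[str, list[DeNovoRead]] = {}
    for s in range(config.n_sites):
        rng_site = np.random.default_rng([config.seed, 5, s])
        site_base = {
            f: float(rng_site.normal(config.community_mu, config.community_sigma))
            for f in families
        }
        for t in range(config.n_timepoints):
            for r in range(config.n_replicates):
                reads = simulate_sample(config, reference, store, s, t, r, site_base, truth)
                samples[reads[0].sample_id] = reads
    return samples, truth


# ---------------------------------------------------------------------------
# annotation lists for the categorisation stages
# ---------------------------------------------------------------------------


def make_annotation_lists(
    config: SimulationConfig,
    store: TaxonomyStore,
    reference: Reference,
) -> dict[str, AnnotationList]:
    """Deterministic pathogen/gut genus lists and disease accession lists.

    A third of the bacterial genera are marked gut-associated, a quarter
    pathogen-associated, with deliberate overlap so every category of
    the pathogen/gut/both/other split is populated.  Three synthetic
    disease lists draw from the human protein accessions.
    """
    rng = np.random.default_rng([config.seed, 6])
    genera = sorted(
        store.name_of(t)
        for t in store.taxids_at_rank("genus")
        if store.lineage(t).taxid_at("superkingdom") == BACTERIA_TAXID
    )
    n = len(genera)
    perm = [genera[i] for i in rng.permutation(n)]
    gut = set(perm[: max(2, n // 3)])
    pathogen = set(perm[n // 4 : n // 4 + max(2, n // 4)])
    human_accs = sorted(r.accession for r in reference.human_records)
    k = max(2, len(human_accs) // 5)
    lists = {
        "gut_genera": AnnotationList("gut_genera", "genus", frozenset(gut)),
        "pathogen_genera": AnnotationList("pathogen_genera", "genus", frozenset(pathogen)),
    }
    for i, disease in enumerate(("breast_cancer", "diabetic_nephropathy", "ibd")):
        members = [human_accs[j] for j in np.random.default_rng(
            [config.seed, 7, i]).permutation(len(human_accs))[:k]]
        lists[disease] = AnnotationList(disease, "protein_accession", frozenset(members))
    return lists


def write_annotation_tsv(lists: dict[str, AnnotationList], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("list_name\tlevel\tmember\n")
        for name in sorted(lists):
            lst = lists[name]
            for member in sorted(lst.members):
                fh.write(f"{lst.list_name}\t{lst.level}\t{member}\n")


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------


def write_fixture_dir(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate and write the complete fixture tree; returns the directory.

    Layout: ``nodes.dmp``/``names.dmp``, ``global.fasta``,
    ``human.fasta``, ``entrapment.fasta``, ``annotations.tsv``,
    ``samples/<sample_id>.csv``, ``truth/`` TSVs, and ``config.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    store = make_taxonomy(config)
    write_taxdump(store, outdir / "nodes.dmp", outdir / "names.dmp")
    reference = make_reference(config, store)
    write_uniref_fasta(reference.records, outdir / "global.fasta")
    write_uniref_fasta(reference.human_records, outdir / "human.fasta")
    write_uniref_fasta(make_entrapment(config, store), outdir / "entrapment.fasta")
    write_annotation_tsv(
        make_annotation_lists(config, store, reference), outdir / "annotations.tsv"
    )
    samples, truth = simulate_study(config, reference, store)
    sample_dir = outdir / "samples"
    sample_dir.mkdir(exist_ok=True)
    for sample_id in sorted(samples):
        write_denovo_csv(samples[sample_id], sample_dir / f"{sample_id}.csv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    with open(truth_dir / "family_composition.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tfamily_taxid\tproportion\n")
        for sid in sorted(truth.family_composition):
            for fam, p in sorted(truth.family_composition[sid].items()):
                fh.write(f"{sid}\t{fam}\t{p:.10g}\n")
    with open(truth_dir / "read_provenance.tsv", "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpeptide\tsource_accession\tis_error\n")
        for sid in sorted(truth.read_provenance):
            for pep, acc, err in truth.read_provenance[sid]:
                fh.write(f"{sid}\t{pep}\t{acc}\t{int(err)}\n")
    config.to_yaml(outdir / "config.yaml")
    return outdir
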