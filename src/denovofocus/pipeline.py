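"""End-to-end pipeline driver: profile -> focus -> search -> quantify -> analyze.

Each stage logs its input/output record counts to stderr and writes its
report tables into the configured output directory with deterministic
formatting, so identical inputs always yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd
import yaml

from . import community, quant, search
from .exceptions import ConfigError, DenovoFocusError
from .focusdb import select_by_family
from .io import (
    AnnotationList,
    DeNovoRead,
    ProteinRecord,
    parse_annotation_tsv,
    parse_denovo_csv,
    parse_uniref_fasta,
    write_report_tsv,
)
from .profiler import FamilyProfile, filter_alc, profile_sample
from .peptides import DigestionParams, PeptideIndex
from .taxonomy import TaxonomyStore

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Threshold defaults carry the pipeline's operating point: ALC >= 70
    for profiling, one missed cleavage in round 1 and up to three in
    round 2, 5% match-level FDR, and the post-identification filter of
    >=2 unique peptides and an overall top-3 area > 5e5.
    """

    taxonomy_nodes: str = ""
    taxonomy_names: str = ""
    global_fasta: str = ""
    human_fasta: str = ""
    sample_csvs: list[str] = field(default_factory=list)
    annotations: str = ""
    entrapment_fasta: str = ""
    output_dir: str = "results"

    alc: float = 70.0
    min_family_peptides: int = 2
    fdr_alpha: float = 0.05
    min_unique: int = 2
    min_overall_area: float = 5e5
    mc_round1: int = 1
    mc_round2: int = 3
    max_subs: int = 0
    min_len: int = 6
    max_len: int = 50
    heatmap_reference: str = ""
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alc <= 100:
            raise ConfigError("alc must be in [0, 100]")
        if not 0 < self.fdr_alpha <= 1:
            raise ConfigError("fdr_alpha must be in (0, 1]")
        if self.max_subs not in (0, 1):
            raise ConfigError("max_subs must be 0 or 1")
        for name in ("min_family_peptides", "min_unique", "mc_round1", "mc_round2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def for_fixture_dir(cls, fixture_dir: str | Path, output_dir: str | Path,
                        **overrides) -> "PipelineConfig":
        """Point a config at a directory written by the fixture generator."""
        d = Path(fixture_dir)
        return cls(
            taxonomy_nodes=str(d / "nodes.dmp"),
            taxonomy_names=str(d / "names.dmp"),
            global_fasta=str(d / "global.fasta"),
            human_fasta=str(d / "human.fasta"),
            sample_csvs=sorted(str(p) for p in (d / "samples").glob("*.csv")),
            annotations=str(d / "annotations.tsv") if (d / "annotations.tsv").exists() else "",
            entrapment_fasta=str(d / "entrapment.fasta") if (d / "entrapment.fasta").exists() else "",
            output_dir=str(output_dir),
            **overrides,
        )


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: PipelineConfig
    store: TaxonomyStore
    profiles: dict[str, FamilyProfile]
    search_results: dict[str, search.SearchResult]
    quant_table: pd.DataFrame
    filtered_table: pd.DataFrame
    microbial: pd.DataFrame
    human: pd.DataFrame
    compositions: dict[str, pd.DataFrame]
    shannon: pd.Series
    dissimilarity: pd.DataFrame
    ordination: community.OrdinationResult | None
    categories: pd.DataFrame | None
    disease_counts: pd.Series | None
    stage_counts: dict[str, int]


def _stage(name: str, count: int, counts: dict[str, int]) -> None:
    counts[name] = count
    logger.info("stage %s: %d records", name, count)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all report tables."""
    counts: dict[str, int] = {}
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------
    try:
        store = TaxonomyStore.from_taxdump(config.taxonomy_nodes, config.taxonomy_names)
    except (OSError, DenovoFocusError) as exc:
        raise DenovoFocusError(f"stage profile: cannot load taxonomy: {exc}") from exc
    global_records = parse_uniref_fasta(config.global_fasta)
    human_records = parse_uniref_fasta(config.human_fasta) if config.human_fasta else []
    _stage("reference", len(global_records), counts)
    taxid_of = {r.accession: r.taxid for r in global_records + human_records}

    samples: dict[str, list[DeNovoRead]] = {}
    for path in config.sample_csvs:
        reads = parse_denovo_csv(path)
        sid = reads[0].sample_id if reads else Path(path).stem
        samples[sid] = reads
    _stage("reads_total", sum(len(v) for v in samples.values()), counts)

    # ---- stage 1: ALC filter + profiling ----------------------------
    global_index = PeptideIndex.build(
        global_records, DigestionParams(config.mc_round1, config.min_len, config.max_len)
    )
    profiles: dict[str, FamilyProfile] = {}
    filtered_reads: dict[str, list[DeNovoRead]] = {}
    for sid, reads in samples.items():
        kept = filter_alc(reads, config.alc)
        filtered_reads[sid] = kept
        profiles[sid] = profile_sample(
            kept, global_index, store, config.min_family_peptides, sample_id=sid
        )
    _stage("reads_alc_filtered", sum(len(v) for v in filtered_reads.values()), counts)
    profile_frames = [p.to_frame(store) for p in profiles.values()]
    write_report_tsv(
        pd.concat(profile_frames, ignore_index=True)
        if profile_frames
        else pd.DataFrame(columns=["sample_id", "family_taxid", "family_name", "peptide_count", "area"]),
        outdir / "family_profiles.tsv",
        sort_by=["sample_id", "family_taxid"],
    )

    # ---- stages 2+3: focusing and two-round search ------------------
    results: dict[str, search.SearchResult] = {}
    psm_rows = []
    for sid in sorted(samples):
        families = profiles[sid].identified_families()
        focused = select_by_family(global_records, families, store, sample_id=sid)
        peptides = search.as_sample_peptides(filtered_reads[sid])
        if not focused.records:
            logger.warning("sample %s: empty focused database, skipping search", sid)
            continue
        result = search.two_round_search(
            peptides,
            focused,
            human_records,
            mc_round1=config.mc_round1,
            mc_round2=config.mc_round2,
            max_subs=config.max_subs,
            alpha=config.fdr_alpha,
            min_len=config.min_len,
            max_len=config.max_len,
        )
        results[sid] = result
        for m in result.matches:
            psm_rows.append(
                {
                    "sample_id": sid,
                    "peptide": m.peptide,
                    "accessions": ";".join(sorted(m.accessions)),
                    "label": m.label,
                    "score": m.score,
                    "area": m.area,
                }
            )
    _stage("psms_surviving", len(psm_rows), counts)
    write_report_tsv(
        pd.DataFrame(psm_rows, columns=["sample_id", "peptide", "accessions", "label", "score", "area"]),
        outdir / "psms.tsv",
        sort_by=["sample_id", "peptide", "accessions"],
    )

    # ---- stage 4: combined quantification ---------------------------
    protein_peptides: dict[str, set[str]] = {}
    peptide_areas: dict[str, dict[str, float]] = {}
    for sid, result in results.items():
        areas = peptide_areas.setdefault(sid, {})
        for m in result.matches:
            areas[m.peptide] = areas.get(m.peptide, 0.0) + m.area
        for acc, peps in result.protein_peptides.items():
            protein_peptides.setdefault(acc, set()).update(peps)
    groups = quant.group_proteins(protein_peptides) if protein_peptides else []
    quant_table = (
        quant.build_quant_table(groups, peptide_areas, store, lambda a: taxid_of.get(a))
        if groups
        else pd.DataFrame()
    )
    _stage("protein_groups", len(quant_table), counts)
    write_report_tsv(quant_table, outdir / "protein_groups.tsv")
    filtered = (
        quant.apply_paper_filters(quant_table, config.min_unique, config.min_overall_area)
        if len(quant_table)
        else quant_table
    )
    _stage("protein_groups_filtered", len(filtered), counts)
    write_report_tsv(filtered, outdir / "protein_groups_filtered.tsv")

    # ---- stage 5: splits, composition, diversity, categorisation ----
    microbial, human = community.split_datasets(filtered) if len(filtered) else (filtered, filtered)
    _stage("microbial_groups", len(microbial), counts)
    _stage("human_groups", len(human), counts)
    write_report_tsv(microbial, outdir / "microbial.tsv")
    write_report_tsv(human, outdir / "human.tsv")

    compositions: dict[str, pd.DataFrame] = {}
    shannon = pd.Series(dtype=float, name="shannon")
    dissim = pd.DataFrame()
    ordination = None
    categories = None
    disease_counts = None
    if len(microbial):
        for rank in ("phylum", "family", "genus"):
            comp = community.composition(microbial, rank, weight="area")
            compositions[rank] = comp
            write_report_tsv(
                comp.reset_index(names="sample_id"), outdir / f"composition_{rank}.tsv"
            )
        genus_comp = compositions["genus"]
        shannon = community.shannon_per_sample(genus_comp)
        write_report_tsv(
            shannon.rename_axis("sample_id").reset_index(), outdir / "shannon.tsv"
        )
        dissim = community.bray_curtis(genus_comp)
        write_report_tsv(
            dissim.reset_index(names="sample_id"), outdir / "bray_curtis.tsv"
        )
        if len(dissim) > 2:
            ordination = community.pcoa(dissim, k=2)
            write_report_tsv(
                ordination.coordinates.reset_index(names="sample_id"),
                outdir / "pcoa.tsv",
            )
        if config.annotations:
            lists = parse_annotation_tsv(config.annotations)
            if "pathogen_genera" in lists and "gut_genera" in lists:
                categories = community.categorize_microbes(
                    genus_comp, lists["pathogen_genera"], lists["gut_genera"]
                )
                write_report_tsv(
                    categories.reset_index(names="sample_id"), outdir / "categories.tsv"
                )
            disease_lists = [
                l for l in lists.values() if l.level == "protein_accession"
            ]
            if disease_lists and len(human):
                disease_counts = community.disease_associations(human, disease_lists)
                write_report_tsv(
                    disease_counts.rename_axis("disease").reset_index(),
                    outdir / "disease_counts.tsv",
                    sort_by=["disease"],
                )
    if len(human):
        ref = config.heatmap_reference or None
        heatmap = community.normalize_heatmap(human, ref)
        write_report_tsv(
            heatmap.reset_index(names="representative"), outdir / "heatmap.tsv"
        )

    _write_manifest(config, counts, outdir)
    return PipelineResult(
        config=config,
        store=store,
        profiles=profiles,
        search_results=results,
        quant_table=quant_table,
        filtered_table=filtered,
        microbial=microbial,
        human=human,
        compositions=compositions,
        shannon=shannon,
        dissimilarity=dissim,
        ordination=ordination,
        categories=categories,
        disease_counts=disease_counts,
        stage_counts=counts,
    )


def _write_manifest(config: PipelineConfig, counts: dict[str, int], outdir: Path) -> None:
    hashes = {}
    for path in sorted(outdir.glob("*.tsv")):
        hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "parameters": dataclasses.asdict(config),
        "stage_counts": counts,
        "output_hashes": hashes,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_entrapment(
    config: PipelineConfig, max_samples: int | None = None
) -> pd.DataFrame:
    """Entrapment evaluation across the configured samples.

    For each sample, the round-2 database is spiked with the entrapment
    proteins and the search rerun; the report aggregates per-sample hit
    fractions next to the search's own FDR estimates.
    """
    if not config.entrapment_fasta:
        raise ConfigError("entrapment_fasta is required for entrapment evaluation")
    store = TaxonomyStore.from_taxdump(config.taxonomy_nodes, config.taxonomy_names)
    global_records = parse_uniref_fasta(config.global_fasta)
    human_records = parse_uniref_fasta(config.human_fasta) if config.human_fasta else []
    entrapment_records = parse_uniref_fasta(config.entrapment_fasta)
    global_index = PeptideIndex.build(
        global_records, DigestionParams(config.mc_round1, config.min_len, config.max_len)
    )
    paths = config.sample_csvs[:max_samples] if max_samples else config.sample_csvs
    if not paths:
        raise ConfigError("no samples configured")
    rows = []
    for path in paths:
        reads = filter_alc(parse_denovo_csv(path), config.alc)
        sid = reads[0].sample_id if reads else Path(path).stem
        profile = profile_sample(
            reads, global_index, store, config.min_family_peptides, sample_id=sid
        )
        focused = select_by_family(
            global_records, profile.identified_families(), store, sample_id=sid
        )
        if not focused.records:
            continue
        peptides = search.as_sample_peptides(reads)
        hits = search.round1(peptides, focused, config.mc_round1, config.min_len, config.max_len)
        db2 = search.build_round2_db(hits, focused, human_records)
        report = search.entrapment_eval(
            peptides,
            db2,
            entrapment_records,
            config.mc_round2,
            config.max_subs,
            config.fdr_alpha,
            config.min_len,
            config.max_len,
        )
        rows.append(
            {
                "sample_id": sid,
                "n_surviving": report.n_surviving,
                "n_entrapment_hits": report.n_entrapment_hits,
                "entrapment_fraction": report.entrapment_fraction,
                "estimated_fdr": report.estimated_fdr,
                "threshold_score": report.threshold_score,
            }
        )
    return pd.DataFrame(rows)
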