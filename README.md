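# denovofocus

De novo-guided focused database searching and community analysis for
metaproteomics of heterogeneous environmental samples, with raw
municipal wastewater as the motivating application.

Wastewater carries proteins from environmental microbes, human gut
bacteria, plant and animal food residues, and freely dissolved human
proteins. Searching such data against a comprehensive reference
collection (UniRef90 scale) is slow and insensitive, because the vast
majority of candidate sequences come from organisms that are not in the
sample. `denovofocus` implements the alternative: use de novo peptide
reads to work out *which taxonomic families are present*, search only
their reference entries, and control errors with target-decoy FDR and
entrapment spike-ins.

The pipeline stages:

1. **Profile** — de novo reads with ALC ≥ 70 are matched (exact,
   I/L-canonicalized) against a tryptic index of the global reference;
   each peptide gets the lowest common ancestor (LCA) of its matching
   taxa, and families with ≥ 2 family-resolving peptides are identified.
2. **Focus** — all global entries of the identified families form the
   per-sample focused database.
3. **Search** — a two-round search: round 1 (1 missed cleavage, no
   score cut-off) collects candidate proteins; candidates plus the
   human reference proteome are searched in round 2 (≤ 3 missed
   cleavages), filtered to a 5% match-level FDR against reversed
   decoys; proteins with ≥ 2 unique peptides are significant.
4. **Quantify** — parsimony protein grouping and top-3 peptide-area
   quantification; groups are kept with ≥ 2 unique peptides and an
   overall top-3 area > 5·10⁵, represented by their top hit.
5. **Analyze** — microbial/human dataset splits, rank-level
   composition, Shannon diversity (H′ = −Σ pᵢ ln pᵢ), Bray–Curtis
   dissimilarity with classical PCoA, pathogen/gut categorisation, and
   disease-list association counts.

A seeded synthetic-fixture generator reproduces the emulated study
design (two sites × five time points × duplicates) with full ground
truth — every read is traceable to its source protein — so each stage
is testable end to end. See `docs/methods.md` for the model, the
parameter defaults and their rationale, and known limitations.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
denovofocus simulate --out demo_fx --seed 1
denovofocus run --fixtures demo_fx --out demo_out --seed 1
```

The run prints its per-stage record counts:

```
reference       228
reads_total     12000
reads_alc_filtered      11983
psms_surviving  11979
protein_groups  228
protein_groups_filtered 228
microbial_groups        141
human_groups    30
```

Reading: the fixture reference holds 228 proteins across 20 families;
of 12 000 de novo reads, 11 983 pass the ALC ≥ 70 filter and 11 979
survive the 5% FDR cut in round 2 (the fixture is error-free, so almost
every read is a confident, correct match). All 228 proteins are
recovered as groups and pass the abundance filter; the lineage split
assigns 141 groups to the microbial dataset and 30 to the human
dataset (the remainder are non-human eukaryotes: plant and animal food
residues).

`demo_out/` then contains the report tables, e.g. genus-level alpha
diversity per sample:

```
$ head -4 demo_out/shannon.tsv
sample_id       shannon
HP1-1   2.70237
HP1-2   2.62404
HP2-1   2.73932
```

and the disease-association counts over the human dataset:

```
$ head -3 demo_out/disease_counts.tsv
disease n_proteins
breast_cancer   6
diabetic_nephropathy    6
```

Other outputs include `composition_{phylum,family,genus}.tsv`,
`bray_curtis.tsv`, `pcoa.tsv`, `categories.tsv` (pathogen / gut / both /
other fractions), `heatmap.tsv` (human proteins, per-sample percent of
total) and a `manifest.json` with parameters and output hashes. Reruns
on the same inputs are byte-identical.

The entrapment check — spiking the round-2 database with proteins from
families absent from the community — runs as:

```sh
denovofocus entrapment --fixtures demo_fx --out demo_out
```

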