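# Methods

`denovofocus` implements a sequence-level metaproteomics data-processing
pipeline for highly heterogeneous environmental samples — the motivating
use case is raw municipal wastewater, where proteins originate from
environmental and gut microbes, plant and animal food residues, and
freely dissolved human proteins. Searching such data directly against a
comprehensive reference collection (a UniRef90-scale database) is both
slow and insensitive; the pipeline instead uses de novo peptide reads to
*focus* the reference per sample before database searching.

## Pipeline model

**Stage 1 — taxonomic profiling of de novo reads.** De novo peptide
calls with an average local confidence (ALC) of at least 70% are
retained (the inequality is inclusive). Reads are canonicalized —
modification annotations stripped, I and L rewritten to the unused
letter J, since the two residues are isobaric and indistinguishable in
de novo calls — and merged per distinct peptide with areas summed.
Each peptide is matched exactly against an in silico tryptic index of
the global reference (one missed cleavage, peptide length 6–50), and
assigned the lowest common ancestor (LCA) of the taxa of all matching
records. A peptide contributes to a taxonomic family only when its LCA
lies at family rank or below; peptides resolving higher would otherwise
inflate every child family. Families supported by at least
`min_family_peptides` (default 2) distinct peptides are *identified*.
Requiring two peptides mirrors the two-unique-peptide rule used at the
protein level and suppresses families introduced by a single spurious
match.

**Stage 2 — focused database.** The per-sample focused database is the
set of global reference entries whose lineage passes through an
identified family. Membership is decided from the record's taxid via
the taxonomy store, not from any per-record family annotation, so the
store is the single source of truth. Records without a taxid cannot be
placed and are excluded from selection (but are never silently dropped
from parsing).

**Stage 3 — two-round search.** Round 1 matches the sample's peptides
exactly against the focused database digested with one missed cleavage
and collects every matched accession, with no score cut-off. These
candidates plus the human reference proteome supplement form the
round-2 database, which is digested with up to three missed cleavages.
Round 2 admits an optional single amino-acid substitution
(`max_subs=1`) to model de novo sequencing errors; the default for
error-free operation is exact matching. Matches are filtered by
target-decoy FDR at the match level: one reversed-sequence decoy per
target, FDR(s) = #decoys ≥ s / max(1, #targets ≥ s), capped at 1, no +1
correction; the admitted threshold is the lowest observed score whose
estimate is ≤ α (default 0.05), with ties at the threshold admitted.
Proteins are called significant when their protein group retains at
least two unique peptides among the surviving matches.

Because the engine operates on peptide sequences rather than spectra,
there is no spectral score; the read's ALC doubles as the match score.
Mass tolerances, fixed/variable modifications and retention-time
alignment are correspondingly out of scope.

**Stage 4 — grouping and quantification.** Proteins with identical
observed peptide sets merge; a protein whose set is a strict subset of
another's is subsumed into that group (parsimony-style). A subsumed
protein with several maximal supersets joins the smallest one, ties
broken on the sorted peptide tuple, making grouping independent of
input order. A peptide is *unique* when it occurs in exactly one
group's peptide set. Protein abundance per sample is the top-3 peptide
area (sum of the three largest peptide areas; all of them when fewer).
Shared peptides contribute their area to every group that contains them
— no razor assignment. The post-identification filter keeps groups
with ≥ 2 unique peptides (inclusive) and an overall across-sample
top-3 area strictly greater than 5·10⁵, then retains only each group's
representative ("top hit"): the member whose own peptide set
accumulates the largest overall top-3 area, ties by ascending
accession.

**Stage 5 — community analysis.** The filtered table splits into a
*microbial* dataset (superkingdom annotated and not Eukaryota) and a
*human* dataset (genus Homo); rows lacking a superkingdom fall in
neither, and the two can never overlap. Rank-level composition
aggregates per-sample top-3 areas (or group counts) by the
representative's lineage at the requested rank; proportions are
normalised over classified rows, with the unclassified mass reported
separately rather than silently folded in. Alpha diversity is the
Shannon index H′ = −Σ pᵢ ln pᵢ (natural log, 0·ln 0 = 0), beta
diversity the Bray–Curtis dissimilarity on genus-level compositions,
ordained by classical (Torgerson) PCoA — deterministic
double-centering and eigendecomposition rather than iterative MDS;
axes with negative eigenvalues are reported but never embedded.
Microbial taxa are categorised into pathogen-associated / gut / both /
other by membership in the two annotation lists, with "both" checked
first; disease associations count retained human groups whose
representative accession (UniRef cluster prefix stripped) appears in
each accession list. The human heatmap normalises each sample's summed
area to 100% and sorts proteins by ascending abundance in a reference
sample.

## Synthetic fixtures and what they do (not) show

The generator emulates the study design the pipeline targets: two sites
("HP", "UT") × five time points × duplicate aliquots, a community of 20
taxonomic families (14 bacterial across several phyla, 3 plant, 2 food
animal, and Hominidae carrying 30 human proteins), log-normal family
abundances (μ=0, σ=1) producing the skewed dominance structure typical
of such communities, per-site baselines with per-time-point jitter
(σ=0.3) so replicates cluster and sites separate in ordination, and
Dirichlet protein abundances within each family. Reads (600 per
sample) are drawn from proteins proportionally to abundance; each read
is a tryptic peptide (≤ 1 missed cleavage, length 6–50) with area ∝
abundance × log-normal noise. With probability `error_rate` a read
receives one random residue substitution (never I↔L, which would be
invisible after canonicalization) and an ALC drawn from Normal(65, 10)
truncated to [0, 100]; correct reads draw from Normal(85, 5). These
distributions place the ALC ≥ 70 filter where it removes most but not
all errorful reads. Protein sequences are uniform random draws over
the 20-residue alphabet with K/R frequency boosted (~10%) so tryptic
peptides of useful length exist; every record is regenerated until it
yields at least two peptides of length ≥ 6. The default error rate is
0 (the error channel is switched on explicitly where it is under
study). Entrapment records carry reserved taxids (≥ 900000) absent
from the taxonomy store, which guarantees they can never be selected
into a focused database or a community; they enter searches only as
tagged spike-ins.

Because the sequences are independent random strings, peptides are
essentially never shared across families, chance matches to decoys or
entrapment records are vanishingly rare, and LCA assignments are almost
always species-level. Real UniRef families share homologous peptides
across genera, so real profiles have more higher-rank LCA mass, more
protein-group ambiguity, and a non-trivial chance-match channel.
Passing tests therefore demonstrate the correctness of the pipeline's
logic under known ground truth, not its operating characteristics on
real wastewater data. A homology mode (families generated by mutating
an ancestral sequence) is the natural extension for more realistic LCA
and grouping behaviour.

## FDR evaluation semantics

A surviving match is counted as a *false assignment* when its matched
accession set does not contain the read's true source protein. Under
single-substitution matching, an errorful read usually still matches
its own source at Hamming distance 1 — the peptide sequence is wrong
but the protein inference is correct — so realized false-assignment
proportions sit far below the 5% control level, and the decoy-based
estimate agrees: with random-sequence databases at this scale both
chance matches and decoy hits are rare. The acceptance check is
therefore the control bound (mean realized proportion ≤ α + 2 binomial
standard errors) together with the entrapment cross-check (spike-in
hit fraction ≤ estimated FDR + binomial tolerance), not a two-sided
match to α; target-decoy FDR guarantees control, not exactness.

## Numerical and design choices

* Determinism everywhere: every generator stream is seeded through
  `numpy` `default_rng` with purpose-specific seed tuples, report rows
  carry stated sort keys, floats are written with 6 significant digits,
  and reruns produce byte-identical report directories.
* FDR estimator: plain decoy/target ratio without the +1 correction,
  ties at the threshold admitted. The correction is a documented,
  easily changed choice; at desk scale it is immaterial.
* Decoys: full sequence reversal — preserves length and composition
  and is the standard open scheme.
* Digestion bounds default to 6–50 residues, the typical detectable
  tryptic range.
* PCoA uses the eigendecomposition route from scikit-bio; Bray–Curtis
  uses the SciPy distance implementation. Two all-zero composition
  vectors are defined to have zero dissimilarity.
* Degenerate inputs: empty read lists profile to an empty family
  profile with a warning; an empty family set yields an empty focused
  database with a warning; searches against empty databases raise;
  `shannon` of an all-zero vector is 0.
* Problem sizes in tests and the acceptance script (20 families, ~230
  proteins, 20 samples × 600 reads) were chosen so the full suite
  completes in a few minutes while every family and protein count stays
  large enough for the recovery and calibration statistics to be
  meaningful.

## Known limitations

* No spectra: spectral scoring, mass tolerances, PTM localisation and
  retention-time alignment are out of scope by construction.
* No razor-peptide apportioning; shared peptide areas are counted once
  per containing group.
* Genus/species-level calling from de novo reads is not attempted; the
  profiler stops at family, which is what database focusing needs.
* The UniProt network fetch that a production focusing step might use
  is abstracted away; selection always runs against a local FASTA.
* Taxid merge/deletion handling across taxonomy versions is not
  implemented; input taxonomies must be self-consistent.
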