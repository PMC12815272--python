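"""Two-round search: candidate collection, decoys, FDR, significance."""

import pytest

from denovofocus.exceptions import (
    EmptyDatabaseError,
    EmptyInputError,
    ValidationError,
)
from denovofocus.focusdb import FocusedDatabase, select_by_family
from denovofocus.io import ProteinRecord
from denovofocus.peptides import DigestionParams, PeptideIndex, canonicalize, digest
from denovofocus import search
from denovofocus.search import (
    SamplePeptide,
    ScoredMatch,
    add_decoys,
    build_round2_db,
    estimate_fdr,
    make_decoys,
    round1,
    round2,
    single_round_search,
    two_round_search,
)


def sp(pep, area=10.0, score=90.0, read_id=-1):
    return SamplePeptide(pep, area, score, read_id)


@pytest.fixture(scope="module")
def focused(sim_store, sim_reference):
    families = sorted(sim_store.taxids_at_rank("family"))[:5]
    return select_by_family(sim_reference.records, set(families), sim_store, "S1")


class TestRound1:
    def test_unique_peptide_returns_its_protein(self, focused):
        rec = focused.records[0]
        pep = digest(rec.sequence, 0, 6, 50)[0]
        hits = round1([sp(pep)], focused)
        assert rec.accession in hits

    def test_no_match_returns_empty_with_warning(self, focused, caplog):
        with caplog.at_level("WARNING"):
            assert round1([sp("WWWWWWWWWW")], focused) == set()
        assert "matched no proteins" in caplog.text

    def test_empty_database_raises(self):
        with pytest.raises(EmptyDatabaseError):
            round1([sp("AAAAAK")], FocusedDatabase("S", []))

    def test_matches_per_peptide_lookup_oracle(self, focused, sim_study):
        samples, _ = sim_study
        reads = samples[sorted(samples)[0]][:300]
        peptides = [sp(r.peptide) for r in reads]
        hits = round1(peptides, focused)
        index = PeptideIndex.build(focused.records, DigestionParams(1, 6, 50))
        expected = set()
        for p in peptides:
            expected |= index.match(canonicalize(p.peptide))
        assert hits == expected


class TestRound2Db:
    def test_empty_hits_gives_human_only(self, focused, sim_reference):
        db2 = build_round2_db(set(), focused, sim_reference.human_records)
        assert db2.accessions == {r.accession for r in sim_reference.human_records}
        assert all(t == search.HUMAN_TAG for t in db2.supplement_tags.values())

    def test_all_hits_gives_union(self, focused, sim_reference):
        db2 = build_round2_db(focused.accessions, focused, sim_reference.human_records)
        expected = focused.accessions | {
            r.accession for r in sim_reference.human_records
        }
        assert db2.accessions == expected

    def test_foreign_hits_rejected(self, focused, sim_reference):
        with pytest.raises(ValidationError):
            build_round2_db({"NOT_THERE"}, focused, sim_reference.human_records)


class TestDecoys:
    def test_sequence_reversed_and_prefixed(self):
        db = FocusedDatabase("S", [ProteinRecord("P1", "", 1, "ABCK")])
        (decoy,) = make_decoys(db)
        assert decoy.accession == "DECOY_P1"
        assert decoy.sequence == "KCBA"

    def test_one_decoy_per_target(self, focused):
        assert len(make_decoys(focused)) == len(focused)

    def test_decoy_digest_differs_from_target(self, focused):
        for rec in focused.records[:20]:
            fwd = set(digest(rec.sequence, 1, 6, 50))
            rev = set(digest(rec.sequence[::-1], 1, 6, 50))
            assert fwd != rev


class TestEstimateFdr:
    @staticmethod
    def matches(targets, decoys):
        out = [
            ScoredMatch("PEPA", frozenset({"P"}), "target", s, 1.0) for s in targets
        ]
        out += [
            ScoredMatch("PEPB", frozenset({"DECOY_P"}), "decoy", s, 1.0) for s in decoys
        ]
        return out

    def test_threshold_excludes_decoy_region(self):
        threshold, survivors = estimate_fdr(
            self.matches([10, 9, 8, 7], [7.5]), alpha=0.05
        )
        assert threshold == 8
        assert sorted(m.score for m in survivors) == [8, 9, 10]

    def test_no_decoys_all_targets_survive(self):
        threshold, survivors = estimate_fdr(self.matches([5, 4, 3], []), 0.05)
        assert len(survivors) == 3

    def test_alpha_one_all_targets_survive(self):
        _, survivors = estimate_fdr(self.matches([5, 4], [6, 5, 4]), 1.0)
        assert len(survivors) == 2

    def test_no_targets_raises(self):
        with pytest.raises(EmptyInputError):
            estimate_fdr(self.matches([], [5]), 0.05)

    def test_survivors_monotone_in_alpha(self):
        ms = self.matches([10, 9, 8, 7, 6, 5], [8.5, 6.5, 5.5])
        prev: set[float] = set()
        for alpha in (0.05, 0.2, 0.5, 1.0):
            _, survivors = estimate_fdr(ms, alpha)
            scores = {m.score for m in survivors}
            assert prev <= scores
            prev = scores

    def test_exhaustive_threshold_scan_oracle(self):
        ms = self.matches([10, 9, 8, 7, 6, 5, 4], [9.5, 6.5, 4.5])
        alpha = 0.34
        candidates = []
        for s in sorted({m.score for m in ms}):
            n_d = sum(1 for m in ms if m.label == "decoy" and m.score >= s)
            n_t = sum(1 for m in ms if m.label == "target" and m.score >= s)
            if n_d / max(1, n_t) <= alpha:
                candidates.append(s)
        threshold, _ = estimate_fdr(ms, alpha)
        assert threshold == min(candidates)


class TestRound2:
    def test_requires_decoys(self, focused):
        with pytest.raises(ValidationError, match="decoy"):
            round2([sp("AAAAAK")], focused)

    def test_error_free_recovery_and_single_peptide_exclusion(self, focused):
        """Proteins with >=2 unique surviving peptides are significant;
        one unique peptide is never enough."""
        rec_a, rec_b = focused.records[0], focused.records[1]
        peps_a = digest(rec_a.sequence, 1, 6, 50)[:3]
        peps_b = digest(rec_b.sequence, 1, 6, 50)[:1]
        peptides = [sp(p) for p in peps_a + peps_b]
        db = add_decoys(
            FocusedDatabase("S", [rec_a, rec_b], supplement_tags={})
        )
        result = round2(peptides, db)
        assert rec_a.accession in result.significant
        assert rec_b.accession not in result.significant
        assert rec_b.accession in result.protein_peptides

    def test_two_round_driver_on_fixture_sample(
        self, sim_store, sim_reference, sim_study
    ):
        samples, truth = sim_study
        sid = sorted(samples)[0]
        reads = samples[sid]
        index = PeptideIndex.build(
            sim_reference.records, DigestionParams(1, 6, 50)
        )
        from denovofocus.profiler import profile_sample

        profile = profile_sample(reads, index, sim_store, 2, sample_id=sid)
        focused = select_by_family(
            sim_reference.records, profile.identified_families(), sim_store, sid
        )
        result = two_round_search(
            search.as_sample_peptides(reads), focused, sim_reference.human_records
        )
        # every significant protein's matches trace back to real sources
        sources = {acc for _, acc, _ in truth.read_provenance[sid]}
        assert result.significant
        assert result.significant <= set(result.protein_peptides)
        # error-free reads: surviving matches include each read's source
        by_read = {m.read_id: m for m in result.matches}
        for i, (pep, acc, is_error) in enumerate(truth.read_provenance[sid]):
            if i in by_read and not is_error:
                assert acc in by_read[i].accessions


class TestEntrapment:
    def test_empty_entrapment_no_hits(self, focused, sim_reference):
        rec = focused.records[0]
        peptides = [sp(p) for p in digest(rec.sequence, 1, 6, 50)[:3]]
        db2 = build_round2_db(
            {rec.accession}, focused, sim_reference.human_records
        )
        report = search.entrapment_eval(peptides, db2, [])
        assert report.n_entrapment_hits == 0

    def test_error_free_exact_matching_no_hits(
        self, sim_store, sim_reference, sim_study
    ):
        from denovofocus.simulate import make_entrapment

        samples, _ = sim_study
        sid = sorted(samples)[0]
        reads = samples[sid][:200]
        families = sorted(sim_store.taxids_at_rank("family"))
        focused = select_by_family(
            sim_reference.records, set(families), sim_store, sid
        )
        peptides = search.as_sample_peptides(reads)
        hits = round1(peptides, focused)
        db2 = build_round2_db(hits, focused, sim_reference.human_records)
        entrapment = make_entrapment(
            __import__("denovofocus.simulate", fromlist=["SimulationConfig"]).SimulationConfig(seed=1),
            sim_store,
        )
        report = search.entrapment_eval(peptides, db2, entrapment)
        assert report.n_entrapment_hits == 0
        assert report.n_surviving > 0


def test_two_round_superset_of_single_round(sim_store, sim_reference, sim_study):
    """The focused->expanded two-round design never loses a protein that a
    plain search of the focused database would have called."""
    from denovofocus.profiler import profile_sample

    samples, _ = sim_study
    index = PeptideIndex.build(sim_reference.records, DigestionParams(1, 6, 50))
    for sid in sorted(samples)[:4]:
        reads = samples[sid]
        profile = profile_sample(reads, index, sim_store, 2, sample_id=sid)
        focused = select_by_family(
            sim_reference.records, profile.identified_families(), sim_store, sid
        )
        peptides = search.as_sample_peptides(reads)
        two = two_round_search(peptides, focused, sim_reference.human_records)
        one = single_round_search(peptides, focused)
        assert one.significant <= two.significant
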