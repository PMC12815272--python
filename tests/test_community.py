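"""Dataset splits, composition, diversity, ordination, categorisation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from denovofocus.community import (
    UNCLASSIFIED,
    bray_curtis,
    categorize_microbes,
    composition,
    disease_associations,
    normalize_heatmap,
    pcoa,
    shannon,
    shannon_per_sample,
    split_datasets,
)
from denovofocus.exceptions import ValidationError
from denovofocus.io import AnnotationList


def make_table(rows):
    defaults = {
        "representative": "P", "n_unique": 2, "overall_area": 1e6,
        "superkingdom": "", "phylum": "", "family": "", "genus": "",
        "area:S1": 1.0, "area:S2": 1.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestSplit:
    def test_bacteria_is_microbial_only(self):
        t = make_table([{"superkingdom": "Bacteria"}])
        microbial, human = split_datasets(t)
        assert len(microbial) == 1 and len(human) == 0

    def test_homo_is_human_only(self):
        t = make_table([{"superkingdom": "Eukaryota", "genus": "Homo"}])
        microbial, human = split_datasets(t)
        assert len(microbial) == 0 and len(human) == 1

    def test_missing_superkingdom_in_neither(self):
        t = make_table([{"superkingdom": ""}])
        microbial, human = split_datasets(t)
        assert len(microbial) == 0 and len(human) == 0

    def test_partition_never_overlaps(self):
        t = make_table(
            [
                {"superkingdom": "Bacteria", "genus": "G1"},
                {"superkingdom": "Eukaryota", "genus": "Homo"},
                {"superkingdom": "Eukaryota", "genus": "Zea"},
                {"superkingdom": "", "genus": ""},
            ]
        )
        microbial, human = split_datasets(t)
        assert set(microbial["genus"]) & set(human["genus"]) == set()


class TestComposition:
    def test_single_protein_is_whole_community(self):
        t = make_table([{"genus": "G1", "area:S1": 5.0, "area:S2": 0.0}])
        comp = composition(t, "genus")
        assert comp.loc["S1", "G1"] == 1.0

    def test_same_family_rows_aggregate(self):
        t = make_table(
            [
                {"family": "F", "area:S1": 2.0},
                {"family": "F", "area:S1": 3.0},
            ]
        )
        comp = composition(t, "family")
        assert comp.loc["S1", "F"] == 1.0

    def test_proportions_match_group_by_oracle(self):
        rng = np.random.default_rng(11)
        genera = ["G1", "G2", "G3", ""]
        rows = [
            {"genus": genera[i % 4], "area:S1": float(rng.uniform(0, 10)),
             "area:S2": float(rng.uniform(0, 10))}
            for i in range(20)
        ]
        t = make_table(rows)
        comp = composition(t, "genus")
        for sample in ("S1", "S2"):
            sums = {}
            for r in rows:
                if r["genus"]:
                    sums[r["genus"]] = sums.get(r["genus"], 0.0) + r[f"area:{sample}"]
            total = sum(sums.values())
            for g, v in sums.items():
                assert comp.loc[sample, g] == pytest.approx(v / total)
        assert comp.drop(columns=[UNCLASSIFIED]).sum(axis=1).to_numpy() == pytest.approx([1, 1])

    def test_unclassified_mass_reported_separately(self):
        t = make_table(
            [{"genus": "G1", "area:S1": 3.0}, {"genus": "", "area:S1": 1.0}]
        )
        comp = composition(t, "genus")
        assert comp.loc["S1", "G1"] == 1.0
        assert comp.loc["S1", UNCLASSIFIED] == pytest.approx(0.25)

    def test_count_weighting(self):
        t = make_table(
            [
                {"genus": "G1", "area:S1": 100.0},
                {"genus": "G2", "area:S1": 1.0},
                {"genus": "G2", "area:S1": 1.0},
            ]
        )
        comp = composition(t, "genus", weight="count")
        assert comp.loc["S1", "G1"] == pytest.approx(1 / 3)
        assert comp.loc["S1", "G2"] == pytest.approx(2 / 3)


class TestShannon:
    def test_uniform_closed_form(self):
        for n in range(1, 101):
            assert shannon([1 / n] * n) == pytest.approx(math.log(n), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([1.0]) == 0.0

    def test_hand_value(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.039721, abs=1e-6)

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(8))
            assert 0 <= shannon(p) <= math.log(8) + 1e-12


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        comp = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"], columns=["x", "y"])
        assert bray_curtis(comp).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        comp = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"], columns=["x", "y"])
        assert bray_curtis(comp).loc["a", "b"] == 1.0

    def test_hand_value(self):
        comp = pd.DataFrame([[2.0, 0.0], [1.0, 1.0]], index=["a", "b"], columns=["x", "y"])
        assert bray_curtis(comp).loc["a", "b"] == pytest.approx(0.5)

    def test_matrix_properties(self):
        rng = np.random.default_rng(5)
        comp = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=8),
            index=[f"s{i}" for i in range(8)],
        )
        comp.columns = [f"t{i}" for i in range(6)]
        d = bray_curtis(comp)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d.to_numpy() >= 0) & (d.to_numpy() <= 1)).all()


class TestPcoa:
    def test_identical_samples_identical_coordinates(self):
        d = pd.DataFrame(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float,
            index=list("abc"), columns=list("abc"),
        )
        coords = pcoa(d, k=1).coordinates
        assert coords.loc["a"].to_numpy() == pytest.approx(coords.loc["b"].to_numpy())

    def test_equidistant_triple_embeds_symmetrically(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords = pcoa(d, k=2).coordinates.to_numpy()
        dists = pdist(coords)
        assert dists == pytest.approx(np.full(3, dists[0]))

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(17)
        points = rng.normal(size=(6, 3))
        d = pd.DataFrame(
            squareform(pdist(points)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(6)],
        )
        res = pcoa(d, k=3)
        embedded = squareform(pdist(res.coordinates.to_numpy()))
        assert embedded == pytest.approx(d.to_numpy(), abs=1e-8)

    def test_k_must_be_below_sample_count(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValidationError):
            pcoa(d, k=3)


class TestCategorise:
    @staticmethod
    def comp():
        return pd.DataFrame(
            [[0.4, 0.3, 0.2, 0.1]], index=["S1"], columns=["Gp", "Gg", "Gb", "Go"]
        )

    @staticmethod
    def lists():
        pathogen = AnnotationList("pathogen_genera", "genus", frozenset({"Gp", "Gb"}))
        gut = AnnotationList("gut_genera", "genus", frozenset({"Gg", "Gb"}))
        return pathogen, gut

    def test_both_takes_precedence(self):
        out = categorize_microbes(self.comp(), *self.lists())
        assert out.loc["S1", "both"] == pytest.approx(0.2)
        assert out.loc["S1", "pathogen"] == pytest.approx(0.4)
        assert out.loc["S1", "gut"] == pytest.approx(0.3)
        assert out.loc["S1", "other"] == pytest.approx(0.1)

    def test_fractions_sum_to_one(self):
        out = categorize_microbes(self.comp(), *self.lists())
        assert out.sum(axis=1).to_numpy() == pytest.approx([1.0])


class TestDiseaseAndHeatmap:
    def test_disease_counts_by_intersection(self):
        t = make_table(
            [
                {"representative": "UniRef90_P1"},
                {"representative": "UniRef90_P2"},
                {"representative": "UniRef90_P3"},
            ]
        )
        lists = [
            AnnotationList("d_all", "protein_accession", frozenset({"P1", "P2", "P3"})),
            AnnotationList("d_some", "protein_accession", frozenset({"P2", "Px"})),
            AnnotationList("d_none", "protein_accession", frozenset({"Qz"})),
        ]
        counts = disease_associations(t, lists)
        assert counts["d_all"] == 3
        assert counts["d_some"] == 1
        assert counts["d_none"] == 0

    def test_heatmap_single_protein_is_100(self):
        t = make_table([{"representative": "P1", "area:S1": 7.0, "area:S2": 3.0}])
        hm = normalize_heatmap(t)
        assert hm.loc["P1"].to_numpy() == pytest.approx([100.0, 100.0])

    def test_heatmap_columns_sum_to_100_and_rows_sorted(self):
        t = make_table(
            [
                {"representative": "P1", "area:S1": 7.0, "area:S2": 1.0},
                {"representative": "P2", "area:S1": 3.0, "area:S2": 9.0},
            ]
        )
        hm = normalize_heatmap(t, reference_sample="S1")
        assert hm.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])
        assert list(hm.index) == ["P2", "P1"]  # ascending in S1


def test_shannon_per_sample_on_fixture_composition(sim_study):
    """Composition-derived Shannon values are finite and bounded."""
    samples, truth = sim_study
    rows = []
    for sid, fams in truth.family_composition.items():
        rows.append(pd.Series(fams, name=sid))
    comp = pd.DataFrame(rows).fillna(0.0)
    h = shannon_per_sample(comp)
    assert ((h >= 0) & (h <= math.log(comp.shape[1]))).all()
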