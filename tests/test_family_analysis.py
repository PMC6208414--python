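"""Count matrix, gene-set partition, Venn, binning, dendrogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coralfam as cf
from coralfam.family_analysis import exponential_bins
from coralfam.ffp_phylogeny import tree_splits


class TestBuildCountMatrix:
    def test_counts_members_per_taxon(self):
        groups = cf.OrthologGroupSet(families={"f": {"a1", "a2", "b1"}})
        m = cf.build_count_matrix(groups, {"a1": "T1", "a2": "T1", "b1": "T2"})
        assert m.counts.loc["f", "T1"] == 2
        assert m.counts.loc["f", "T2"] == 1

    def test_empty_groups(self):
        m = cf.build_count_matrix(cf.OrthologGroupSet(families={}), {})
        assert m.counts.empty

    def test_unknown_taxon_rejected(self):
        groups = cf.OrthologGroupSet(families={"f": {"a1"}})
        with pytest.raises(ValueError, match="taxon"):
            cf.build_count_matrix(groups, {})

    def test_no_event_simulation_gives_all_ones(self):
        cfg = cf.SimulationConfig(n_families=10, seed=3,
                                  duplication_rate=0.0, loss_rate=0.0)
        proteomes, truth, _ = cf.simulate_dataset(cfg)
        gene_taxon = {r.gene_id: t for t, rs in proteomes.items() for r in rs}
        fams: dict[str, set[str]] = {}
        for g, f in truth.gene_to_family.items():
            fams.setdefault(f, set()).add(g)
        m = cf.build_count_matrix(cf.OrthologGroupSet(families=fams),
                                  gene_taxon)
        assert (m.counts.values == 1).all()


class TestClassifyGeneSets:
    def test_hand_derived_partition(self, toy_matrix):
        matrix, groups, gene_taxon, grouping = toy_matrix
        part = cf.classify_gene_sets(matrix, grouping, groups=groups,
                                     gene_taxon=gene_taxon)
        assert part.core == {"famA", "famB", "famC", "famG"}
        assert part.clade_specific == {"famB"}
        assert part.focal_specific_families == {"famE", "famH"}
        assert part.focal_specific == {"F1_famE_0", "F1_famE_1", "F1_famH_0"}

    def test_family_in_outgroup_not_clade_specific(self, toy_matrix):
        matrix, groups, gene_taxon, grouping = toy_matrix
        part = cf.classify_gene_sets(matrix, grouping, groups=groups,
                                     gene_taxon=gene_taxon)
        assert "famG" in part.core and "famG" not in part.clade_specific

    def test_missing_focal_taxon_breaks_core(self, toy_matrix):
        matrix, groups, gene_taxon, grouping = toy_matrix
        part = cf.classify_gene_sets(matrix, grouping)
        assert "famD" not in part.core

    def test_unknown_grouping_taxa_rejected(self, toy_matrix):
        matrix, _, _, _ = toy_matrix
        bad = cf.TaxonGrouping(focal_clade={"F1", "ZZ"}, comparison_clade=set(),
                               outgroups=set(), focal_species="F1")
        with pytest.raises(ValueError, match="absent"):
            cf.classify_gene_sets(matrix, bad)

    def test_no_event_truth_core_is_everything(self):
        cfg = cf.SimulationConfig(n_families=12, seed=9,
                                  duplication_rate=0.0, loss_rate=0.0)
        proteomes, truth, _ = cf.simulate_dataset(cfg)
        gene_taxon = {r.gene_id: t for t, rs in proteomes.items() for r in rs}
        fams: dict[str, set[str]] = {}
        for g, f in truth.gene_to_family.items():
            fams.setdefault(f, set()).add(g)
        groups = cf.OrthologGroupSet(families=fams)
        matrix = cf.build_count_matrix(groups, gene_taxon)
        grouping = cf.TaxonGrouping(focal_clade={"F1", "F2", "F3", "F4"},
                                    comparison_clade={"C1", "C2"},
                                    outgroups={"O1", "O2"},
                                    focal_species="F1")
        part = cf.classify_gene_sets(matrix, grouping, groups=groups,
                                     gene_taxon=gene_taxon)
        assert part.core == set(matrix.families)
        assert part.clade_specific == set()
        assert part.focal_specific == set()


class TestCoreFraction:
    def test_toy_fraction(self, toy_matrix):
        matrix, groups, gene_taxon, grouping = toy_matrix
        part = cf.classify_gene_sets(matrix, grouping)
        # F1: core families A,B,C,G contribute 1+2+1+1=5 of 9 F1 genes
        assert cf.core_gene_fraction(matrix, part, "F1") == pytest.approx(5 / 9)

    def test_all_core_gives_one(self):
        counts = pd.DataFrame({"A": [1, 1], "B": [1, 2], "C": [1, 1]},
                              index=["f1", "f2"])
        m = cf.FamilyCountMatrix(counts=counts,
                                 taxon_totals={"A": 2, "B": 3, "C": 2})
        grouping = cf.TaxonGrouping(focal_clade={"A", "B", "C"},
                                    comparison_clade=set(), outgroups=set(),
                                    focal_species="A")
        part = cf.classify_gene_sets(m, grouping)
        assert cf.core_gene_fraction(m, part, "B") == 1.0

    def test_unknown_taxon_rejected(self, toy_matrix):
        matrix, _, _, grouping = toy_matrix
        part = cf.classify_gene_sets(matrix, grouping)
        with pytest.raises(ValueError, match="unknown taxon"):
            cf.core_gene_fraction(matrix, part, "ZZ")


class TestVenn:
    def test_toy_enumeration(self, toy_matrix):
        matrix, _, _, _ = toy_matrix
        venn = cf.venn_counts(matrix, ["F1", "F2", "F3", "F4"])
        # presence patterns among F1..F4 per family, hand-enumerated:
        # famA,B,C,G -> all four; famD -> F1,F3,F4; famE,famH -> F1 only;
        # famF -> none (excluded)
        assert venn[frozenset(["F1", "F2", "F3", "F4"])] == 4
        assert venn[frozenset(["F1", "F3", "F4"])] == 1
        assert venn[frozenset(["F1"])] == 2
        assert sum(venn.values()) == 7  # famF absent from all four

    def test_region_sum_matches_present_families(self, small_dataset):
        _, proteomes, truth, _ = small_dataset
        gene_taxon = {r.gene_id: t for t, rs in proteomes.items() for r in rs}
        fams: dict[str, set[str]] = {}
        for g, f in truth.gene_to_family.items():
            fams.setdefault(f, set()).add(g)
        matrix = cf.build_count_matrix(cf.OrthologGroupSet(families=fams),
                                       gene_taxon)
        taxa = ["F1", "F2", "C1"]
        venn = cf.venn_counts(matrix, taxa)
        present = (matrix.counts[taxa] >= 1).any(axis=1).sum()
        assert sum(venn.values()) == present

    def test_more_than_four_taxa_rejected(self, toy_matrix):
        matrix, _, _, _ = toy_matrix
        with pytest.raises(ValueError, match="4"):
            cf.venn_counts(matrix, ["F1", "F2", "F3", "F4", "C1"])


class TestExponentialBins:
    def test_caption_convention(self):
        # size 1 alone in the first interval; sizes 2 and 3 in the second
        assert exponential_bins([1, 2, 3]) == [((0, 1), 1), ((1, 3), 2)]

    def test_placement_of_four(self):
        assert exponential_bins([4]) == [((0, 1), 0), ((1, 3), 0), ((3, 7), 1)]

    def test_uniform_1_to_15(self):
        bins = exponential_bins(list(range(1, 16)))
        assert [c for _, c in bins] == [1, 2, 4, 8]

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            exponential_bins([0, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=100))
    def test_conserves_total_count(self, sizes):
        bins = exponential_bins(sizes)
        assert sum(c for _, c in bins) == len(sizes)
        for (lo, hi), _ in bins:
            assert lo < hi


class TestGeneContentDendrogram:
    def matrix_from_presence(self, presence: dict[str, list[int]]):
        counts = pd.DataFrame(presence)
        counts.index = [f"f{i}" for i in range(len(counts))]
        totals = {t: max(int(counts[t].sum()), 1) for t in counts.columns}
        return cf.FamilyCountMatrix(counts=counts, taxon_totals=totals)

    def test_identical_sets_distance_zero_cherry(self):
        m = self.matrix_from_presence({
            "A": [1, 1, 1, 0], "B": [1, 1, 1, 0], "C": [0, 0, 1, 1]})
        tree = cf.gene_content_dendrogram(m)
        pdm = tree.phylogenetic_distance_matrix()
        ns = tree.taxon_namespace
        assert pdm.distance(ns.get_taxon("A"), ns.get_taxon("B")) == 0.0

    def test_subset_distance_zero_under_min_formula(self):
        # A's families all shared with B -> d=0 regardless of |B|
        m = self.matrix_from_presence({
            "A": [1, 1, 0, 0, 0], "B": [1, 1, 1, 1, 1], "C": [0, 0, 0, 0, 1]})
        tree = cf.gene_content_dendrogram(m)
        pdm = tree.phylogenetic_distance_matrix()
        ns = tree.taxon_namespace
        assert pdm.distance(ns.get_taxon("A"), ns.get_taxon("B")) == 0.0

    def test_ultrametric_output(self, toy_matrix):
        matrix, _, _, _ = toy_matrix
        tree = cf.gene_content_dendrogram(matrix)
        depths = []
        for leaf in tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9

    def test_zero_family_taxon_rejected(self):
        counts = pd.DataFrame({"A": [1], "B": [0], "C": [1]}, index=["f0"])
        m = cf.FamilyCountMatrix(counts=counts,
                                 taxon_totals={"A": 1, "B": 1, "C": 1})
        with pytest.raises(ValueError, match="zero families"):
            cf.gene_content_dendrogram(m)

    def test_recovers_clade_structure(self, small_dataset):
        _, proteomes, truth, _ = small_dataset
        gene_taxon = {r.gene_id: t for t, rs in proteomes.items() for r in rs}
        fams: dict[str, set[str]] = {}
        for g, f in truth.gene_to_family.items():
            fams.setdefault(f, set()).add(g)
        matrix = cf.build_count_matrix(cf.OrthologGroupSet(families=fams),
                                       gene_taxon)
        tree = cf.gene_content_dendrogram(matrix)
        splits = tree_splits(tree)
        # focal clade should cluster together by shared gene content
        assert frozenset({"F1", "F2", "F3", "F4"}) in splits or frozenset(
            {"C1", "C2", "O1", "O2"}) in splits
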