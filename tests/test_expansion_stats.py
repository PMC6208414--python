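"""Fisher exact, binomial LRT, BH-FDR and the two expansion sweeps.

Fisher oracle: exhaustive enumeration over all 2x2 tables with the
observed margins, computed from binomial coefficients only.  LRT oracle:
direct numeric maximization of the null and alternative binomial
likelihoods (frozen value computed with scipy.optimize before the tests
were written).
"""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coralfam as cf


def fisher_brute(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail fixed-margin enumeration from first principles."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)
    return sum(
        comb(c1, x) * comb(n - c1, r1 - x) / denom
        for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if x >= a
    )


class TestFisherExact:
    def test_spec_style_table(self):
        # brute-force enumeration gives exactly 0.5 for [[2,3],[1,4]]
        assert fisher_brute(2, 3, 1, 4) == pytest.approx(0.5, abs=1e-15)
        assert cf.fisher_exact_one_sided(2, 3, 1, 4) == pytest.approx(
            0.5, abs=1e-12)

    def test_zero_counts_give_one(self):
        assert cf.fisher_exact_one_sided(0, 7, 0, 11) == 1.0

    def test_equal_proportions_above_half(self):
        assert cf.fisher_exact_one_sided(5, 95, 5, 95) > 0.5

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            cf.fisher_exact_one_sided(-1, 2, 3, 4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.integers(0, 30), b=st.integers(0, 30),
           c=st.integers(0, 30), d=st.integers(0, 30))
    def test_matches_enumeration_small_margins(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert cf.fisher_exact_one_sided(a, b, c, d) == pytest.approx(
            fisher_brute(a, b, c, d), abs=1e-12)


class TestBinomialLRT:
    def test_identical_proportions_null(self):
        stat, p, direction = cf.binomial_lrt(
            [5, 5], [1000, 1000], [True, False])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert direction == 0

    def test_oracle_value_from_numeric_maximization(self):
        # frozen oracle: scipy bounded maximization of both likelihoods
        # on focal (20,22)/(10000,10000) vs comparison (2,1)/(10000,10000)
        # gave statistic 40.3777, p 2.093e-10
        stat, p, direction = cf.binomial_lrt(
            [20, 22, 2, 1], [10000] * 4, [True, True, False, False])
        assert stat == pytest.approx(40.3777, abs=1e-3)
        assert p == pytest.approx(2.093e-10, rel=1e-3)
        assert direction == 1

    def test_direction_negative_when_focal_smaller(self):
        stat, p, direction = cf.binomial_lrt(
            [1, 50], [1000, 1000], [True, False])
        assert direction == -1
        assert p < 1e-6

    def test_all_zero_degenerate(self):
        assert cf.binomial_lrt([0, 0], [10, 10], [True, False]) == (0.0, 1.0, 0)

    def test_p_decreases_with_scale(self):
        _, p1, _ = cf.binomial_lrt([4, 1], [100, 100], [True, False])
        _, p10, _ = cf.binomial_lrt([40, 10], [1000, 1000], [True, False])
        assert p10 < p1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cf.binomial_lrt([1, 2], [10, 10], [True, True])


class TestBHFDR:
    def test_hand_evaluated_stepup(self):
        assert cf.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert cf.bh_fdr([0.37]) == [pytest.approx(0.37)]

    def test_all_ones(self):
        assert cf.bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cf.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_and_permutation_invariant(self, ps):
        qs = cf.bh_fdr(ps)
        order = np.argsort(ps, kind="stable")
        sorted_qs = [qs[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(sorted_qs, sorted_qs[1:]))
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        rev = cf.bh_fdr(ps[::-1])
        assert rev[::-1] == pytest.approx(qs)


def matrix_from_counts(rows: dict[str, list[int]], taxa: list[str],
                       totals: dict[str, int]):
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts.index.name = "family_id"
    return cf.FamilyCountMatrix(counts=counts, taxon_totals=totals)


GROUPING = cf.TaxonGrouping(
    focal_clade={"F1", "F2", "F3", "F4"},
    comparison_clade={"C1", "C2"},
    outgroups={"O1", "O2"},
    focal_species="F1",
)
TAXA = ["F1", "F2", "F3", "F4", "C1", "C2", "O1", "O2"]
TOTALS = {t: 1000 for t in TAXA}


class TestCladeDiversified:
    def test_strong_planted_family_significant(self):
        rows = {"big": [20, 22, 18, 25, 2, 1, 0, 0]}
        rows.update({f"null{i}": [1] * 8 for i in range(50)})
        m = matrix_from_counts(rows, TAXA, TOTALS)
        res = cf.test_clade_diversified(m, GROUPING)
        sig = {r.family_id for r in res if r.significant}
        assert sig == {"big"}

    def test_uniform_family_not_significant(self):
        m = matrix_from_counts({"f": [1] * 8}, TAXA, TOTALS)
        res = cf.test_clade_diversified(m, GROUPING)
        assert not res[0].significant

    def test_outgroup_only_family_skipped(self):
        m = matrix_from_counts({"og": [0, 0, 0, 0, 0, 0, 5, 5],
                                "f": [1] * 8}, TAXA, TOTALS)
        res = cf.test_clade_diversified(m, GROUPING)
        assert {r.family_id for r in res} == {"f"}

    def test_contraction_direction_filtered(self):
        # comparison clade much larger: significant but direction negative
        m = matrix_from_counts({"down": [1, 1, 1, 1, 40, 45, 0, 0],
                                "f": [1] * 8}, TAXA, TOTALS)
        res = cf.test_clade_diversified(m, GROUPING)
        down = next(r for r in res if r.family_id == "down")
        assert down.direction == -1
        assert not down.significant
        assert down.q_value < 0.01  # would pass FDR, blocked by direction

    def test_fisher_method_agrees_on_strong_signal(self):
        rows = {"big": [20, 22, 18, 25, 2, 1, 0, 0]}
        rows.update({f"null{i}": [1] * 8 for i in range(20)})
        m = matrix_from_counts(rows, TAXA, TOTALS)
        res = cf.test_clade_diversified(m, GROUPING, method="fisher")
        assert next(r for r in res if r.family_id == "big").significant

    def test_empty_comparison_rejected(self):
        g = cf.TaxonGrouping(focal_clade={"F1", "F2"}, comparison_clade=set(),
                             outgroups=set(), focal_species="F1")
        m = matrix_from_counts({"f": [1, 1]}, ["F1", "F2"],
                               {"F1": 10, "F2": 10})
        with pytest.raises(ValueError, match="comparison"):
            cf.test_clade_diversified(m, g)


class TestSpeciesExpansion:
    def test_planted_single_taxon_expansion_found(self):
        rows = {"exp": [75, 5, 5, 5]}
        rows.update({f"null{i}": [2, 2, 2, 2] for i in range(30)})
        m = matrix_from_counts(rows, ["F1", "F2", "F3", "F4"],
                               {t: 1000 for t in ["F1", "F2", "F3", "F4"]})
        _, expanded = cf.test_species_expansion(m, GROUPING)
        assert expanded["F1"] == {"exp"}
        assert expanded["F2"] == set()

    def test_equal_counts_no_expansion(self):
        m = matrix_from_counts({"f": [5, 5, 5, 5]},
                               ["F1", "F2", "F3", "F4"],
                               {t: 1000 for t in ["F1", "F2", "F3", "F4"]})
        _, expanded = cf.test_species_expansion(m, GROUPING)
        assert all(not v for v in expanded.values())

    def test_family_in_two_taxa_only_that_pair_tested(self):
        m = matrix_from_counts({"f2": [3, 2, 0, 0], "bg": [1, 1, 1, 1]},
                               ["F1", "F2", "F3", "F4"],
                               {t: 1000 for t in ["F1", "F2", "F3", "F4"]})
        results, _ = cf.test_species_expansion(m, GROUPING)
        contrasts = {r.contrast for r in results if r.family_id == "f2"}
        assert contrasts == {"F1>F2", "F2>F1"}

    def test_all_pairs_rule_stricter_than_any(self):
        # expanded vs two taxa but tied with the third
        rows = {"partial": [40, 2, 40, 2], "bg": [1, 1, 1, 1]}
        m = matrix_from_counts(rows, ["F1", "F2", "F3", "F4"],
                               {t: 1000 for t in ["F1", "F2", "F3", "F4"]})
        _, all_rule = cf.test_species_expansion(m, GROUPING, rule="all")
        _, any_rule = cf.test_species_expansion(m, GROUPING, rule="any")
        assert "partial" not in all_rule["F1"]
        assert "partial" in any_rule["F1"]

    def test_singleton_families_not_tested(self):
        m = matrix_from_counts({"solo": [4, 0, 0, 0], "bg": [1, 1, 1, 1]},
                               ["F1", "F2", "F3", "F4"],
                               {t: 1000 for t in ["F1", "F2", "F3", "F4"]})
        results, expanded = cf.test_species_expansion(m, GROUPING)
        assert all(r.family_id != "solo" for r in results)
        assert "solo" not in expanded["F1"]
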