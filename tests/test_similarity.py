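import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from florahom.exceptions import (
    DomainError,
    EmptyInputError,
    UndefinedSimilarityError,
)
from florahom.phylo import PhyloIndex, parse_newick
from florahom.similarity import (
    branch_overlap,
    h_matrix,
    homogenization_index,
    pairwise_table,
    remove_widely_naturalized,
    scenario_naturalized_sets,
    simpson_phylo,
    simpson_tax,
    sorensen_tax,
)

from .conftest import random_presence
from .oracles import (
    brute_branch_overlap,
    brute_simpson_tax,
    brute_sorensen_tax,
    random_tree,
)

floras = st.sets(st.sampled_from("abcdefghij"), min_size=1, max_size=8)


class TestTaxonomicIndices:
    @pytest.mark.parametrize(
        "fa,fb,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x", "y", "z"}, {"y", "z", "w", "v"}, 1 - 1 / 3),
            ({"x", "y"}, {"x", "y", "z", "w"}, 1.0),  # nested sets
        ],
    )
    def test_simpson_examples(self, fa, fb, expected):
        assert simpson_tax(fa, fb) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "fa,fb,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x", "y", "z"}, {"y", "z", "w", "v"}, 4 / 7),
        ],
    )
    def test_sorensen_examples(self, fa, fb, expected):
        assert sorensen_tax(fa, fb) == pytest.approx(expected)

    def test_empty_flora_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            simpson_tax(set(), {"x"})
        with pytest.raises(UndefinedSimilarityError):
            sorensen_tax({"x"}, set())

    @given(floras, floras)
    def test_simpson_at_least_sorensen_and_symmetric(self, fa, fb):
        simp, sor = simpson_tax(fa, fb), sorensen_tax(fa, fb)
        assert simp >= sor - 1e-12
        assert simp == pytest.approx(simpson_tax(fb, fa))
        assert sor == pytest.approx(sorensen_tax(fb, fa))
        assert simp == pytest.approx(brute_simpson_tax(fa, fb))
        assert sor == pytest.approx(brute_sorensen_tax(fa, fb))


class TestBranchOverlap:
    def test_disjoint_clades_share_root_branchless_tree(self, toy_tree):
        ov = branch_overlap(toy_tree, {"s1", "s2"}, {"s3", "s4"})
        assert ov.A == 0.0

    def test_derived_example(self, toy_tree):
        ov = branch_overlap(toy_tree, {"s1", "s3"}, {"s1", "s4"})
        assert (ov.A, ov.B, ov.C) == (3.0, 1.0, 1.0)
        assert simpson_phylo(toy_tree, {"s1", "s3"}, {"s1", "s4"}) == pytest.approx(0.75)

    def test_identical_floras(self, toy_tree):
        ov = branch_overlap(toy_tree, {"s1", "s3"}, {"s1", "s3"})
        assert ov.B == ov.C == 0.0
        assert simpson_phylo(toy_tree, {"s1", "s3"}, {"s1", "s3"}) == 1.0

    def test_star_tree_phylo_equals_tax(self):
        tree = parse_newick("(a:1,b:1,c:1,d:1,e:1,f:1);")
        tips = "abcdef"
        from itertools import combinations

        subsets = [set(c) for r in (1, 2, 3) for c in combinations(tips, r)]
        for fa in subsets:
            for fb in subsets:
                assert simpson_phylo(tree, fa, fb) == pytest.approx(
                    simpson_tax(fa, fb)
                )

    def test_matches_bruteforce_on_random_trees(self):
        rng = np.random.default_rng(42)
        for k in range(30):
            n_tips = int(rng.integers(4, 13))
            tree = random_tree(k, n_tips)
            index = PhyloIndex(tree)
            labels = [f"t{i + 1}" for i in range(n_tips)]
            max_size = min(6, n_tips)
            for _ in range(5):
                fa = set(rng.choice(labels, size=rng.integers(1, max_size + 1), replace=False))
                fb = set(rng.choice(labels, size=rng.integers(1, max_size + 1), replace=False))
                ov = branch_overlap(index, fa, fb)
                A, B, C = brute_branch_overlap(tree, fa, fb)
                assert ov.A == pytest.approx(A)
                assert ov.B == pytest.approx(B)
                assert ov.C == pytest.approx(C)


class TestHomogenizationIndex:
    @pytest.mark.parametrize(
        "sc,sn,expected",
        [
            (0.5, 0.5, 0.0),
            (0.0, 0.0, 0.0),
            (0.399, 0.199, math.log(0.4 / 0.2)),
        ],
    )
    def test_examples(self, sc, sn, expected):
        assert homogenization_index(sc, sn) == pytest.approx(expected)

    def test_domain_check(self):
        with pytest.raises(DomainError):
            homogenization_index(1.2, 0.5)
        with pytest.raises(DomainError):
            homogenization_index(0.5, -0.1)

    def test_sign_convention(self):
        assert homogenization_index(0.8, 0.2) > 0  # homogenization
        assert homogenization_index(0.2, 0.8) < 0  # differentiation


class TestScenarios:
    def test_native_to_one_keeps_cross_native_species(self):
        # species native in A, naturalized in B
        na, nb = {"p"}, {"q"}
        fa, fb = scenario_naturalized_sets(na, nb, set(), {"p"}, "native_to_one")
        assert fb == {"p"} and fa == set()

    def test_native_to_one_drops_alien_to_both(self):
        na, nb = {"p"}, {"q"}
        fa, fb = scenario_naturalized_sets(na, nb, {"z"}, {"z"}, "native_to_one")
        assert fa == fb == set()

    def test_non_native_to_both_keeps_true_aliens(self):
        na, nb = {"p"}, {"q"}
        fa, fb = scenario_naturalized_sets(na, nb, {"z"}, set(), "non_native_to_both")
        assert fa == {"z"} and fb == set()

    def test_all_passthrough(self):
        fa, fb = scenario_naturalized_sets({"p"}, {"q"}, {"z"}, {"w"}, "all")
        assert fa == {"z"} and fb == {"w"}


class TestPairwiseTable:
    def test_two_regions_one_record(self, toy_presence, toy_tree):
        table = pairwise_table(toy_presence, tree=toy_tree)
        assert len(table) == 1
        row = table.iloc[0]
        # native: A={s1,s2}, B={s2,s3}: a=1, b=1, c=1 -> 0.5
        assert row.sim_tax_native == pytest.approx(0.5)
        # combined: A={s1,s2,s3}, B={s1,s2,s3,s4}: nested -> 1
        assert row.sim_tax_combined == pytest.approx(1.0)
        assert row.h_tax == pytest.approx(math.log(1.001 / 0.501))

    def test_pair_count_formula(self):
        rng = np.random.default_rng(0)
        presence = random_presence(rng, n_regions=9, n_species=25)
        table = pairwise_table(presence)
        assert len(table) == 9 * 8 // 2

    def test_scenario_columns_match_set_semantics(self, toy_presence, toy_tree):
        for scenario in ("all", "native_to_one", "non_native_to_both"):
            table = pairwise_table(toy_presence, tree=toy_tree, scenario=scenario)
            na = toy_presence.native_set("A")
            nb = toy_presence.native_set("B")
            fa, fb = scenario_naturalized_sets(
                na, nb, toy_presence.naturalized_set("A"),
                toy_presence.naturalized_set("B"), scenario,
            )
            expected = simpson_tax(na | fa, nb | fb)
            assert table.iloc[0].sim_tax_combined == pytest.approx(expected)

    def test_native_to_one_never_differentiates(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            presence = random_presence(rng)
            table = pairwise_table(presence, scenario="native_to_one")
            ok = table[table.flag == ""]
            assert (ok.h_tax >= -1e-12).all()

    def test_alien_to_one_never_homogenizes_single_pair(self):
        # a species naturalized in only one region, native to neither,
        # cannot increase Simpson similarity of that pair
        rng = np.random.default_rng(3)
        for _ in range(20):
            presence = random_presence(rng, n_regions=2, n_species=20)
            table = pairwise_table(presence, scenario="non_native_to_both")
            row = table.iloc[0]
            na = presence.native_set("r0")
            nb = presence.native_set("r1")
            fa, fb = scenario_naturalized_sets(
                na, nb, presence.naturalized_set("r0"),
                presence.naturalized_set("r1"), "non_native_to_both",
            )
            only_one_sided = not (fa & fb)
            if only_one_sided and not math.isnan(row.sim_tax_combined):
                assert row.sim_tax_combined <= row.sim_tax_native + 1e-12

    def test_sorensen_index_option(self, toy_presence):
        table = pairwise_table(toy_presence, index="sorensen")
        assert table.iloc[0].sim_tax_native == pytest.approx(2 * 1 / (2 + 1 + 1))

    def test_undefined_pairs_flagged_not_fatal(self):
        import pandas as pd

        from florahom.checklists import PresenceData

        presence = PresenceData(
            regions=["A", "B"],
            species=["s1"],
            native=np.array([[1], [1]], dtype=bool),
            naturalized=np.zeros((2, 1), dtype=bool),
        )
        table = pairwise_table(presence)
        assert table.iloc[0].flag == ""  # identical floras are fine
        assert table.iloc[0].sim_tax_native == 1.0

    def test_h_matrix_roundtrip(self, toy_presence):
        table = pairwise_table(toy_presence)
        M = h_matrix(table, toy_presence.regions, "h_tax")
        assert M[0, 1] == M[1, 0] == pytest.approx(table.iloc[0].h_tax)
        assert M[0, 0] == 0.0


class TestRemoveWidelyNaturalized:
    def test_removes_single_most_widespread(self):
        rng = np.random.default_rng(1)
        native = np.zeros((6, 10), dtype=bool)
        native[0] = True  # region 0 native to all
        naturalized = np.zeros((6, 10), dtype=bool)
        for j in range(10):  # species j naturalized in j%5 +... varying spread
            naturalized[1 : 1 + (j % 5) + 1, j] = True
        presence_kwargs = dict(
            regions=[f"r{i}" for i in range(6)],
            species=[f"s{j}" for j in range(10)],
        )
        from florahom.checklists import PresenceData

        presence = PresenceData(
            native=native, naturalized=naturalized, **presence_kwargs
        )
        counts = naturalized.sum(axis=0)
        top = np.max(counts)
        reduced = remove_widely_naturalized(presence, 0.1, "most")
        removed = np.flatnonzero(
            presence.naturalized.any(axis=0) & ~reduced.naturalized.any(axis=0)
        )
        assert len(removed) == 1
        assert counts[removed[0]] == top
        # ties broken by name order: the first species with max count
        first_max = min(j for j in range(10) if counts[j] == top)
        assert removed[0] == first_max

    def test_native_unchanged(self):
        rng = np.random.default_rng(5)
        presence = random_presence(rng)
        reduced = remove_widely_naturalized(presence, 0.3, "least")
        assert np.array_equal(reduced.native, presence.native)

    def test_full_removal_limit(self):
        rng = np.random.default_rng(6)
        presence = random_presence(rng)
        reduced = remove_widely_naturalized(presence, 0.999999, "most")
        assert not reduced.naturalized.any()

    def test_no_naturalized_is_error(self):
        from florahom.checklists import PresenceData

        presence = PresenceData(
            regions=["A", "B"],
            species=["s"],
            native=np.ones((2, 1), dtype=bool),
            naturalized=np.zeros((2, 1), dtype=bool),
        )
        with pytest.raises(EmptyInputError):
            remove_widely_naturalized(presence)

    def test_decile_bounds(self, toy_presence):
        with pytest.raises(DomainError):
            remove_widely_naturalized(toy_presence, 0.0)
        with pytest.raises(DomainError):
            remove_widely_naturalized(toy_presence, 1.0)
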