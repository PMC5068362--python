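"""Trait tables, imputation, Gower and cophenetic distances."""

import numpy as np
import pandas as pd
import pytest

import commdecomp as cd
from commdecomp.errors import ImputationError, InputError


def make_table(data, kinds, axes, **kw):
    return cd.TraitTable(data=data, axis=pd.Series(axes), kind=pd.Series(kinds), **kw)


# ---------------------------------------------------------------------------
# TraitTable container
# ---------------------------------------------------------------------------

class TestTraitTable:
    def test_rejects_nonbinary_values_in_binary_column(self):
        data = pd.DataFrame({"a": [0.0, 2.0]}, index=["x", "y"])
        with pytest.raises(InputError, match="binary"):
            make_table(data, {"a": "binary"}, {"a": "ax"})

    def test_rejects_negative_mensural(self):
        data = pd.DataFrame({"a": [1.0, -2.0]}, index=["x", "y"])
        with pytest.raises(InputError, match="negative"):
            make_table(data, {"a": "mensural"}, {"a": "ax"})

    def test_rejects_attribute_without_axis(self):
        data = pd.DataFrame({"a": [0.0, 1.0]}, index=["x", "y"])
        with pytest.raises(InputError, match="axis"):
            cd.TraitTable(data=data, axis=pd.Series(dtype=object),
                          kind=pd.Series({"a": "binary"}))

    def test_csv_round_trip(self, tmp_path, study_pool):
        path = tmp_path / "traits.csv"
        t = study_pool.traits
        t.to_csv(path)
        back = cd.TraitTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, t.data)
        assert back.mass_attr == t.mass_attr
        assert list(back.axis) == list(t.axis)
        assert list(back.kind) == list(t.kind)
        pd.testing.assert_series_equal(back.genus, t.genus, check_names=False)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

class TestImputation:
    def test_complete_table_returned_unchanged(self, study_pool):
        res = cd.impute_traits(study_pool.traits)
        pd.testing.assert_frame_equal(res.table.data, study_pool.traits.data)
        assert res.report.empty

    def test_exact_linear_relation_recovered(self):
        # attribute = 2 * mass within the subfamily -> missing value 20 at mass 10
        data = pd.DataFrame(
            {"mass": [5.0, 8.0, 10.0], "wing": [10.0, 16.0, np.nan]},
            index=["a", "b", "c"],
        )
        t = make_table(
            data,
            {"mass": "mensural", "wing": "mensural"},
            {"mass": "size", "wing": "aero"},
            mass_attr="mass",
            subfamily=pd.Series(["s1", "s1", "s1"], index=data.index),
            genus=pd.Series(["g1", "g1", "g2"], index=data.index),
        )
        res = cd.impute_traits(t)
        assert res.table.data.loc["c", "wing"] == pytest.approx(20.0)
        assert len(res.report) == 1

    def test_categorical_copied_from_nearest_congener(self):
        data = pd.DataFrame(
            {"mass": [5.0, 8.0, 12.0], "diet_1": [np.nan, 1.0, 0.0]},
            index=["a", "b", "c"],
        )
        t = make_table(
            data,
            {"mass": "mensural", "diet_1": "binary"},
            {"mass": "size", "diet_1": "diet"},
            mass_attr="mass",
            subfamily=pd.Series(["s1"] * 3, index=data.index),
            genus=pd.Series(["g1", "g1", "g1"], index=data.index),
        )
        phylo = cd.cophenetic("((a:1,c:1):2,b:3);")
        res = cd.impute_traits(t, phylo_distances=phylo)
        # c is the closer congener on the tree, so its value (0) is copied
        assert res.table.data.loc["a", "diet_1"] == 0.0
        assert "congener[c]" in res.report.iloc[0]["source"]

    def test_error_when_too_few_subfamily_members(self):
        data = pd.DataFrame(
            {"mass": [5.0, 8.0], "wing": [10.0, np.nan]}, index=["a", "b"]
        )
        t = make_table(
            data, {"mass": "mensural", "wing": "mensural"},
            {"mass": "size", "wing": "aero"}, mass_attr="mass",
            subfamily=pd.Series(["s1", "s2"], index=data.index),
            genus=pd.Series(["g1", "g1"], index=data.index),
        )
        with pytest.raises(ImputationError, match="wing"):
            cd.impute_traits(t)

    def test_error_when_no_congener(self):
        data = pd.DataFrame(
            {"mass": [5.0, 8.0], "diet_1": [np.nan, 1.0]}, index=["a", "b"]
        )
        t = make_table(
            data, {"mass": "mensural", "diet_1": "binary"},
            {"mass": "size", "diet_1": "diet"}, mass_attr="mass",
            subfamily=pd.Series(["s1", "s1"], index=data.index),
            genus=pd.Series(["g1", "g2"], index=data.index),
        )
        with pytest.raises(ImputationError, match="congener"):
            cd.impute_traits(t)

    def test_observed_cells_never_altered(self, study_pool):
        masked = cd.inject_missing(study_pool.traits, 38 / 918, seed=3)
        res = cd.impute_traits(masked)
        observed = ~masked.data.isna()
        orig = study_pool.traits.data
        assert res.table.data.where(observed).equals(orig.where(observed))
        assert len(res.report) == masked.data.isna().sum().sum()


# ---------------------------------------------------------------------------
# Gower distances
# ---------------------------------------------------------------------------

class TestGower:
    def test_hand_computed_toy(self, toy_traits):
        # axis weights 1/2 each: d(1,2)=0.5 (binary mismatch only),
        # d(2,3)=0.5 (full mensural range), d(1,3)=1.0 (both)
        D = cd.gower(toy_traits)
        expected = np.array([[0.0, 0.5, 1.0], [0.5, 0.0, 0.5], [1.0, 0.5, 0.0]])
        np.testing.assert_allclose(D.values, expected, atol=1e-12)

    def test_identical_species_distance_zero(self, study_pool):
        t = study_pool.traits.copy()
        t.data.iloc[1] = t.data.iloc[0]
        D = cd.gower(t)
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_symmetry(self, study_pool):
        D = cd.gower(study_pool.traits)
        assert D.values.min() >= 0 and D.values.max() <= 1 + 1e-12
        np.testing.assert_allclose(D.values, D.values.T, atol=1e-12)

    def test_species_permutation_consistency(self, study_pool):
        t = study_pool.traits
        perm = list(reversed(t.species))
        tp = t.copy()
        tp.data = tp.data.reindex(perm)
        if tp.subfamily is not None:
            tp.subfamily = tp.subfamily.reindex(perm)
            tp.genus = tp.genus.reindex(perm)
        D = cd.gower(t).to_frame()
        Dp = cd.gower(tp).to_frame()
        pd.testing.assert_frame_equal(Dp, D.reindex(index=perm, columns=perm))

    def test_single_axis_equals_unweighted_gower(self, study_pool):
        t = study_pool.traits
        ax = t.axes[0]
        D = cd.gower(t, axes=[ax]).values
        attrs = [a for a in t.attributes if t.axis[a] == ax]
        X = t.data[attrs].to_numpy()
        n = X.shape[0]
        expect = np.zeros((n, n))
        for k in range(len(attrs)):  # binary axis: mean mismatch
            expect += (X[:, k][:, None] != X[:, k][None, :]) / len(attrs)
        np.testing.assert_allclose(D, expect, atol=1e-12)

    def test_zero_range_attribute_excluded_with_warning(self):
        data = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [3.0, 3.0]}, index=["x", "y"]
        )
        t = make_table(data, {"a": "binary", "b": "mensural"},
                       {"a": "ax1", "b": "ax2"})
        with pytest.warns(UserWarning, match="zero range"):
            D = cd.gower(t)
        # only the binary axis remains; its weight renormalises to 1
        assert D.values[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------

class TestCophenetic:
    def test_printed_three_taxon_tree(self):
        D = cd.cophenetic("((A:1,B:1):1,C:2);")
        f = D.to_frame()
        assert f.loc["A", "B"] == pytest.approx(2.0)
        assert f.loc["A", "C"] == pytest.approx(4.0)
        assert f.loc["B", "C"] == pytest.approx(4.0)

    def test_single_species_zero_matrix(self):
        D = cd.cophenetic("((A:1,B:1):1,C:2);", species=["A"])
        assert D.values.shape == (1, 1) and D.values[0, 0] == 0.0

    def test_matches_graph_path_oracle_on_random_trees(self, study_pool):
        import dendropy
        import networkx as nx

        for seed in (1, 2, 3):
            pool = cd.generate_species_pool(
                cd.ScenarioConfig(n_species=10, seed=seed))
            D = cd.cophenetic(pool.newick).to_frame()
            tree = dendropy.Tree.get(data=pool.newick, schema="newick")
            g = nx.Graph()
            for edge in tree.preorder_edge_iter():
                if edge.tail_node is not None:
                    g.add_edge(id(edge.tail_node), id(edge.head_node),
                               weight=edge.length)
            tips = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
            for a in tips:
                for b in tips:
                    want = nx.shortest_path_length(
                        g, tips[a], tips[b], weight="weight")
                    assert D.loc[a, b] == pytest.approx(want, abs=1e-9)

    def test_ultrametric_three_point_condition(self, study_pool):
        D = cd.cophenetic(study_pool.newick).values
        n = D.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(n, 3, replace=False)
            trio = sorted([D[i, j], D[i, k], D[j, k]])
            assert trio[2] - trio[1] < 1e-9

    def test_substitution_to_shared_tip_gives_zero(self, caplog):
        D = cd.cophenetic("((A:1,B:1):1,C:2);", species=["x", "y", "C"],
                          substitutions={"x": "A", "y": "A"})
        assert D.to_frame().loc["x", "y"] == 0.0

    def test_unmapped_species_error(self):
        with pytest.raises(InputError, match="zz"):
            cd.cophenetic("((A:1,B:1):1,C:2);", species=["A", "zz"])
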