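"""Matrix assembly, phenotype thresholds, clustering, correlation neighbors."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

from tnprof import (
    build_matrix,
    classify_phenotypes,
    cluster_profiles,
    correlation_neighbors,
    make_fitness_matrix,
    render_heatmap,
    simulate_pathway_profiles,
)

from _oracles import naive_cophenetic, pearson


def scores_frame(ws, flag="ok"):
    return pd.DataFrame(
        {"W": list(ws.values()), "flag": flag}, index=pd.Index(ws, name="gene_id")
    )


class TestBuildMatrix:
    def test_three_by_two(self):
        m = build_matrix(
            {
                "c1": scores_frame({"a": 1.0, "b": 0.5, "c": 1.2}),
                "c2": scores_frame({"a": 0.9, "b": 1.0, "c": 1.0}),
            }
        )
        assert m.shape == (3, 2)
        assert m.condition_labels == ["c1", "c2"]
        assert m.values.loc["b", "c1"] == 0.5

    def test_no_data_gene_keeps_row(self):
        c1 = scores_frame({"a": 1.0, "b": np.nan})
        c1.loc["b", "flag"] = "no_data"
        m = build_matrix({"c1": c1, "c2": scores_frame({"a": 1.0, "b": 1.1})})
        assert np.isnan(m.values.loc["b", "c1"])
        assert m.flags.loc["b", "c1"] == "no_data"

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_matrix(
                {"c1": scores_frame({"a": 1.0}), "c2": scores_frame({"a": 1.0, "b": 1.0})}
            )

    def test_duplicate_condition_label_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix({"c1": scores_frame({"a": 1.0})}, condition_order=["c1", "c1"])


class TestClassifyPhenotypes:
    def test_single_strong_cell_dominates(self):
        m = make_fitness_matrix(
            pd.DataFrame({"c1": [0.74, 1.0], "c2": [1.0, 1.0]}, index=["hit", "flat"])
        )
        calls, counts = classify_phenotypes(m)
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["hit"].category == "strong"
        assert by_gene["hit"].triggering_conditions == ["c1"]
        assert by_gene["flat"].category == "none"
        assert counts == {"strong": 1, "moderate": 0, "none": 1}

    def test_fitness_advantage_counts_as_phenotype(self):
        m = make_fitness_matrix(pd.DataFrame({"c1": [1.26]}, index=["adv"]))
        calls, _ = classify_phenotypes(m)
        assert calls[0].category == "strong"

    def test_all_cells_near_one_is_none(self):
        m = make_fitness_matrix(
            pd.DataFrame({"c1": [0.95], "c2": [1.05], "c3": [1.0]}, index=["g"])
        )
        assert classify_phenotypes(m)[0][0].category == "none"

    def test_partition_is_exclusive_and_exhaustive(self, rng):
        vals = pd.DataFrame(
            rng.normal(1.0, 0.25, size=(80, 6)),
            index=[f"g{i}" for i in range(80)],
            columns=[f"c{j}" for j in range(6)],
        )
        m = make_fitness_matrix(vals)
        calls, counts = classify_phenotypes(m)
        assert len(calls) == 80
        assert counts["strong"] + counts["moderate"] + counts["none"] == 80
        for call in calls:
            row = m.values.loc[call.gene_id]
            if call.category == "strong":
                assert (np.abs(row - 1) > 0.25).any()
            elif call.category == "moderate":
                assert not ((row < 0.75) | (row > 1.25)).any()
                assert ((row < 0.9) | (row > 1.1)).any()
            else:
                assert ((row >= 0.9) & (row <= 1.1)).all()

    def test_all_na_gene_warns_and_calls_none(self):
        values = pd.DataFrame({"c1": [np.nan], "c2": [np.nan]}, index=["ghost"])
        m = make_fitness_matrix(values)
        with pytest.warns(UserWarning, match="ghost"):
            calls, _ = classify_phenotypes(m)
        assert calls[0].category == "none"


class TestClusterProfiles:
    def test_two_orthogonal_pairs_merge_first(self):
        vals = pd.DataFrame(
            {
                "a1": [0.2, 1.0, 1.0, 1.0, 1.0],
                "a2": [0.21, 1.0, 1.0, 1.0, 1.0],
                "b1": [1.0, 1.0, 1.0, 0.3, 1.0],
                "b2": [1.0, 1.0, 1.0, 0.31, 1.0],
            },
            index=[f"c{j}" for j in range(5)],
        ).T
        res = cluster_profiles(make_fitness_matrix(vals))
        first_two = {frozenset(map(int, res.linkage[0, :2])), frozenset(map(int, res.linkage[1, :2]))}
        ids = {g: i for i, g in enumerate(res.gene_ids)}
        assert frozenset((ids["a1"], ids["a2"])) in first_two
        assert frozenset((ids["b1"], ids["b2"])) in first_two
        # each pair is adjacent in leaf order
        order = res.leaf_order
        assert abs(order.index("a1") - order.index("a2")) == 1
        assert abs(order.index("b1") - order.index("b2")) == 1

    def test_singleton(self):
        res = cluster_profiles(make_fitness_matrix(pd.DataFrame({"c1": [1.0]}, index=["g"])))
        assert res.leaf_order == ["g"]
        assert res.to_newick() == "g:0;"

    def test_merge_heights_non_decreasing(self, rng):
        vals = pd.DataFrame(rng.normal(1, 0.2, (12, 5)), index=[f"g{i:02d}" for i in range(12)])
        res = cluster_profiles(make_fitness_matrix(vals))
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()
        assert sorted(res.leaf_order) == sorted(vals.index)

    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_matches_naive_agglomeration_oracle(self, method, rng):
        for _ in range(20):
            n = int(rng.integers(2, 9))
            pts = rng.normal(1.0, 0.3, size=(n, int(rng.integers(3, 7))))
            vals = pd.DataFrame(pts, index=[f"g{i}" for i in range(n)])
            res = cluster_profiles(make_fitness_matrix(vals), method=method)
            expected = naive_cophenetic(pts, method)
            if n == 2:
                got = np.array([[0, res.linkage[0, 2]], [res.linkage[0, 2], 0]])
            else:
                from scipy.spatial.distance import squareform

                got = squareform(cophenet(res.linkage))
            np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_na_imputed_to_neutral(self):
        vals = pd.DataFrame(
            {"c1": [1.0, np.nan, 5.0], "c2": [1.0, 1.0, 5.0], "c3": [1.0, 1.0, 5.0]},
            index=["g1", "g2", "far"],
        )
        res = cluster_profiles(make_fitness_matrix(vals))
        # g2's missing cell counts as neutral, so g1 and g2 merge first
        assert frozenset(map(int, res.linkage[0, :2])) == frozenset(
            (res.gene_ids.index("g1"), res.gene_ids.index("g2"))
        )
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_row_under_correlation_gets_max_distance(self):
        vals = pd.DataFrame(
            {"c1": [1.0, 0.5, 0.5], "c2": [1.0, 0.7, 0.7], "c3": [1.0, 0.2, 0.2]},
            index=["flat", "g1", "g2"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_profiles(make_fitness_matrix(vals), metric="correlation")
        # the flat profile joins last, at the maximal correlation distance
        assert res.linkage[-1, 2] == pytest.approx(2.0)

    def test_ward_requires_euclidean(self):
        m = make_fitness_matrix(pd.DataFrame({"c1": [1.0, 0.5]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="ward"):
            cluster_profiles(m, metric="correlation", method="ward")


class TestCorrelationNeighbors:
    @pytest.fixture()
    def matrix(self, rng):
        base = rng.normal(1.0, 0.2, 5)
        vals = pd.DataFrame(
            {
                "query": base,
                "twin": base,
                "anti": 2 * base.mean() - base,  # negated around the mean
                "noise": rng.normal(1.0, 0.2, 5),
            },
            index=[f"c{j}" for j in range(5)],
        ).T
        return make_fitness_matrix(vals)

    def test_duplicate_profile_ranks_first_with_r_one(self, matrix):
        ranking = correlation_neighbors(matrix, "query")
        assert ranking.neighbors.iloc[0]["gene_id"] == "twin"
        assert ranking.neighbors.iloc[0]["r"] == pytest.approx(1.0)
        assert "query" not in set(ranking.neighbors["gene_id"])

    def test_negated_profile_ranks_last_with_r_minus_one(self, matrix):
        ranking = correlation_neighbors(matrix, "query")
        assert ranking.neighbors.iloc[-1]["gene_id"] == "anti"
        assert ranking.neighbors.iloc[-1]["r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        vals = pd.DataFrame(
            rng.normal(1.0, 0.3, size=(4, 5)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"c{j}" for j in range(5)],
        )
        m = make_fitness_matrix(vals)
        ranking = correlation_neighbors(m, "g1")
        for rec in ranking.neighbors.itertuples(index=False):
            expected = pearson(vals.loc["g1"], vals.loc[rec.gene_id])
            assert rec.r == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_over_missing_cells(self, rng):
        vals = pd.DataFrame(
            rng.normal(1.0, 0.3, size=(3, 6)),
            index=["g1", "g2", "g3"],
            columns=[f"c{j}" for j in range(6)],
        )
        vals.loc["g2", "c0"] = np.nan
        m = make_fitness_matrix(vals)
        ranking = correlation_neighbors(m, "g1")
        got = ranking.neighbors.set_index("gene_id")["r"]
        assert got["g2"] == pytest.approx(
            pearson(vals.loc["g1"], vals.loc["g2"]), abs=1e-12
        )

    def test_query_without_data_rejected(self):
        values = pd.DataFrame(
            {"c1": [np.nan, 1.0], "c2": [np.nan, 1.1], "c3": [np.nan, 0.9]},
            index=["ghost", "g"],
        )
        m = make_fitness_matrix(values)
        with pytest.raises(ValueError, match="no fitness data"):
            correlation_neighbors(m, "ghost")


class TestPathwayRecovery:
    def test_planted_groups_are_tight_and_contiguous(self):
        matrix, labels = simulate_pathway_profiles(
            n_groups=3, genes_per_group=5, n_conditions=10, noise_sd=0.03, seed=8
        )
        res = cluster_profiles(matrix)
        order = res.leaf_order
        for group in ("group1", "group2", "group3"):
            members = [g for g, lab in labels.items() if lab == group]
            rs = [
                pearson(matrix.values.loc[a], matrix.values.loc[b])
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            ]
            assert np.mean(rs) > 0.9
            idx = sorted(order.index(g) for g in members)
            assert idx == list(range(idx[0], idx[0] + len(members)))


class TestRenderHeatmap:
    def test_writes_file_and_respects_leaf_order(self, tmp_path, rng):
        vals = pd.DataFrame(
            rng.normal(1.0, 0.3, size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"c{j}" for j in range(4)],
        )
        m = make_fitness_matrix(vals)
        res = cluster_profiles(m)
        out = render_heatmap(m, res, tmp_path / "h.png")
        assert out.exists() and out.stat().st_size > 0

    def test_uniform_neutral_matrix_renders(self, tmp_path):
        m = make_fitness_matrix(
            pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        )
        out = render_heatmap(m, None, tmp_path / "flat.png")
        assert out.exists()
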