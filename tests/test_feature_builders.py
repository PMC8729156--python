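"""Feature builders against brute-force oracles and hand-computed cases."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from drpredict import (
    BINARY,
    DR,
    NOT_DR,
    AnnotationDAG,
    FeatureMatrix,
    LabeledGeneSet,
    PathwayGraph,
    PPINetwork,
    ValidationError,
)
from drpredict.feature_builders import (
    adjacency_features,
    go_matrix,
    impute_5nn,
    influence_matrix,
    influence_profile,
    intersect_complete,
    membership_matrix,
    merge_datasets,
    propagate_annotations,
)
from tests.conftest import make_labels


class TestMembership:
    def test_single_set_indicator(self):
        genes = LabeledGeneSet.from_arrays(["g1", "g2"], [DR, NOT_DR])
        mat = membership_matrix({"P1": {"g1"}}, genes)
        assert mat.values["P1"].tolist() == [1.0, 0.0]
        assert mat.kinds["P1"] == BINARY

    def test_no_sets_gives_zero_columns(self, toy_labels):
        mat = membership_matrix({}, toy_labels)
        assert mat.shape == (6, 0)

    def test_pathway_scale_shape(self):
        # the study's pathway-membership dataset: 986 genes x 1640 pathways
        genes = make_labels(99, 887)
        rng = np.random.default_rng(0)
        sets = {
            f"P{j}": set(rng.choice(genes.gene_ids, size=5, replace=False))
            for j in range(1640)
        }
        mat = membership_matrix(sets, genes)
        assert mat.shape == (986, 1640)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            membership_matrix({"P": {"g"}}, LabeledGeneSet(pd.Series(dtype=object)))


def chain_dag() -> AnnotationDAG:
    g = nx.DiGraph([("a", "b"), ("b", "root")])
    return AnnotationDAG(graph=g, root="root", annotations={"g1": {"a"}})


class TestPropagation:
    def test_chain_closure(self):
        closed = propagate_annotations(chain_dag())
        assert closed.annotations["g1"] == {"a", "b", "root"}

    def test_root_annotation_fixpoint(self):
        dag = chain_dag()
        dag.annotations = {"g1": {"root"}}
        assert propagate_annotations(dag).annotations["g1"] == {"root"}

    def test_idempotent(self):
        once = propagate_annotations(chain_dag())
        twice = propagate_annotations(once)
        assert once.annotations == twice.annotations

    def test_random_dag_matches_dfs_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            g = nx.DiGraph()
            nodes = [f"t{i}" for i in range(n)]
            g.add_node(nodes[0])
            for i in range(1, n):
                parents = rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False)
                for p in parents:
                    g.add_edge(nodes[i], nodes[p])
            ann = {
                f"g{k}": set(rng.choice(nodes[1:], size=int(rng.integers(1, 3)), replace=False))
                for k in range(5)
            }
            dag = AnnotationDAG(graph=g, root=nodes[0], annotations=ann)
            closed = propagate_annotations(dag)

            def dfs_ancestors(term):  # independent oracle: explicit stack walk
                seen, stack = set(), [term]
                while stack:
                    t = stack.pop()
                    for parent in g.successors(t):
                        if parent not in seen:
                            seen.add(parent)
                            stack.append(parent)
                return seen

            for gene, terms in ann.items():
                expected = set(terms).union(*(dfs_ancestors(t) for t in terms))
                assert closed.annotations[gene] == expected

    def test_cycle_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a"), ("a", "root")])
        dag = AnnotationDAG(graph=g, root="root", annotations={})
        with pytest.raises(ValidationError, match="cycle"):
            propagate_annotations(dag)

    def test_go_matrix_drops_unannotated_genes(self):
        dag = chain_dag()
        genes = LabeledGeneSet.from_arrays(["g1", "g2"], [DR, NOT_DR])
        mat = go_matrix(dag, genes)
        assert list(mat.instance_ids) == ["g1"]
        assert set(mat.feature_ids) == {"a", "b", "root"}
        assert (mat.values.loc["g1"] == 1.0).all()


class TestInfluence:
    def test_sole_source_full_influence(self):
        pw = PathwayGraph("p", nx.DiGraph([("r", "a"), ("a", "b")]))
        profile = influence_profile(pw, "r")
        assert profile == {"a": 1.0, "b": 1.0}

    def test_two_independent_sources_half(self):
        pw = PathwayGraph("p", nx.DiGraph([("r", "t"), ("s", "t")]))
        assert influence_profile(pw, "r")["t"] == 0.5

    def test_upstream_target_zero(self):
        pw = PathwayGraph("p", nx.DiGraph([("t", "r")]))
        assert influence_profile(pw, "r")["t"] == 0.0

    def test_missing_reference_raises(self):
        pw = PathwayGraph("p", nx.DiGraph([("a", "b")]))
        with pytest.raises(KeyError):
            influence_profile(pw, "zzz")

    def test_values_in_unit_interval_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(3, 10))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)), directed=True)
            pw = PathwayGraph("p", nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)}))
            for ref in pw.graph.nodes:
                for v in influence_profile(pw, ref).values():
                    assert 0.0 <= v <= 1.0

    def test_matrix_star_pathway(self):
        star = PathwayGraph("p1", nx.DiGraph([("r", "a"), ("r", "b"), ("r", "c")]))
        genes = LabeledGeneSet.from_arrays(["r", "a", "zz"], [DR, NOT_DR, NOT_DR])
        mat = influence_matrix([star], genes)
        assert mat.values.loc["r", "p1"] == 1.0  # mean of three 1s
        assert mat.values.loc["zz", "p1"] == 0.0  # gene absent from pathway

    def test_matrix_single_node_pathway(self):
        lone = PathwayGraph("p1", nx.DiGraph())
        lone.graph.add_node("r")
        genes = LabeledGeneSet.from_arrays(["r", "a"], [DR, NOT_DR])
        mat = influence_matrix([lone], genes)
        assert (mat.values["p1"] == 0.0).all()


class TestAdjacency:
    def test_triangle_with_unlabeled_node(self):
        g = nx.Graph([("g1", "g2"), ("g2", "x"), ("g1", "x")])
        net = PPINetwork(graph=g)
        genes = LabeledGeneSet.from_arrays(["g1", "g2"], [DR, NOT_DR])
        mat = adjacency_features(net, genes)
        assert list(mat.feature_ids) == ["g1", "g2", "x"]
        assert mat.values.loc["g1"].tolist() == [0.0, 1.0, 1.0]

    def test_edgeless_network(self):
        g = nx.Graph()
        g.add_nodes_from(["g1", "g2"])
        genes = LabeledGeneSet.from_arrays(["g1", "g2"], [DR, NOT_DR])
        mat = adjacency_features(PPINetwork(graph=g), genes)
        assert list(mat.feature_ids) == ["g1", "g2"]
        assert mat.values.to_numpy().sum() == 0.0

    def test_matches_dense_adjacency_slice(self, small_config, small_labels):
        from drpredict.synthetic_data import simulate_ppi_network

        net = simulate_ppi_network(small_labels, small_config)
        mat = adjacency_features(net, small_labels)
        dense = nx.to_pandas_adjacency(net.graph)  # oracle: full adjacency build
        for g in mat.instance_ids:
            for c in mat.feature_ids:
                expected = dense.loc[g, c] if c in dense.columns else 0.0
                assert mat.values.loc[g, c] == expected


class TestMergeImputeIntersect:
    def make_merge(self):
        a = FeatureMatrix(
            pd.DataFrame({"f1": [1.0, 0.0], "f2": [0.5, 1.5]}, index=["g1", "g2"])
        )
        b = FeatureMatrix(pd.DataFrame({"f1": [1.0, 0.0]}, index=["g2", "g3"]))
        return merge_datasets([a, b], prefixes=["A", "B"])

    def test_merge_unions_instances_and_concats_columns(self):
        merged = self.make_merge()
        assert merged.shape == (3, 3)
        assert merged.missing_mask.loc["g3", "A:f1"]
        assert merged.missing_mask.loc["g1", "B:f1"]
        assert not merged.missing_mask.loc["g2"].any()

    def test_merge_column_count_is_sum(self):
        rng = np.random.default_rng(0)
        mats = [
            FeatureMatrix(
                pd.DataFrame(rng.random((3, k)), index=["a", "b", "c"]).add_prefix("f")
            )
            for k in (4, 7, 2)
        ]
        assert merge_datasets(mats).shape[1] == 13

    def test_unimputed_gene_unchanged(self):
        merged = self.make_merge()
        filled = impute_5nn(merged, merged.instance_ids)
        pd.testing.assert_series_equal(filled.values.loc["g2"], merged.values.loc["g2"])

    def test_binary_mode_imputation(self):
        # gene g9 lacks binary feature F; its 5 nearest neighbours have values 1,1,1,0,0
        base = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 5.0, 6.0, 9.0])
        values = pd.DataFrame(
            {
                "dist": np.append(base, 0.05),
                "F": [1, 1, 1, 0, 0, 1, 1, 1, np.nan],
            },
            index=[f"g{i}" for i in range(1, 10)],
        )
        mat = FeatureMatrix(values, {"dist": "continuous", "F": "binary"})
        filled = impute_5nn(mat, mat.instance_ids)
        assert filled.values.loc["g9", "F"] == 1.0

    def test_toy_merge_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.random((8, 4)), index=[f"g{i}" for i in range(8)],
                              columns=list("wxyz"))
        values.iloc[0, 1] = np.nan
        values.iloc[3, 2] = np.nan
        mat = FeatureMatrix(values)
        filled = impute_5nn(mat, mat.instance_ids)
        # oracle: exhaustive distance table over shared observed features
        for gi, feat in [(0, "x"), (3, "y")]:
            gene = values.index[gi]
            dists = {}
            for other in values.index:
                if other == gene or pd.isna(values.loc[other, feat]):
                    continue
                both = values.loc[gene].notna() & values.loc[other].notna()
                dists[other] = ((values.loc[gene, both] - values.loc[other, both]) ** 2).mean()
            nearest = sorted(dists, key=lambda o: (dists[o], o))[:5]
            expected = values.loc[nearest, feat].mean()
            assert filled.values.loc[gene, feat] == pytest.approx(expected)

    def test_intersect_complete_removes_all_missing(self):
        merged = self.make_merge()
        complete = intersect_complete(merged)
        assert list(complete.instance_ids) == ["g2"]
        assert not complete.missing_mask.any().any()
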