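"""Synthetic generators for labels, annotation structures, graphs and matrices.

Every generator draws from a sub-stream derived deterministically from the
single ``SimulationConfig.seed``, so different artifact kinds over the same
gene universe are jointly reproducible: regenerating the binary matrix never
perturbs the labels or the PPI network.

The generators emulate the statistical structure of the real study inputs —
a roughly tenfold class imbalance, sparse binary annotation matrices with a
planted subset of minority-enriched features, single-rooted annotation DAGs
obeying the true-path rule, directed pathway graphs, and hub-dominated
undirected interaction networks — without any biological content.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import (
    BINARY,
    CONTINUOUS,
    DR,
    NOT_DR,
    AnnotationDAG,
    FeatureMatrix,
    LabeledGeneSet,
    PathwayGraph,
    PPINetwork,
)

# Sub-stream keys: one per artifact kind, so generators are independent.
_STREAMS = {
    "labels": 0,
    "binary": 1,
    "dag": 2,
    "pathway": 3,
    "ppi": 4,
    "continuous": 5,
}


def _rng(config: SimulationConfig, kind: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[kind],)))


def gene_universe(config: SimulationConfig) -> pd.Index:
    width = len(str(config.n_genes))
    return pd.Index([f"G{i:0{width}d}" for i in range(config.n_genes)], name="gene_id")


def simulate_labels(config: SimulationConfig) -> LabeledGeneSet:
    """Draw a labeled gene set with exactly ``round(minority_fraction * n_genes)``
    minority (DR) genes, assigned to uniformly random positions."""
    rng = _rng(config, "labels")
    ids = gene_universe(config)
    n_minority = round(config.minority_fraction * config.n_genes)
    minority_pos = rng.choice(config.n_genes, size=n_minority, replace=False)
    labels = np.full(config.n_genes, NOT_DR, dtype=object)
    labels[minority_pos] = DR
    return LabeledGeneSet(pd.Series(labels, index=ids, name="label"))


def simulate_binary_matrix(
    labels: LabeledGeneSet, config: SimulationConfig
) -> tuple[FeatureMatrix, list[str]]:
    """Sparse binary matrix with ``n_enriched_features`` planted columns.

    Planted columns are positive with probability
    ``min(1, base_positive_rate * enrichment_odds)`` in the minority class and
    ``base_positive_rate`` in the majority class; all other columns are
    positive at the base rate in both classes. Returns the matrix and the
    planted feature ids, for recovery tests.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    rng = _rng(config, "binary")
    n, p = len(labels), config.n_binary_features
    feature_ids = [f"B{j:04d}" for j in range(p)]
    planted = feature_ids[: config.n_enriched_features]
    probs = np.full((n, p), config.base_positive_rate)
    enriched_rate = min(1.0, config.base_positive_rate * config.enrichment_odds)
    minority_rows = labels.y.astype(bool)
    probs[np.ix_(minority_rows, np.arange(config.n_enriched_features))] = enriched_rate
    values = (rng.random((n, p)) < probs).astype(float)
    df = pd.DataFrame(values, index=labels.gene_ids, columns=feature_ids)
    return FeatureMatrix(df, {c: BINARY for c in feature_ids}), planted


def simulate_dag_annotations(labels: LabeledGeneSet, config: SimulationConfig) -> AnnotationDAG:
    """Layered random DAG with a single root, plus direct gene annotations.

    Layer 0 is the root; each node of layer ``d`` gets 1–2 parents drawn from
    layer ``d-1``, guaranteeing acyclicity and a directed path from every term
    to the root. Direct annotations attach each gene to a few random non-root
    terms and are returned un-propagated: ancestor closure is the feature
    builder's job.
    """
    rng = _rng(config, "dag")
    g = nx.DiGraph()
    root = "T0000"
    g.add_node(root)
    layers = [[root]]
    term_counter = 1
    for depth in range(1, config.dag_depth + 1):
        width = max(1, config.dag_branching * len(layers[-1]) // 2 + 1)
        layer = []
        for _ in range(width):
            term = f"T{term_counter:04d}"
            term_counter += 1
            n_parents = 1 + int(rng.random() < 0.3 and len(layers[-1]) > 1)
            parents = rng.choice(layers[-1], size=min(n_parents, len(layers[-1])), replace=False)
            for parent in parents:
                g.add_edge(term, parent)  # child -> parent
            layer.append(term)
        layers.append(layer)
    non_root = [t for layer in layers[1:] for t in layer]
    annotations: dict[str, set[str]] = {}
    for gene in labels.gene_ids:
        k = int(rng.integers(1, 4))
        annotations[gene] = set(rng.choice(non_root, size=min(k, len(non_root)), replace=False))
    dag = AnnotationDAG(graph=g, root=root, annotations=annotations)
    dag.validate()
    return dag


def simulate_pathway_graph(
    config: SimulationConfig, pathway_id: str = "P0", acyclic: bool = True
) -> PathwayGraph:
    """Directed pathway interaction graph.

    In acyclic mode nodes are ordered and only forward edges drawn, which
    guarantees at least one zero-in-degree (source) node. Otherwise edges are
    drawn in both directions uniformly at density ``graph_edge_density``.
    """
    rng = _rng(config, "pathway")
    n = config.graph_n_nodes
    nodes = [f"{pathway_id}_N{i:03d}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if acyclic and j <= i:
                continue
            if rng.random() < config.graph_edge_density:
                g.add_edge(nodes[i], nodes[j])
    return PathwayGraph(pathway_id=pathway_id, graph=g)


def simulate_ppi_network(labels: LabeledGeneSet, config: SimulationConfig) -> PPINetwork:
    """Hub-dominated undirected interaction network over the labeled genes plus
    unlabeled neighbor nodes, via preferential attachment.

    The resulting graph is simple (no loops, no repeated edges). Roughly 20%
    extra unlabeled nodes model interactors outside the ageing gene universe.
    """
    rng = _rng(config, "ppi")
    n_extra = max(1, len(labels) // 5)
    extra = [f"X{i:04d}" for i in range(n_extra)]
    all_nodes = list(labels.gene_ids) + extra
    order = rng.permutation(len(all_nodes))
    m = max(1, int(round(config.graph_edge_density * 10)))  # edges added per new node
    seed_int = int(rng.integers(0, 2**31 - 1))
    ba = nx.barabasi_albert_graph(len(all_nodes), min(m, len(all_nodes) - 1), seed=seed_int)
    g = nx.relabel_nodes(ba, {i: all_nodes[order[i]] for i in range(len(all_nodes))})
    g.remove_edges_from(nx.selfloop_edges(g))
    net = PPINetwork(graph=g, node_labels=dict(labels.labels))
    net.validate()
    return net


def simulate_continuous_matrix(
    labels: LabeledGeneSet, config: SimulationConfig
) -> tuple[FeatureMatrix, list[str]]:
    """Standard-normal feature matrix with a planted class effect.

    Planted columns shift the minority-class mean by
    ``continuous_effect_size`` standard deviations; the remaining columns
    carry no class signal. Returns the matrix and the planted feature ids.
    """
    if len(labels) == 0:
        raise ValueError("labels must be nonempty")
    rng = _rng(config, "continuous")
    n, p = len(labels), config.n_continuous_features
    n_planted = min(config.n_enriched_features, p)
    feature_ids = [f"C{j:04d}" for j in range(p)]
    planted = feature_ids[:n_planted]
    values = rng.standard_normal((n, p))
    values[labels.y.astype(bool), :n_planted] += config.continuous_effect_size
    df = pd.DataFrame(values, index=labels.gene_ids, columns=feature_ids)
    return FeatureMatrix(df, {c: CONTINUOUS for c in feature_ids}), planted
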