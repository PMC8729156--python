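"""Builders that turn annotation and graph inputs into feature matrices.

Each builder mirrors one feature type of the gene-prioritisation study:
pathway membership indicators, ancestor-propagated ontology annotations,
pathway-graph influence scores, interaction-network adjacency indicators,
and the merge / k-nearest-neighbour imputation / complete-case steps that
assemble the combined dataset.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    BINARY,
    CONTINUOUS,
    AnnotationDAG,
    FeatureMatrix,
    LabeledGeneSet,
    PathwayGraph,
    PPINetwork,
    ValidationError,
)


# --------------------------------------------------------------------------
# gene-set membership
# --------------------------------------------------------------------------

def membership_matrix(gene_sets: Mapping[str, set[str]], genes: LabeledGeneSet) -> FeatureMatrix:
    """Binary matrix: cell (g, S) = 1 iff gene g belongs to gene set S.

    Genes with no membership are kept as all-zero rows; dropping them is the
    caller's choice.
    """
    if len(genes) == 0:
        raise ValidationError("empty gene list")
    set_names = list(gene_sets)
    data = np.zeros((len(genes), len(set_names)))
    for j, name in enumerate(set_names):
        members = gene_sets[name]
        data[:, j] = [1.0 if g in members else 0.0 for g in genes.gene_ids]
    df = pd.DataFrame(data, index=genes.gene_ids, columns=set_names)
    return FeatureMatrix(df, {c: BINARY for c in set_names})


# --------------------------------------------------------------------------
# ontology annotations: true-path-rule closure
# --------------------------------------------------------------------------

def propagate_annotations(dag: AnnotationDAG) -> AnnotationDAG:
    """Close direct annotations under the true-path rule.

    A gene annotated to a term is annotated to every ancestor of that term
    up to the root. Idempotent: propagating an already closed DAG changes
    nothing.
    """
    dag.validate()
    ancestor_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in ancestor_cache:
            ancestor_cache[term] = dag.ancestors_of(term)
        return ancestor_cache[term]

    closed = {
        gene: set(terms).union(*(ancestors(t) for t in terms)) if terms else set()
        for gene, terms in dag.annotations.items()
    }
    return AnnotationDAG(graph=dag.graph, root=dag.root, annotations=closed)


def go_matrix(dag: AnnotationDAG, genes: LabeledGeneSet) -> FeatureMatrix:
    """Binary matrix over the ancestor-closed annotation set.

    One column per term appearing in the closed annotations; genes with zero
    annotations are dropped from the matrix (they carry no signal for this
    feature type).
    """
    closed = propagate_annotations(dag)
    annotated = [g for g in genes.gene_ids if closed.annotations.get(g)]
    terms = sorted(set().union(*(closed.annotations[g] for g in annotated)) if annotated else set())
    data = np.zeros((len(annotated), len(terms)))
    term_pos = {t: j for j, t in enumerate(terms)}
    for i, g in enumerate(annotated):
        for t in closed.annotations[g]:
            data[i, term_pos[t]] = 1.0
    df = pd.DataFrame(data, index=pd.Index(annotated, name="gene_id"), columns=terms)
    return FeatureMatrix(df, {t: BINARY for t in terms})


# --------------------------------------------------------------------------
# pathway-graph influence
# --------------------------------------------------------------------------

def _sources(graph: nx.DiGraph) -> list:
    srcs = [n for n in graph.nodes if graph.in_degree(n) == 0]
    # cyclic pathway with no source: every node counts as a source
    return srcs if srcs else list(graph.nodes)


def influence_profile(pathway: PathwayGraph, reference: str) -> dict[str, float]:
    """How strongly ``reference`` controls upstream access to each other node.

    For a target t, let S(t) be the source nodes (zero in-degree; all nodes
    if the graph is source-free) from which t is reachable, and S_-r(t) the
    same after deleting the reference and its edges. The influence exerted on
    t is ``1 - |S_-r(t)| / |S(t)|``: 1 when every upstream route passes
    through the reference, 0 when none does. Targets unreachable from the
    reference get influence 0.
    """
    g = pathway.graph
    if reference not in g:
        raise KeyError(f"reference {reference!r} not in pathway {pathway.pathway_id!r}")
    sources = _sources(g)
    downstream = nx.descendants(g, reference)
    reach_from = {s: nx.descendants(g, s) | {s} for s in sources}
    g_minus = g.copy()
    g_minus.remove_node(reference)
    reach_minus = {
        s: (nx.descendants(g_minus, s) | {s}) if s in g_minus else set()
        for s in sources
    }
    profile: dict[str, float] = {}
    for t in g.nodes:
        if t == reference:
            continue
        if t not in downstream:
            profile[t] = 0.0
            continue
        upstream = [s for s in sources if t in reach_from[s]]
        if not upstream:
            profile[t] = 0.0
            continue
        surviving = sum(1 for s in upstream if t in reach_minus[s])
        profile[t] = 1.0 - surviving / len(upstream)
    return profile


def influence_matrix(pathways: Sequence[PathwayGraph], genes: LabeledGeneSet) -> FeatureMatrix:
    """One continuous column per pathway; cell (g, p) is the mean influence
    gene g exerts over the other nodes of pathway p, or 0 when g is absent."""
    cols = {}
    for pw in pathways:
        col = np.zeros(len(genes))
        for i, g in enumerate(genes.gene_ids):
            if g in pw.graph and pw.graph.number_of_nodes() > 1:
                profile = influence_profile(pw, g)
                col[i] = float(np.mean(list(profile.values()))) if profile else 0.0
        cols[pw.pathway_id] = col
    df = pd.DataFrame(cols, index=genes.gene_ids)
    return FeatureMatrix(df, {c: CONTINUOUS for c in cols})


# --------------------------------------------------------------------------
# interaction-network adjacency
# --------------------------------------------------------------------------

def adjacency_features(net: PPINetwork, genes: LabeledGeneSet) -> FeatureMatrix:
    """Binary adjacency slice of the interaction network.

    Rows are the labeled genes present in the network. Columns are all
    labeled genes plus any unlabeled node that directly interacts with at
    least one labeled gene, so interactors outside the ageing gene universe
    still contribute as features.
    """
    net.validate()
    g = net.graph
    labeled = [x for x in genes.gene_ids if x in g]
    labeled_set = set(genes.gene_ids)
    extra = sorted(
        {nbr for x in labeled for nbr in g.neighbors(x) if nbr not in labeled_set}
    )
    columns = list(genes.gene_ids) + extra
    data = np.zeros((len(labeled), len(columns)))
    col_pos = {c: j for j, c in enumerate(columns)}
    for i, x in enumerate(labeled):
        for nbr in g.neighbors(x):
            j = col_pos.get(nbr)
            if j is not None:
                data[i, j] = 1.0
    df = pd.DataFrame(data, index=pd.Index(labeled, name="gene_id"), columns=columns)
    return FeatureMatrix(df, {c: BINARY for c in columns})


# --------------------------------------------------------------------------
# merge / impute / intersect
# --------------------------------------------------------------------------

def merge_datasets(matrices: Sequence[FeatureMatrix], prefixes: Sequence[str] | None = None) -> FeatureMatrix:
    """Union of instances, concatenation of feature columns.

    Column ids are prefixed by their source dataset so they stay globally
    unique; a gene absent from a source dataset gets missing cells for that
    dataset's features.
    """
    if prefixes is None:
        prefixes = [f"D{i}" for i in range(len(matrices))]
    if len(prefixes) != len(matrices):
        raise ValidationError("one prefix per matrix required")
    frames, kinds = [], {}
    for mat, prefix in zip(matrices, prefixes):
        renamed = mat.values.add_prefix(f"{prefix}:")
        frames.append(renamed)
        for c in mat.feature_ids:
            kinds[f"{prefix}:{c}"] = mat.kinds[c]
    all_instances = frames[0].index
    for f in frames[1:]:
        all_instances = all_instances.union(f.index)
    merged = pd.concat([f.reindex(all_instances) for f in frames], axis=1)
    if merged.columns.has_duplicates:
        raise ValidationError("feature ids collide across datasets after prefixing")
    return FeatureMatrix(merged, kinds)


def _neighbor_distances(target: pd.Series, candidates: pd.DataFrame) -> pd.Series:
    """Mean squared difference over the features observed in both rows."""
    diff = candidates.sub(target, axis=1) ** 2
    return diff.mean(axis=1, skipna=True)


def impute_5nn(matrix: FeatureMatrix, train_ids: Iterable[str], k: int = 5) -> FeatureMatrix:
    """Fill missing cells from the k nearest training genes.

    Distance between two genes is the mean squared difference over features
    observed in both; neighbours are training genes with the target feature
    observed. Continuous features impute the neighbour mean, binary features
    the neighbour mode (ties resolve to 0: absence is the majority state of
    sparse annotations). Fewer than k eligible neighbours → use all, with a
    warning; none → column-wise training mean/mode fallback.
    """
    train_ids = pd.Index(list(train_ids))
    stray = train_ids.difference(matrix.instance_ids)
    if len(stray):
        raise ValidationError(f"train ids not in matrix: {stray[:5].tolist()}")
    values = matrix.values.copy()
    train_block = matrix.values.loc[train_ids]
    for gene in matrix.instance_ids:
        row = values.loc[gene]
        missing_feats = row.index[row.isna()]
        if not len(missing_feats):
            continue
        pool = train_block.drop(index=gene, errors="ignore")
        dist = _neighbor_distances(row, pool)
        for feat in missing_feats:
            eligible = dist[pool[feat].notna() & dist.notna()].sort_values(kind="mergesort")
            if len(eligible) == 0:
                col = train_block[feat].dropna()
                if matrix.kinds[feat] == BINARY:
                    fill = _mode_zero_ties(col.to_numpy()) if len(col) else 0.0
                else:
                    fill = float(col.mean()) if len(col) else 0.0
                warnings.warn(
                    f"no eligible neighbour for gene {gene!r} feature {feat!r}; "
                    "falling back to training column statistic"
                )
            else:
                if len(eligible) < k:
                    warnings.warn(
                        f"only {len(eligible)} eligible neighbours for gene {gene!r} "
                        f"feature {feat!r}; using all"
                    )
                nbrs = eligible.index[:k]
                nbr_vals = pool.loc[nbrs, feat].to_numpy()
                if matrix.kinds[feat] == BINARY:
                    fill = _mode_zero_ties(nbr_vals)
                else:
                    fill = float(np.mean(nbr_vals))
            values.loc[gene, feat] = fill
    return FeatureMatrix(values, matrix.kinds)


def _mode_zero_ties(vals: np.ndarray) -> float:
    ones = int(np.sum(vals == 1.0))
    zeros = len(vals) - ones
    return 1.0 if ones > zeros else 0.0


def intersect_complete(matrix: FeatureMatrix) -> FeatureMatrix:
    """Keep only the instances observed in every feature (complete cases)."""
    keep = matrix.values.dropna(axis=0).index
    return FeatureMatrix(matrix.values.loc[keep], matrix.kinds)
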