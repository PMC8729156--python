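"""Node-level topology measures for undirected interaction networks.

Eighteen per-node measures: eight classic ones available in networkx
(degree, closeness, betweenness, eigenvector, eccentricity, k-core,
clustering coefficient, subgraph centrality), nine further centralities
implemented here following their literature definitions (topological
coefficient, leverage, Markov, maximum neighborhood component, Laplacian,
diffusion degree, semilocal, geodesic k-path, lobby index), and the
class-aware DR-ratio: the fraction of a node's direct neighbours carrying
the minority (DR) label.

Conventions for degenerate cases (isolated nodes, disconnected graphs) are
stated in each measure's docstring.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import CONTINUOUS, DR, FeatureMatrix, LabeledGeneSet, PPINetwork

MEASURE_NAMES = [
    "degree",
    "closeness",
    "betweenness",
    "eigenvector",
    "eccentricity",
    "k_core",
    "clustering",
    "topological_coefficient",
    "leverage",
    "markov",
    "mnc",
    "laplacian",
    "diffusion_degree",
    "semilocal",
    "subgraph",
    "geodesic_kpath",
    "lobby",
    "dr_ratio",
]


def topological_coefficient(g: nx.Graph) -> dict:
    """T(v) = mean over partners w of J(v, w) / deg(v), where a partner shares
    at least one neighbour with v and J counts shared neighbours, plus one if
    w is itself adjacent to v. Nodes with degree < 1 or no partners score 0."""
    out = {}
    for v in g.nodes:
        kv = g.degree(v)
        if kv == 0:
            out[v] = 0.0
            continue
        nv = set(g.neighbors(v))
        partners = {w for u in nv for w in g.neighbors(u) if w != v}
        if not partners:
            out[v] = 0.0
            continue
        j_vals = []
        for w in partners:
            shared = len(nv & set(g.neighbors(w)))
            j_vals.append(shared + (1 if w in nv else 0))
        out[v] = float(np.mean(j_vals)) / kv
    return out


def leverage_centrality(g: nx.Graph) -> dict:
    """l(v) = (1/deg v) * sum over neighbours w of (k_v - k_w)/(k_v + k_w);
    positive for locally dominant hubs. Isolated nodes score 0."""
    out = {}
    for v in g.nodes:
        kv = g.degree(v)
        if kv == 0:
            out[v] = 0.0
            continue
        out[v] = float(np.mean([(kv - g.degree(w)) / (kv + g.degree(w)) for w in g.neighbors(v)]))
    return out


def markov_centrality(g: nx.Graph) -> dict:
    """Inverse mean first-passage time of an unbiased random walk.

    Within each connected component C: C_M(v) = |C| / sum over s in C of
    mfpt(s -> v), with mfpt(v -> v) = 0, computed from the fundamental
    matrix Z = (I - P + 1 pi^T)^{-1}. Components of size 1 score 0.
    """
    out = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        nc = len(nodes)
        if nc < 2:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes)
        deg = a.sum(axis=1)
        p = a / deg[:, None]
        pi = deg / deg.sum()
        z = np.linalg.inv(np.eye(nc) - p + np.outer(np.ones(nc), pi))
        # mfpt(s -> v) = (z_vv - z_sv) / pi_v
        for j, v in enumerate(nodes):
            mfpt_to_v = (z[j, j] - z[:, j]) / pi[j]
            out[v] = nc / float(mfpt_to_v.sum())
    return out


def maximum_neighborhood_component(g: nx.Graph) -> dict:
    """Size of the largest connected component of the subgraph induced by the
    open neighbourhood of v (v excluded); 0 for isolated nodes."""
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = float(max(len(c) for c in nx.connected_components(sub)))
    return out


def diffusion_degree(g: nx.Graph) -> dict:
    """deg(v) plus the summed degree of its neighbours (propagation
    probability fixed at 1): the number of nodes reachable by a two-step
    broadcast, with multiplicity."""
    return {v: float(g.degree(v) + sum(g.degree(w) for w in g.neighbors(v))) for v in g.nodes}


def semilocal_centrality(g: nx.Graph) -> dict:
    """C(v) = sum over neighbours u of Q(u); Q(u) = sum over neighbours w of u
    of N2(w), where N2(w) counts nodes within distance two of w (w excluded)."""
    n2 = {}
    for w in g.nodes:
        reach = nx.single_source_shortest_path_length(g, w, cutoff=2)
        n2[w] = len(reach) - 1
    q = {u: float(sum(n2[w] for w in g.neighbors(u))) for u in g.nodes}
    return {v: float(sum(q[u] for u in g.neighbors(v))) for v in g.nodes}


def geodesic_kpath_centrality(g: nx.Graph, k: int = 3) -> dict:
    """Number of nodes whose geodesic distance from v is at most k
    (v excluded)."""
    out = {}
    for v in g.nodes:
        reach = nx.single_source_shortest_path_length(g, v, cutoff=k)
        out[v] = float(len(reach) - 1)
    return out


def lobby_index(g: nx.Graph) -> dict:
    """h-index of the neighbour degree sequence: the largest l such that v has
    at least l neighbours of degree at least l."""
    out = {}
    for v in g.nodes:
        degs = sorted((g.degree(w) for w in g.neighbors(v)), reverse=True)
        l = 0
        for i, d in enumerate(degs, start=1):
            if d >= i:
                l = i
            else:
                break
        out[v] = float(l)
    return out


def dr_ratio(net: PPINetwork) -> dict:
    """Fraction of direct neighbours carrying the minority (DR) label;
    0 for degree-0 nodes."""
    g = net.graph
    out = {}
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0:
            out[v] = 0.0
            continue
        n_dr = sum(1 for w in g.neighbors(v) if net.node_labels.get(w) == DR)
        out[v] = n_dr / deg
    return out


def _eccentricity(g: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        out.update({v: float(e) for v, e in nx.eccentricity(sub).items()})
    return out


def _eigenvector(g: nx.Graph) -> dict:
    """Principal-eigenvector centrality from a dense eigendecomposition
    (robust for very small graphs); entries are absolute values of the unit
    leading eigenvector. Edgeless graphs score 0 everywhere."""
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in g.nodes}
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    eigvals, eigvecs = np.linalg.eigh(a)
    lead = np.abs(eigvecs[:, int(np.argmax(eigvals))])
    lead = lead / np.linalg.norm(lead)
    return {v: float(x) for v, x in zip(nodes, lead)}


def _laplacian(g: nx.Graph) -> dict:
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in g.nodes}
    return nx.laplacian_centrality(g, normalized=False)


def graph_measures(net: PPINetwork, genes: LabeledGeneSet) -> FeatureMatrix:
    """Continuous 18-column matrix of node measures for the labeled genes.

    Measures are computed on the full network (unlabeled interactors shape
    the topology) and then sliced to the labeled genes. Genes absent from the
    network are dropped with a warning.
    """
    net.validate()
    g = net.graph
    present = [x for x in genes.gene_ids if x in g]
    absent = [x for x in genes.gene_ids if x not in g]
    if absent:
        warnings.warn(f"{len(absent)} labeled genes absent from the network were dropped")
    measures = {
        "degree": {v: float(d) for v, d in g.degree()},
        "closeness": nx.closeness_centrality(g),
        "betweenness": nx.betweenness_centrality(g, normalized=False),
        "eigenvector": _eigenvector(g),
        "eccentricity": _eccentricity(g),
        "k_core": {v: float(c) for v, c in nx.core_number(g).items()},
        "clustering": nx.clustering(g),
        "topological_coefficient": topological_coefficient(g),
        "leverage": leverage_centrality(g),
        "markov": markov_centrality(g),
        "mnc": maximum_neighborhood_component(g),
        "laplacian": _laplacian(g),
        "diffusion_degree": diffusion_degree(g),
        "semilocal": semilocal_centrality(g),
        "subgraph": nx.subgraph_centrality(g) if g.number_of_nodes() else {},
        "geodesic_kpath": geodesic_kpath_centrality(g),
        "lobby": lobby_index(g),
        "dr_ratio": dr_ratio(net),
    }
    data = {name: [float(measures[name][v]) for v in present] for name in MEASURE_NAMES}
    df = pd.DataFrame(data, index=pd.Index(present, name="gene_id"), columns=MEASURE_NAMES)
    return FeatureMatrix(df, {c: CONTINUOUS for c in MEASURE_NAMES})
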