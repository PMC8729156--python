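"""Simulate a labeled gene universe and build every feature type from it.

Generates a ~1:10 imbalanced gene set plus annotation, pathway and
interaction-network structures, then turns each into a feature matrix the
classifier can consume. The printed shapes show instances (genes) x
features per source.
"""

from drpredict import SimulationConfig
from drpredict.centrality import graph_measures
from drpredict.feature_builders import (
    adjacency_features,
    go_matrix,
    influence_matrix,
    membership_matrix,
)
from drpredict.synthetic_data import (
    simulate_binary_matrix,
    simulate_dag_annotations,
    simulate_labels,
    simulate_pathway_graph,
    simulate_ppi_network,
)

cfg = SimulationConfig(n_genes=300, minority_fraction=0.1, graph_n_nodes=40, seed=42)
labels = simulate_labels(cfg)
print(f"genes: {len(labels)} ({len(labels.minority_ids)} DR, {len(labels.majority_ids)} NotDR)")

binary, planted = simulate_binary_matrix(labels, cfg)
print(f"annotation-style binary matrix: {binary.shape}, planted signal features: {planted}")

dag = simulate_dag_annotations(labels, cfg)
go = go_matrix(dag, labels)
print(f"ontology matrix after ancestor propagation: {go.shape} "
      f"({len(dag.graph.nodes)} terms in the DAG)")

# pathway membership: treat each planted feature's positive genes as a gene set
sets = {f"S{j}": set(binary.instance_ids[binary.values[f] == 1.0]) for j, f in enumerate(planted)}
membership = membership_matrix(sets, labels)
print(f"gene-set membership matrix: {membership.shape}")

pathway = simulate_pathway_graph(cfg, pathway_id="pw1")
# relabel a few pathway nodes to gene ids so some genes sit inside the pathway
import networkx as nx

mapping = dict(zip(list(pathway.graph.nodes)[:10], labels.gene_ids[:10]))
pathway.graph = nx.relabel_nodes(pathway.graph, mapping)
infl = influence_matrix([pathway], labels)
nonzero = (infl.values["pw1"] > 0).sum()
print(f"pathway influence matrix: {infl.shape}, genes with influence > 0: {nonzero}")

net = simulate_ppi_network(labels, cfg)
adj = adjacency_features(net, labels)
meas = graph_measures(net, labels)
print(f"interaction adjacency matrix: {adj.shape}")
print(f"graph-measure matrix: {meas.shape} (18 topology measures incl. DR-ratio)")
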