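"""Plain-text readers and writers for the formats the pipeline exchanges.

One tabular dialect throughout: tab-separated values with a header line and
``NA`` for missing cells. Gene sets travel as GMT (one set per line:
name, description, member ids); graphs as two-column edge lists; annotation
DAGs as child→parent term pairs. All writers sort identifiers so output is
byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .datatypes import FeatureMatrix, LabeledGeneSet, ValidationError

NA = "NA"


class ParseError(ValueError):
    """Raised when an input file does not conform to its format."""


# --------------------------------------------------------------------------
# labels
# --------------------------------------------------------------------------

def read_labels(path: str | Path) -> LabeledGeneSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "label"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: label table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes[:5]}")
    return LabeledGeneSet(pd.Series(df["label"].values, index=pd.Index(df["gene_id"], name="gene_id"), name="label"))


def write_labels(labels: LabeledGeneSet, path: str | Path) -> None:
    out = labels.labels.sort_index()
    out.rename_axis("gene_id").reset_index().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# feature matrices
# --------------------------------------------------------------------------

def read_matrix(path: str | Path, kinds: Mapping[str, str] | None = None) -> FeatureMatrix:
    """Read a TSV feature matrix (first column = instance id, ``NA`` missing).

    Feature kind is inferred as binary iff a column's non-missing values are
    a subset of {0, 1}, unless ``kinds`` overrides the inference.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return FeatureMatrix(values, kinds)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    out = matrix.values.sort_index(axis=0).sort_index(axis=1)
    out.rename_axis("gene_id").to_csv(path, sep="\t", na_rep=NA)


# --------------------------------------------------------------------------
# gene sets (GMT)
# --------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: member gene ids}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
            name = parts[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gene_sets(gene_sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


# --------------------------------------------------------------------------
# graphs
# --------------------------------------------------------------------------

def read_edge_list(path: str | Path, directed: bool) -> nx.Graph | nx.DiGraph:
    """Two-column TSV edge list. Undirected edges are canonicalized, so a
    duplicated ``a b`` / ``b a`` pair collapses to a single edge."""
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated node ids")
            g.add_edge(parts[0], parts[1])
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_edge_list(graph: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    if graph.is_directed():
        edges = sorted(graph.edges())
    else:
        edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


# --------------------------------------------------------------------------
# gene -> term annotations
# --------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: annotation table needs columns {sorted(required)}")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# provenance manifest
# --------------------------------------------------------------------------

def write_manifest(path: str | Path, config: Mapping, seed: int, inputs: Mapping[str, str] | None = None) -> None:
    """Record the configuration and seed of a run for provenance."""
    payload = {"seed": seed, "config": dict(config), "inputs": dict(inputs or {})}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
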