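"""Core in-memory containers shared by every pipeline stage.

The pipeline classifies ageing-related genes into a minority class
(dietary-restriction related, ``DR``) and a majority class (``NotDR``).
Instances are genes; features come from heterogeneous sources (pathway
membership, ontology annotations, graph topology, expression) and are either
binary or continuous, with explicit missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Class label of the minority (dietary-restriction related) class.
DR = "DR"
#: Class label of the majority class.
NOT_DR = "NotDR"

BINARY = "binary"
CONTINUOUS = "continuous"


class ValidationError(ValueError):
    """Raised when an input container violates a documented invariant."""


@dataclass(frozen=True)
class LabeledGeneSet:
    """Ordered gene identifiers with binary class labels.

    Parameters
    ----------
    labels
        Series indexed by unique gene id with values ``"DR"`` (minority)
        or ``"NotDR"`` (majority).
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        idx = self.labels.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        bad = set(self.labels.unique()) - {DR, NOT_DR}
        if bad:
            raise ValidationError(f"unknown class labels: {sorted(bad)}")

    @classmethod
    def from_arrays(cls, gene_ids: Sequence[str], labels: Sequence[str]) -> "LabeledGeneSet":
        return cls(pd.Series(list(labels), index=pd.Index(gene_ids, name="gene_id"), name="label"))

    @property
    def gene_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def y(self) -> np.ndarray:
        """Binary vector with 1 for the minority (DR) class."""
        return (self.labels == DR).to_numpy(dtype=int)

    @property
    def minority_ids(self) -> pd.Index:
        return self.labels.index[self.labels == DR]

    @property
    def majority_ids(self) -> pd.Index:
        return self.labels.index[self.labels == NOT_DR]

    def subset(self, gene_ids: Iterable[str]) -> "LabeledGeneSet":
        ids = pd.Index(list(gene_ids))
        missing = ids.difference(self.labels.index)
        if len(missing):
            raise KeyError(f"genes not in label set: {missing[:5].tolist()}")
        return LabeledGeneSet(self.labels.loc[ids])

    def __len__(self) -> int:
        return len(self.labels)


class FeatureMatrix:
    """Instances x features value table with per-feature kind and missing mask.

    Values live in a float DataFrame; missing cells are ``NaN``. ``kinds``
    maps each feature id to ``"binary"`` or ``"continuous"``; binary columns
    may only contain 0/1 where observed.
    """

    def __init__(self, values: pd.DataFrame, kinds: Mapping[str, str] | pd.Series | None = None):
        if values.index.has_duplicates:
            raise ValidationError("duplicate instance ids")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        self.values = values.astype(float)
        if kinds is None:
            kinds = {c: self._infer_kind(self.values[c]) for c in self.values.columns}
        kinds = pd.Series(dict(kinds) if not isinstance(kinds, pd.Series) else kinds)
        kinds = kinds.reindex(self.values.columns)
        if kinds.isna().any():
            missing = kinds.index[kinds.isna()].tolist()
            raise ValidationError(f"kind missing for features: {missing[:5]}")
        unknown = set(kinds.unique()) - {BINARY, CONTINUOUS}
        if unknown:
            raise ValidationError(f"unknown feature kinds: {sorted(unknown)}")
        self.kinds = kinds
        self._check_binary()

    @staticmethod
    def _infer_kind(col: pd.Series) -> str:
        obs = col.dropna().unique()
        return BINARY if set(obs) <= {0.0, 1.0} else CONTINUOUS

    def _check_binary(self) -> None:
        bin_cols = self.kinds.index[self.kinds == BINARY]
        if len(bin_cols):
            block = self.values[bin_cols]
            ok = block.isna() | block.isin([0.0, 1.0])
            if not ok.all().all():
                bad = ok.all()[~ok.all()].index.tolist()
                raise ValidationError(f"binary columns with non-{{0,1}} values: {bad[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def instance_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        ids = pd.Index(list(feature_ids))
        return FeatureMatrix(self.values[ids], self.kinds.loc[ids])

    def select_instances(self, instance_ids: Iterable[str]) -> "FeatureMatrix":
        ids = pd.Index(list(instance_ids))
        return FeatureMatrix(self.values.loc[ids], self.kinds)

    def binary_features(self) -> pd.Index:
        """Features routed to the binary branch: declared binary, or realising
        at most two values {0,1} in the observed cells."""
        out = []
        for c in self.values.columns:
            if self.kinds[c] == BINARY:
                out.append(c)
            else:
                obs = set(self.values[c].dropna().unique())
                if obs <= {0.0, 1.0}:
                    out.append(c)
        return pd.Index(out)

    def __repr__(self) -> str:  # pragma: no cover
        n_bin = int((self.kinds == BINARY).sum())
        return f"FeatureMatrix({self.shape[0]} instances x {self.shape[1]} features, {n_bin} binary)"


@dataclass
class AnnotationDAG:
    """Rooted term DAG (edges child -> parent) plus direct gene annotations.

    The root models the top of an ontology hierarchy (e.g. the
    biological-process root of the Gene Ontology); every term must be able to
    reach it. ``annotations`` are direct, un-propagated gene -> term links.
    """

    graph: nx.DiGraph
    root: str
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise ValidationError(f"annotation graph has a cycle through edge {cyc[0][:2]}")
        if self.root not in self.graph:
            raise ValidationError(f"root {self.root!r} not a term of the DAG")
        # every term reaches the root along child->parent edges
        can_reach = nx.ancestors(self.graph, self.root) | {self.root}
        stranded = set(self.graph.nodes) - can_reach
        if stranded:
            raise ValidationError(f"terms with no path to root: {sorted(stranded)[:5]}")
        for gene, terms in self.annotations.items():
            unknown = set(terms) - set(self.graph.nodes)
            if unknown:
                raise ValidationError(f"gene {gene} annotated to unknown terms {sorted(unknown)[:5]}")

    def ancestors_of(self, term: str) -> set[str]:
        """All ancestors of ``term`` following child->parent edges (term excluded)."""
        return nx.descendants(self.graph, term)


@dataclass
class PathwayGraph:
    """Directed intra-pathway interaction graph."""

    pathway_id: str
    graph: nx.DiGraph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class PPINetwork:
    """Undirected simple physical-interaction graph, optionally class-labeled."""

    graph: nx.Graph
    node_labels: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"PPI network contains self-loops: {loops[:3]}")
        if self.graph.is_multigraph():
            raise ValidationError("PPI network must be a simple graph")
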