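"""Run-time configuration objects.

``SimulationConfig`` parameterises the synthetic-data generators;
``RunConfig`` carries the knobs of the evaluation pipeline (fold counts,
preprocessing thresholds, classification threshold, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study-condition generators.

    Defaults emulate the study conditions the pipeline is designed for:
    a roughly 1:10 minority/majority class ratio, sparse binary annotation
    matrices with a planted subset of minority-enriched features, and
    continuous matrices with a controllable standardized class effect.
    """

    n_genes: int = 1137
    minority_fraction: float = 0.10
    n_binary_features: int = 200
    n_enriched_features: int = 10
    enrichment_odds: float = 5.0
    base_positive_rate: float = 0.04
    n_continuous_features: int = 50
    continuous_effect_size: float = 1.0
    dag_depth: int = 4
    dag_branching: int = 3
    graph_n_nodes: int = 60
    graph_edge_density: float = 0.08
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0.0 < self.minority_fraction < 1.0:
            raise ConfigurationError("minority_fraction must lie in (0, 1)")
        n_min = round(self.minority_fraction * self.n_genes)
        if n_min < 2 or self.n_genes - n_min < 2:
            raise ConfigurationError("each class needs at least 2 genes")
        if self.n_enriched_features > self.n_binary_features:
            raise ConfigurationError("n_enriched_features cannot exceed n_binary_features")
        if self.enrichment_odds <= 0:
            raise ConfigurationError("enrichment_odds must be positive")
        if not 0.0 <= self.base_positive_rate <= 1.0:
            raise ConfigurationError("base_positive_rate must lie in [0, 1]")
        if self.dag_depth < 1:
            raise ConfigurationError("dag_depth must be >= 1")
        if self.graph_n_nodes < 2:
            raise ConfigurationError("graph_n_nodes must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RunConfig:
    """Evaluation-pipeline configuration.

    ``thresholds_set`` is the candidate grid of minimum-occurrence cutoffs
    for binary features, tuned inside the inner cross-validation together
    with the classifier hyperparameters.
    """

    outer_folds: int = 10
    inner_folds: int = 5
    thresholds_set: tuple[int, ...] = (3, 4, 5)
    correlation_cutoff: float = 0.99
    univariate_k: int = 1000
    classification_threshold: float = 0.5
    significance_level: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        if self.outer_folds < 2:
            raise ConfigurationError("outer_folds must be >= 2")
        if self.inner_folds < 2:
            raise ConfigurationError("inner_folds must be >= 2")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ConfigurationError("classification_threshold must lie in (0, 1)")
        if not all(t >= 1 for t in self.thresholds_set):
            raise ConfigurationError("occurrence thresholds must be >= 1")
        if not 0.0 < self.correlation_cutoff <= 1.0:
            raise ConfigurationError("correlation_cutoff must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds_set"] = list(self.thresholds_set)
        return d
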