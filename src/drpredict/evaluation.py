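"""Nested cross-validation of imbalance-aware classifiers.

An outer stratified k-fold estimates generalisation; inside each outer
training set an inner k-fold selects the classifier hyperparameters and the
binary minimum-occurrence threshold jointly, by mean geometric mean of
sensitivity and specificity (Gmean) — the imbalance-robust criterion. The
winning configuration is refitted on the full outer training set and scored
on the untouched test fold. Test folds partition the instance set, so the
per-fold probabilities concatenate into one gene-indexed DR-probability
vector covering every gene exactly once.

Undersampling (discarding majority training genes until classes balance) is
applied per member inside the balanced ensembles, and once per training set
for algorithms without internal balancing. Test folds keep the original
imbalanced class distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .classifiers import ClassifierSpec, make_classifier
from .config import RunConfig
from .datatypes import FeatureMatrix, LabeledGeneSet, ValidationError
from .preprocessing import PreprocessPlan, plan_for_dataset


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return math.sqrt(sensitivity * specificity)


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    gmean: float
    auc: float

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, prob: np.ndarray, threshold: float = 0.5) -> "MetricSet":
        y_true = np.asarray(y_true)
        prob = np.asarray(prob, dtype=float)
        if set(np.unique(y_true)) != {0, 1}:
            raise ValidationError("metrics need both classes present in the evaluated fold")
        pred = (prob >= threshold).astype(int)
        pos, neg = y_true == 1, y_true == 0
        sens = float(np.mean(pred[pos] == 1))
        spec = float(np.mean(pred[neg] == 0))
        return cls(sens, spec, gmean(sens, spec), float(roc_auc_score(y_true, prob)))


def stratified_folds(
    labels: LabeledGeneSet,
    k: int,
    seed: int,
    groups: pd.Series | None = None,
) -> list[pd.Index]:
    """Split gene ids into k class-stratified folds (a partition).

    With ``groups`` given (e.g. protein rows sharing a gene), all instances
    of a group land in one fold and stratification applies at group level.
    Ids are sorted before splitting so the assignment depends only on the
    seed, not on input order.
    """
    n_minority = len(labels.minority_ids)
    if k > n_minority:
        raise ValidationError(f"cannot build {k} stratified folds with {n_minority} minority genes")
    ids = labels.gene_ids.sort_values()
    y = labels.subset(ids).y
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        grp = groups.loc[ids].to_numpy()
        splits = splitter.split(np.zeros(len(ids)), y, groups=grp)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(ids)), y)
    return [ids[test_idx] for _, test_idx in splits]


def undersample(train_ids: pd.Index, labels: LabeledGeneSet, seed: int) -> pd.Index:
    """Balance a training set: keep all minority genes, subsample majority
    genes without replacement down to the minority count."""
    sub = labels.subset(train_ids)
    minority = sub.minority_ids.sort_values()
    majority = sub.majority_ids.sort_values()
    if len(minority) == 0 or len(majority) == 0:
        raise ValidationError("undersampling needs both classes in the training set")
    rng = np.random.default_rng(seed)
    take = min(len(minority), len(majority))
    picked = rng.choice(len(majority), size=take, replace=False)
    return minority.append(majority[np.sort(picked)])


@dataclass
class FoldResult:
    test_ids: pd.Index
    probabilities: pd.Series
    chosen_params: dict[str, Any]
    chosen_threshold: int
    metrics: MetricSet


@dataclass
class EvaluationResult:
    """Outcome of one nested-CV run: per-fold detail plus the assembled
    gene-indexed DR-probability and DR-annotation vectors."""

    folds: list[FoldResult]
    aggregate: MetricSet
    probability_vector: pd.Series
    annotation_vector: pd.Series
    audit: list[tuple[str, int, frozenset]] = field(default_factory=list)

    def fold_metrics_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds):
            rows.append(
                {
                    "fold": i,
                    "n_test": len(f.test_ids),
                    "min_occurrence": f.chosen_threshold,
                    "sensitivity": f.metrics.sensitivity,
                    "specificity": f.metrics.specificity,
                    "gmean": f.metrics.gmean,
                    "auc": f.metrics.auc,
                    **{f"param_{k}": v for k, v in f.chosen_params.items()},
                }
            )
        return pd.DataFrame(rows)

    def probability_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probability": self.probability_vector, "annotation": self.annotation_vector}
        ).rename_axis("gene_id")


def _fit_plan(
    matrix: FeatureMatrix, labels: LabeledGeneSet, t: int, config: RunConfig
) -> PreprocessPlan:
    return plan_for_dataset(
        matrix, labels, min_occurrence=t,
        univariate_k=config.univariate_k, correlation_cutoff=config.correlation_cutoff,
    )


def _fit_and_score(
    spec: ClassifierSpec,
    params: dict,
    t: int,
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    train_ids: pd.Index,
    eval_ids: pd.Index,
    config: RunConfig,
    seed: int,
) -> tuple[Any, PreprocessPlan, pd.Series]:
    """Fit one configuration on ``train_ids`` and return the fitted model,
    the plan, and minority probabilities on ``eval_ids``."""
    train_labels = labels.subset(train_ids)
    plan = _fit_plan(matrix.select_instances(train_ids), train_labels, t, config)
    if not plan.retained:
        raise ValidationError("preprocessing retained no features")
    fit_ids = train_ids
    if not spec.handles_imbalance_internally:
        fit_ids = undersample(train_ids, labels, seed)
    x_train = plan.transform(matrix.select_instances(fit_ids)).values.to_numpy()
    y_train = labels.subset(fit_ids).y
    model = make_classifier(spec, params, seed)
    model.fit(x_train, y_train)
    x_eval = plan.transform(matrix.select_instances(eval_ids)).values.to_numpy()
    prob = model.predict_proba(x_eval)
    minority_col = int(np.flatnonzero(np.asarray(model.classes_) == 1)[0])
    return model, plan, pd.Series(prob[:, minority_col], index=eval_ids)


def inner_select(
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    spec: ClassifierSpec,
    config: RunConfig,
    seed: int,
    audit: list | None = None,
    fold_tag: int = -1,
) -> tuple[dict[str, Any], int, float]:
    """Choose (hyperparameters, occurrence threshold) by inner-CV mean Gmean.

    Every configuration is scored with the same inner fold split; the argmax
    is returned, ties broken by grid order (hyperparameters outer, thresholds
    inner). Undersampling and preprocessing are fitted inside inner training
    folds only.
    """
    inner = stratified_folds(labels, config.inner_folds, seed)
    all_ids = labels.gene_ids
    configurations = [
        (params, t) for params in spec.configurations() for t in config.thresholds_set
    ]
    if not configurations:
        raise ValidationError("empty configuration grid")
    best: tuple[dict, int] | None = None
    best_score = -np.inf
    failures: list[str] = []
    for params, t in configurations:
        scores = []
        try:
            for j, val_ids in enumerate(inner):
                train_ids = all_ids.difference(val_ids, sort=False).sort_values()
                if audit is not None:
                    audit.append(("inner_train", fold_tag, frozenset(train_ids)))
                _, _, prob = _fit_and_score(
                    spec, params, t, matrix, labels, train_ids, val_ids, config, seed + j
                )
                m = MetricSet.from_predictions(
                    labels.subset(val_ids).y, prob.to_numpy(), config.classification_threshold
                )
                scores.append(m.gmean)
        except (ValidationError, ValueError) as exc:
            failures.append(f"(params={params}, t={t}): {exc}")
            continue
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score = mean_score
            best = (params, t)
    if best is None:
        raise ValidationError(
            "every configuration failed to fit; first failure " + failures[0]
        )
    return best[0], best[1], best_score


def nested_cv(
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    spec: ClassifierSpec,
    config: RunConfig | None = None,
    groups: pd.Series | None = None,
) -> EvaluationResult:
    """Full nested cross-validation of one {dataset, algorithm} model.

    Returns per-fold metrics, their mean, and the concatenated DR-probability
    vector over all outer test folds. The ``audit`` trail records exactly
    which instance ids were visible to preprocessing fitting, undersampling
    and inner selection in each fold, so leakage is checkable after the fact.
    """
    config = config or RunConfig()
    if matrix.missing_mask.any().any():
        raise ValidationError("nested_cv requires a complete matrix; impute or intersect first")
    common = labels.gene_ids.intersection(matrix.instance_ids)
    if len(common) < len(labels.gene_ids):
        labels = labels.subset(common)
    matrix = matrix.select_instances(labels.gene_ids)
    outer = stratified_folds(labels, config.outer_folds, config.seed, groups)
    audit: list[tuple[str, int, frozenset]] = []
    folds: list[FoldResult] = []
    prob_parts, annot_parts = [], []
    for i, test_ids in enumerate(outer):
        train_ids = labels.gene_ids.difference(test_ids, sort=False).sort_values()
        train_labels = labels.subset(train_ids)
        train_matrix = matrix.select_instances(train_ids)
        audit.append(("preprocess_fit", i, frozenset(train_ids)))
        audit.append(("undersample_pool", i, frozenset(train_ids)))
        params, t, _ = inner_select(
            train_matrix, train_labels, spec, config, config.seed + 1000 * (i + 1),
            audit=audit, fold_tag=i,
        )
        _, _, prob = _fit_and_score(
            spec, params, t, matrix, labels, train_ids, test_ids, config, config.seed + i
        )
        m = MetricSet.from_predictions(
            labels.subset(test_ids).y, prob.to_numpy(), config.classification_threshold
        )
        folds.append(FoldResult(test_ids, prob, params, t, m))
        prob_parts.append(prob)
        annot_parts.append(labels.labels.loc[test_ids])
    aggregate = MetricSet(
        sensitivity=float(np.mean([f.metrics.sensitivity for f in folds])),
        specificity=float(np.mean([f.metrics.specificity for f in folds])),
        gmean=float(np.mean([f.metrics.gmean for f in folds])),
        auc=float(np.mean([f.metrics.auc for f in folds])),
    )
    probability_vector = pd.concat(prob_parts)
    annotation_vector = pd.concat(annot_parts)
    if probability_vector.index.has_duplicates or len(probability_vector) != len(labels):
        raise ValidationError("outer test folds failed to partition the instance set")
    return EvaluationResult(
        folds=folds,
        aggregate=aggregate,
        probability_vector=probability_vector,
        annotation_vector=annotation_vector,
        audit=audit,
    )
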