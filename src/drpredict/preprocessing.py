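"""Training-fold-fitted feature filters.

Binary features pass a minimum-occurrence filter (a feature must be positive
in at least ``t`` training genes, ``t`` tuned from a small candidate set
inside the inner cross-validation). Continuous features pass a univariate
ANOVA-F top-k filter followed by a greedy high-correlation filter. All
filters are fitted on training instances only and then applied unchanged to
held-out folds, so no test information leaks into feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .datatypes import BINARY, FeatureMatrix, LabeledGeneSet, ValidationError


@dataclass
class PreprocessPlan:
    """Fitted feature filter: the ordered list of retained feature ids.

    ``branch`` records which filter family produced each retained feature
    ("binary" or "continuous"), ``statistic`` an auditing score where the
    filter computes one (positive-occurrence count or F statistic).
    """

    retained: list[str]
    branch: dict[str, str] = field(default_factory=dict)
    statistic: dict[str, float] = field(default_factory=dict)

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        missing = [f for f in self.retained if f not in matrix.feature_ids]
        if missing:
            raise ValidationError(f"plan refers to unknown features: {missing[:5]}")
        return matrix.select_features(self.retained)

    def to_frame(self, all_features: pd.Index | None = None) -> pd.DataFrame:
        """Audit table: feature id, retained flag, branch, statistic."""
        feats = list(all_features) if all_features is not None else self.retained
        kept = set(self.retained)
        return pd.DataFrame(
            {
                "feature_id": feats,
                "retained": [f in kept for f in feats],
                "branch": [self.branch.get(f, "") for f in feats],
                "statistic": [self.statistic.get(f, np.nan) for f in feats],
            }
        )


def fit_min_occurrence(matrix: FeatureMatrix, t: int) -> PreprocessPlan:
    """Retain binary features positive in at least ``t`` fitting instances."""
    if t < 1:
        raise ValueError("occurrence threshold must be >= 1")
    non_binary = [
        c for c in matrix.feature_ids if not set(matrix.values[c].dropna().unique()) <= {0.0, 1.0}
    ]
    if non_binary:
        raise TypeError(f"min-occurrence filter requires binary columns; got {non_binary[:5]}")
    counts = (matrix.values == 1.0).sum(axis=0)
    retained = [c for c in matrix.feature_ids if counts[c] >= t]
    return PreprocessPlan(
        retained=retained,
        branch={c: "binary" for c in retained},
        statistic={c: float(counts[c]) for c in matrix.feature_ids},
    )


def fit_correlation_filter(matrix: FeatureMatrix, cutoff: float = 0.99) -> PreprocessPlan:
    """Greedy de-duplication of near-collinear continuous features.

    Walking columns in order, a feature is dropped iff its absolute Pearson
    correlation with an already-retained feature exceeds ``cutoff``
    ("keep the earlier column"). Zero-variance columns have undefined
    correlation, treated as 0 — they are retained unless they duplicate an
    already-retained constant column exactly.
    """
    if matrix.shape[0] < 2:
        raise ValidationError("correlation filter needs at least 2 instances")
    vals = matrix.values
    stds = vals.std(axis=0, ddof=0)
    constant = stds == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance columns: correlation treated as 0"
        )
    retained: list[str] = []
    for c in matrix.feature_ids:
        drop = False
        for r in retained:
            if constant[c] or constant[r]:
                if constant[c] and constant[r] and vals[c].equals(vals[r]):
                    drop = True
                    break
                continue
            pair = vals[[r, c]].dropna()
            if len(pair) < 2:
                continue
            corr = abs(pair[r].corr(pair[c]))
            if not np.isnan(corr) and corr > cutoff:
                drop = True
                break
        if not drop:
            retained.append(c)
    return PreprocessPlan(retained=retained, branch={c: "continuous" for c in retained})


def fit_univariate_k(matrix: FeatureMatrix, labels: LabeledGeneSet, k: int) -> PreprocessPlan:
    """Retain the k features with the largest one-way ANOVA F statistic
    against the binary class label; all features when fewer than k."""
    y = labels.subset(matrix.instance_ids).y
    if len(np.unique(y)) < 2:
        raise ValidationError("univariate filter needs both classes present")
    x = matrix.values.fillna(matrix.values.mean()).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield F=nan
        f_stats, _ = f_classif(x, y)
    f_stats = np.nan_to_num(f_stats, nan=0.0)
    order = np.argsort(-f_stats, kind="stable")
    keep_pos = sorted(order[: min(k, len(order))])
    retained = [matrix.feature_ids[i] for i in keep_pos]
    return PreprocessPlan(
        retained=retained,
        branch={c: "continuous" for c in retained},
        statistic={matrix.feature_ids[i]: float(f_stats[i]) for i in range(len(f_stats))},
    )


def plan_for_dataset(
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    min_occurrence: int,
    univariate_k: int = 1000,
    correlation_cutoff: float = 0.99,
) -> PreprocessPlan:
    """Dispatch features to the binary or continuous filter branch.

    Columns whose observed values realise only {0, 1} are routed to the
    binary branch even when typed continuous (two-valued scores behave like
    indicators). Continuous columns pass the univariate top-k filter and then
    the correlation filter. Retained set = union of both branches, in
    original column order.
    """
    binary_cols = matrix.binary_features()
    continuous_cols = matrix.feature_ids.difference(binary_cols, sort=False)
    plans: list[PreprocessPlan] = []
    if len(binary_cols):
        plans.append(fit_min_occurrence(matrix.select_features(binary_cols), min_occurrence))
    if len(continuous_cols):
        cont = matrix.select_features(continuous_cols)
        uni = fit_univariate_k(cont, labels, univariate_k)
        corr = fit_correlation_filter(uni.transform(cont), correlation_cutoff)
        corr.statistic = {c: uni.statistic.get(c, np.nan) for c in corr.retained}
        plans.append(corr)
    retained_set = {c for p in plans for c in p.retained}
    retained = [c for c in matrix.feature_ids if c in retained_set]
    branch = {c: b for p in plans for c, b in p.branch.items()}
    statistic = {c: s for p in plans for c, s in p.statistic.items()}
    return PreprocessPlan(retained=retained, branch=branch, statistic=statistic)
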