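"""Feature relevance for a fitted model, rescaled to [0, 100].

Two routes: the impurity (Gini) importances a tree ensemble exposes, and a
model-agnostic permutation importance measured as the drop in training-set
Gmean when one feature's column is shuffled. Raw scores are min-max rescaled
to [0, 100] so rankings from different models are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, LabeledGeneSet
from .evaluation import gmean


@dataclass
class ImportanceRanking:
    """Per-feature raw and [0, 100]-rescaled scores, sorted descending."""

    scores: pd.DataFrame  # columns: raw, scaled
    method: str

    @property
    def ranked_features(self) -> pd.Index:
        return self.scores.index

    def top(self, k: int) -> pd.Index:
        return self.scores.index[:k]

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["method"] = self.method
        return out.rename_axis("feature_id")


def rescale_0_100(raw: pd.Series) -> pd.Series:
    """Affine min-max map to [0, 100].

    Degenerate constant vectors have no spread to map: all-zero (or negative)
    scores rescale to 0, while a constant positive vector rescales to 100 —
    the feature(s) carry all the importance there is (this keeps a
    single-feature model at score 100).
    """
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        warnings.warn("constant importance vector; rescaling is degenerate")
        return pd.Series(100.0 if hi > 0 else 0.0, index=raw.index)
    return 100.0 * (raw - lo) / (hi - lo)


def _ranking(raw: pd.Series, method: str) -> ImportanceRanking:
    scaled = rescale_0_100(raw)
    df = pd.DataFrame({"raw": raw, "scaled": scaled})
    # descending score; stable sort after an index sort makes ties break on feature id
    df = df.sort_index(kind="mergesort").sort_values("scaled", ascending=False, kind="mergesort")
    return ImportanceRanking(scores=df, method=method)


def impurity_importance(model, feature_ids) -> ImportanceRanking:
    """Mean impurity-decrease importances of a fitted tree ensemble,
    min-max rescaled to [0, 100]."""
    if not hasattr(model, "feature_importances_"):
        raise TypeError("model exposes no impurity-based feature importances")
    raw = pd.Series(np.asarray(model.feature_importances_, dtype=float), index=list(feature_ids))
    return _ranking(raw, method="impurity")


def permutation_importance(
    model,
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    n_repeats: int = 10,
    seed: int = 42,
    threshold: float = 0.5,
) -> ImportanceRanking:
    """Mean Gmean drop when one feature column is randomly permuted.

    The model must already be fitted on ``matrix`` (the full gene set is the
    training set for this analysis). Negative drops — permutations that
    accidentally help — are floored at 0 before rescaling.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = matrix.values.to_numpy().copy()
    y = labels.subset(matrix.instance_ids).y
    minority_col = int(np.flatnonzero(np.asarray(model.classes_) == 1)[0])

    def score(xm: np.ndarray) -> float:
        prob = model.predict_proba(xm)[:, minority_col]
        pred = (prob >= threshold).astype(int)
        sens = float(np.mean(pred[y == 1] == 1))
        spec = float(np.mean(pred[y == 0] == 0))
        return gmean(sens, spec)

    baseline = score(x)
    rng = np.random.default_rng(seed)
    drops = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        deltas = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            deltas.append(baseline - score(xp))
        drops[j] = max(0.0, float(np.mean(deltas)))
    raw = pd.Series(drops, index=matrix.feature_ids)
    return _ranking(raw, method="permutation")
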