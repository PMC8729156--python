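"""Novel-candidate inference from classifier probabilities.

A majority-annotated gene that a well-performing model nevertheless assigns
a minority (DR) probability at or above the classification threshold is a
"false positive" in cross-validation terms — and a candidate novel DR gene
in biological terms. Candidates are ranked per model by probability, and
fused across two models by min-max normalising each model's probability
vector over its full gene set and averaging the normalised scores of the
genes the models share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DR, NOT_DR, ValidationError
from .evaluation import EvaluationResult


def _vectors(result: EvaluationResult | tuple[pd.Series, pd.Series]) -> tuple[pd.Series, pd.Series]:
    if isinstance(result, EvaluationResult):
        return result.probability_vector, result.annotation_vector
    prob, annot = result
    if not prob.index.equals(annot.index):
        prob, annot = prob.align(annot, join="inner")
    return prob, annot


def false_positive_ranking(
    result: EvaluationResult | tuple[pd.Series, pd.Series],
    threshold: float = 0.5,
    top_k: int = 10,
) -> pd.DataFrame:
    """Majority-annotated genes with DR-probability >= threshold, ranked.

    Sorted by descending probability with ties broken on gene id; the first
    ``top_k`` rows are flagged. An empty result (no candidate crosses the
    threshold) is returned as an empty frame, not an error.
    """
    prob, annot = _vectors(result)
    mask = (annot == NOT_DR) & (prob >= threshold)
    sub = prob[mask]
    df = pd.DataFrame({"probability": sub, "annotation": annot[mask]}).rename_axis("gene_id")
    df = df.sort_index(kind="mergesort").sort_values("probability", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["top_k"] = df["rank"] <= top_k
    return df


def normalize_scores(prob: pd.Series) -> pd.Series:
    """Affine min-max map of a probability vector onto [0, 1].

    Computed over the model's full gene set so that the two models' scores
    live on one comparison scale regardless of how wide each model's raw
    probability distribution is.
    """
    lo, hi = float(prob.min()), float(prob.max())
    if hi == lo:
        raise ValidationError("cannot normalize a constant probability vector")
    return (prob - lo) / (hi - lo)


def joint_ranking(
    result_a: EvaluationResult | tuple[pd.Series, pd.Series],
    result_b: EvaluationResult | tuple[pd.Series, pd.Series],
    mean_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Fuse two models' scores over their common genes.

    Each model's probabilities are min-max normalised over its own full gene
    set; common genes get the arithmetic mean of the two normalised scores.
    Reported rows are the majority-annotated common genes whose mean exceeds
    ``mean_cutoff``, with each model's rank computed among the common
    majority-class genes.
    """
    prob_a, annot_a = _vectors(result_a)
    prob_b, annot_b = _vectors(result_b)
    norm_a = normalize_scores(prob_a)
    norm_b = normalize_scores(prob_b)
    common = norm_a.index.intersection(norm_b.index)
    if len(common) == 0:
        raise ValidationError("the two models share no genes")
    annot = annot_a.loc[common]
    df = pd.DataFrame(
        {
            "score_a": norm_a.loc[common],
            "score_b": norm_b.loc[common],
            "annotation": annot,
        }
    ).rename_axis("gene_id")
    df["mean_score"] = (df["score_a"] + df["score_b"]) / 2.0
    majority = df[df["annotation"] == NOT_DR].copy()
    majority["rank_a"] = majority["score_a"].rank(ascending=False, method="min").astype(int)
    majority["rank_b"] = majority["score_b"].rank(ascending=False, method="min").astype(int)
    out = majority[majority["mean_score"] > mean_cutoff]
    out = out.sort_index(kind="mergesort").sort_values("mean_score", ascending=False, kind="mergesort")
    out = out.copy()
    out["joint_rank"] = np.arange(1, len(out) + 1)
    return out


def score_correlation(
    result_a: EvaluationResult | tuple[pd.Series, pd.Series],
    result_b: EvaluationResult | tuple[pd.Series, pd.Series],
) -> dict[str, float]:
    """Pearson correlation of the two models' normalised scores on common
    genes: overall, within the minority class, within the majority class."""
    prob_a, annot_a = _vectors(result_a)
    prob_b, _ = _vectors(result_b)
    norm_a = normalize_scores(prob_a)
    norm_b = normalize_scores(prob_b)
    common = norm_a.index.intersection(norm_b.index)
    annot = annot_a.loc[common]
    out = {}
    for name, ids in [
        ("overall", common),
        ("minority", common[annot == DR]),
        ("majority", common[annot == NOT_DR]),
    ]:
        if len(ids) < 3:
            raise ValidationError(f"stratum {name!r} has fewer than 3 common genes")
        out[name] = float(stats.pearsonr(norm_a.loc[ids], norm_b.loc[ids]).statistic)
    return out


def probability_density_summary(
    result: EvaluationResult | tuple[pd.Series, pd.Series],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-class histogram of DR-probabilities over [0, 1] plus the peak bin.

    Bins partition [0, 1]; counts per class sum to the class sizes. The
    ``peak`` column marks, per class, the centre of its most populated bin.
    """
    prob, annot = _vectors(result)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    rows = []
    for cls in (DR, NOT_DR):
        vals = prob[annot == cls].to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        peak = centers[int(np.argmax(counts))] if len(vals) else np.nan
        for c, center in zip(counts, centers):
            rows.append(dict(annotation=cls, bin_center=center, count=int(c), peak=peak))
    return pd.DataFrame(rows)
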