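"""Class-enrichment statistics for selected features.

For a binary feature, a two-proportion z-test asks whether the fraction of
minority (DR) genes carrying the annotation differs from the fraction of
majority genes carrying it; for a continuous feature a Welch t-test compares
class means. P-values are adjusted across the tested family with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BINARY, FeatureMatrix, LabeledGeneSet, ValidationError


def two_proportion_test(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided pooled-variance two-proportion z-test p-value.

    Degenerate pooled proportions (0 or 1, i.e. the annotation is absent or
    universal in both groups combined) return p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("counts must lie within their group sizes")
    pooled = (a + b) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (a / n1 - b / n2) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def welch_t_test(x_minority: Sequence[float], x_majority: Sequence[float]) -> float:
    """Two-sided unequal-variance (Welch) t-test p-value.

    Two constant, equal groups make the statistic 0/0; that degenerate case
    returns p = 1 with a warning.
    """
    x1 = np.asarray(x_minority, dtype=float)
    x2 = np.asarray(x_majority, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(x1) == 0.0 and np.std(x2) == 0.0 and np.mean(x1) == np.mean(x2):
        warnings.warn("both groups constant and equal; p set to 1")
        return 1.0
    return float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    matrix: FeatureMatrix,
    labels: LabeledGeneSet,
    feature_ids: Sequence[str] | None = None,
    alpha: float = 0.01,
    adjust_within: str = "all",
) -> pd.DataFrame:
    """Per-feature enrichment rows with counts, proportions and p-values.

    ``adjust_within`` sets the multiple-testing family: ``"all"`` adjusts
    over every feature of the matrix (then reports the requested subset),
    ``"selected"`` over the requested features only. Proportions are reported
    in percent at two decimals, recomputable from the stored counts.
    """
    if adjust_within not in {"all", "selected"}:
        raise ValueError("adjust_within must be 'all' or 'selected'")
    labels = labels.subset(matrix.instance_ids)
    minority = labels.minority_ids
    majority = labels.majority_ids
    if len(minority) == 0 or len(majority) == 0:
        raise ValidationError("both classes required")
    family = list(matrix.feature_ids) if adjust_within == "all" else list(feature_ids or matrix.feature_ids)
    rows = []
    for feat in family:
        col = matrix.values[feat]
        if matrix.kinds[feat] == BINARY:
            a = int((col.loc[minority] == 1.0).sum())
            b = int((col.loc[majority] == 1.0).sum())
            n1, n2 = int(col.loc[minority].notna().sum()), int(col.loc[majority].notna().sum())
            p = two_proportion_test(a, n1, b, n2)
            rows.append(
                dict(feature_id=feat, kind=BINARY, minority_positives=a, n_minority=n1,
                     majority_positives=b, n_majority=n2,
                     minority_pct=round(100.0 * a / n1, 2), majority_pct=round(100.0 * b / n2, 2),
                     p_raw=p)
            )
        else:
            x1 = col.loc[minority].dropna().to_numpy()
            x2 = col.loc[majority].dropna().to_numpy()
            p = welch_t_test(x1, x2)
            rows.append(
                dict(feature_id=feat, kind="continuous", minority_positives=np.nan,
                     n_minority=len(x1), majority_positives=np.nan, n_majority=len(x2),
                     minority_pct=np.nan, majority_pct=np.nan, p_raw=p)
            )
    table = pd.DataFrame(rows).set_index("feature_id")
    table["p_adjusted"] = benjamini_hochberg(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha
    if feature_ids is not None:
        table = table.loc[list(feature_ids)]
    return table
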