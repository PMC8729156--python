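"""Nested cross-validation: metrics, folds, undersampling, model selection,
and the no-leakage guarantee."""

import numpy as np
import pandas as pd
import pytest

from drpredict import (
    DR,
    NOT_DR,
    ClassifierSpec,
    RunConfig,
    SimulationConfig,
    ValidationError,
    gmean,
    nested_cv,
    stratified_folds,
    undersample,
)
from drpredict.evaluation import MetricSet, inner_select
from drpredict.synthetic_data import simulate_binary_matrix, simulate_labels
from tests.conftest import make_labels


class TestGmean:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            (1.0, 1.0, 1.0),
            (0.0, 0.9, 0.0),
            (0.77, 0.77, 0.77),  # equal-rate fixed point
            (0.87, 0.67, 0.7634788799),
        ],
    )
    def test_values(self, sens, spec, expected):
        assert gmean(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gmean(1.2, 0.5)

    def test_metricset_consistency(self):
        y = np.array([1, 1, 0, 0, 0])
        prob = np.array([0.9, 0.2, 0.1, 0.8, 0.3])
        m = MetricSet.from_predictions(y, prob)
        assert m.gmean == pytest.approx(np.sqrt(m.sensitivity * m.specificity))
        assert 0 <= m.auc <= 1


class TestStratifiedFolds:
    def test_one_minority_per_fold(self):
        labels = make_labels(10, 90)
        folds = stratified_folds(labels, k=10, seed=0)
        for fold in folds:
            assert (labels.labels.loc[fold] == DR).sum() == 1

    def test_partition(self):
        labels = make_labels(10, 90)
        folds = stratified_folds(labels, k=10, seed=1)
        union = folds[0]
        for f in folds[1:]:
            assert len(union.intersection(f)) == 0
            union = union.union(f)
        assert set(union) == set(labels.gene_ids)

    def test_groups_never_split(self):
        labels = make_labels(6, 24, prefix="p")
        # three proteins per gene
        groups = pd.Series(
            [f"gene{i // 3}" for i in range(30)], index=labels.gene_ids
        )
        folds = stratified_folds(labels, k=3, seed=2, groups=groups)
        for fold in folds:
            grp = set(groups.loc[fold])
            others = [g for f in folds if f is not fold for g in groups.loc[f]]
            assert grp.isdisjoint(others)

    def test_too_many_folds_rejected(self):
        labels = make_labels(3, 30)
        with pytest.raises(ValidationError):
            stratified_folds(labels, k=5, seed=0)

    def test_seed_determines_assignment_regardless_of_order(self):
        labels = make_labels(10, 40)
        shuffled = labels.subset(labels.gene_ids[::-1])
        a = stratified_folds(labels, k=5, seed=3)
        b = stratified_folds(shuffled, k=5, seed=3)
        assert [set(f) for f in a] == [set(f) for f in b]


class TestUndersample:
    def test_balanced_output(self):
        labels = make_labels(10, 100)
        picked = undersample(labels.gene_ids, labels, seed=0)
        sub = labels.subset(picked)
        assert len(picked) == 20
        assert len(sub.minority_ids) == 10 and len(sub.majority_ids) == 10

    def test_already_balanced_identity(self):
        labels = make_labels(9, 9)
        picked = undersample(labels.gene_ids, labels, seed=0)
        assert set(picked) == set(labels.gene_ids)

    def test_deterministic(self):
        labels = make_labels(10, 100)
        a = undersample(labels.gene_ids, labels, seed=5)
        b = undersample(labels.gene_ids, labels, seed=5)
        assert list(a) == list(b)


def signal_setup(n_genes=300, odds=8.0, seed=0):
    cfg = SimulationConfig(
        n_genes=n_genes, minority_fraction=0.1, n_binary_features=40,
        n_enriched_features=6, enrichment_odds=odds, base_positive_rate=0.05,
        seed=seed,
    )
    labels = simulate_labels(cfg)
    matrix, planted = simulate_binary_matrix(labels, cfg)
    return labels, matrix, planted


FAST_SPEC = ClassifierSpec("balanced-bagged-trees", {"n_estimators": [25]})


class TestInnerSelect:
    def test_single_configuration_returned(self):
        labels, matrix, _ = signal_setup()
        config = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,))
        params, t, score = inner_select(matrix, labels, FAST_SPEC, config, seed=1)
        assert params == {"n_estimators": 25} and t == 3

    def test_tie_breaks_to_first_configuration(self):
        labels, matrix, _ = signal_setup()
        spec = ClassifierSpec("balanced-bagged-trees", {"n_estimators": [25, 25]})
        config = RunConfig(inner_folds=3, thresholds_set=(3,), seed=0)
        params, t, _ = inner_select(matrix, labels, spec, config, seed=1)
        assert params == {"n_estimators": 25}

    def test_threshold_that_keeps_signal_features_wins(self):
        # planted features positive in exactly 4 minority training genes:
        # a min-occurrence threshold of 5 deletes them, 3 keeps them
        rng = np.random.default_rng(0)
        labels = make_labels(12, 108)
        n = len(labels)
        data = (rng.random((n, 20)) < 0.02).astype(float)
        y = labels.y.astype(bool)
        minority_rows = np.flatnonzero(y)
        for j in range(6):  # signal features: 4 distinct minority positives each
            data[:, j] = 0.0
            rows = rng.choice(minority_rows, size=4, replace=False)
            data[rows, j] = 1.0
        df = pd.DataFrame(data, index=labels.gene_ids, columns=[f"f{j:02d}" for j in range(20)])
        from drpredict import FeatureMatrix

        matrix = FeatureMatrix(df)
        config = RunConfig(inner_folds=3, thresholds_set=(3, 5), seed=0)
        _, t, _ = inner_select(matrix, labels, FAST_SPEC, config, seed=2)
        assert t == 3


class TestNestedCV:
    def test_structure_and_probability_vector(self):
        labels, matrix, _ = signal_setup()
        config = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,), seed=0)
        result = nested_cv(matrix, labels, FAST_SPEC, config)
        assert len(result.folds) == 5
        assert len(result.probability_vector) == len(labels)
        assert not result.probability_vector.index.has_duplicates
        pd.testing.assert_series_equal(
            result.annotation_vector.sort_index(), labels.labels.sort_index(),
            check_names=False,
        )
        for f in result.folds:
            assert f.metrics.gmean == pytest.approx(
                np.sqrt(f.metrics.sensitivity * f.metrics.specificity)
            )

    def test_permuted_labels_near_chance(self):
        labels, matrix, _ = signal_setup(n_genes=300, odds=1.0, seed=3)
        config = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,), seed=0)
        aucs = []
        for seed in range(3):
            cfg = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,), seed=seed)
            aucs.append(nested_cv(matrix, labels, FAST_SPEC, cfg).aggregate.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_strong_signal_learnable(self):
        labels, matrix, _ = signal_setup(n_genes=400, odds=10.0, seed=4)
        config = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,), seed=0)
        result = nested_cv(matrix, labels, FAST_SPEC, config)
        assert result.aggregate.gmean > 0.6
        assert result.aggregate.auc > 0.7

    def test_missing_values_rejected(self):
        labels, matrix, _ = signal_setup()
        vals = matrix.values.copy()
        vals.iloc[0, 0] = np.nan
        from drpredict import FeatureMatrix

        holed = FeatureMatrix(vals, matrix.kinds)
        with pytest.raises(ValidationError, match="impute"):
            nested_cv(holed, labels, FAST_SPEC, RunConfig(outer_folds=3, inner_folds=2))

    def test_no_test_fold_instance_reaches_training_stages(self):
        # leakage guard: audit trail covers preprocessing fitting, the
        # undersampling pool and every inner-CV training set
        labels, matrix, _ = signal_setup(n_genes=200)
        config = RunConfig(outer_folds=4, inner_folds=3, thresholds_set=(3,), seed=0)
        result = nested_cv(matrix, labels, FAST_SPEC, config)
        fold_tests = {i: set(f.test_ids) for i, f in enumerate(result.folds)}
        stages_seen = set()
        for stage, fold, ids in result.audit:
            stages_seen.add(stage)
            if fold >= 0:
                assert fold_tests[fold].isdisjoint(ids), f"{stage} saw test instances"
        assert {"preprocess_fit", "undersample_pool", "inner_train"} <= stages_seen


class TestGradientBoostingAdapter:
    def test_xgboost_runs_with_external_undersampling(self):
        pytest.importorskip("xgboost")
        labels, matrix, _ = signal_setup(n_genes=300, odds=10.0, seed=6)
        spec = ClassifierSpec("gradient-boosting-xgb", {"n_estimators": [30]})
        assert not spec.handles_imbalance_internally
        config = RunConfig(outer_folds=3, inner_folds=2, thresholds_set=(3,), seed=0)
        result = nested_cv(matrix, labels, spec, config)
        assert result.aggregate.auc > 0.6
        assert len(result.probability_vector) == len(labels)
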