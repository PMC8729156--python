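"""Infer novel DR-candidate genes from two models' probability vectors.

Trains two models on different feature types over the same genes, then:
(1) ranks majority-annotated genes whose predicted DR-probability crosses
0.5 — cross-validated "false positives", i.e. candidate novel DR genes;
(2) min-max normalises each model's probabilities and averages them over
the shared genes, reporting candidates both models agree on; and
(3) reports the correlation between the two models' scores.
"""

from drpredict import (
    ClassifierSpec,
    RunConfig,
    SimulationConfig,
    false_positive_ranking,
    joint_ranking,
    nested_cv,
    score_correlation,
)
from drpredict.synthetic_data import (
    simulate_binary_matrix,
    simulate_continuous_matrix,
    simulate_labels,
)

cfg = SimulationConfig(
    n_genes=600, minority_fraction=0.1, n_binary_features=80,
    n_enriched_features=8, enrichment_odds=8.0, base_positive_rate=0.05,
    n_continuous_features=40, continuous_effect_size=1.2, seed=42,
)
labels = simulate_labels(cfg)
binary, _ = simulate_binary_matrix(labels, cfg)
continuous, _ = simulate_continuous_matrix(labels, cfg)

spec = ClassifierSpec("balanced-bagged-trees", {"n_estimators": [50]})
run = RunConfig(outer_folds=5, inner_folds=3, thresholds_set=(3,), seed=42)
model_a = nested_cv(binary, labels, spec, run)
model_b = nested_cv(continuous, labels, spec, run)
print(f"model A (annotations): gmean={model_a.aggregate.gmean:.2f}")
print(f"model B (expression):  gmean={model_b.aggregate.gmean:.2f}")

fp = false_positive_ranking(model_a, threshold=0.5, top_k=10)
print(f"\nmodel A candidates (majority-annotated, P(DR) >= 0.5): {len(fp)}")
print(fp.head(5).round(3).to_string())

# the default cutoff of 0.8 is strict; 0.6 here keeps the demo populated
joint = joint_ranking(model_a, model_b, mean_cutoff=0.6)
print(f"\njoint candidates with mean normalised score > 0.6: {len(joint)}")
print(joint[["score_a", "score_b", "mean_score", "rank_a", "rank_b"]].head(5)
      .round(3).to_string())

r = score_correlation(model_a, model_b)
print(f"\nscore correlation overall={r['overall']:.2f} "
      f"minority={r['minority']:.2f} majority={r['majority']:.2f}")
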