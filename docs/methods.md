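# Methods

This note documents the models and procedures implemented in `drpredict`,
the assumptions behind them, the parameters that matter, and the places
where the design was genuinely open.

## Problem setting

Instances are ageing-related genes; the target is a binary DR-relatedness
label with a minority class (`DR`) roughly ten times smaller than the
majority (`NotDR`). Features are heterogeneous: sparse binary annotation
indicators (pathway membership, ontology terms, interaction adjacency) and
continuous scores (expression-like values, pathway influence, network
topology). The pipeline estimates how predictive each feature type is,
which features drive the predictions, and which majority-annotated genes
look like mislabeled minority genes — the candidate novel DR genes.

## Feature construction

**Membership matrices.** One binary column per gene set; a cell is 1 iff
the gene belongs to the set. Genes with no membership are kept as all-zero
rows; dropping them is a caller decision because different sources cover
different gene subsets.

**Ontology closure.** Direct gene→term annotations are closed under the
true-path rule: a gene annotated to a term is annotated to every ancestor up
to the single root. Closure is computed by ancestor reachability on the
child→parent DAG and is idempotent. Genes with no annotation at all are
dropped from the resulting matrix — they carry no information for this
feature type, only coverage noise.

**Pathway influence.** For a directed pathway graph, the influence a
reference node *r* exerts on a target *t* is
`1 − |S₋ᵣ(t)|/|S(t)|`, where `S(t)` is the set of source nodes (zero
in-degree; all nodes if the graph is source-free, e.g. fully cyclic) from
which *t* is reachable and `S₋ᵣ(t)` the same after deleting *r*. The value
is 1 when every upstream route to *t* passes through *r*, 0 when none does,
and 0 for targets not downstream of *r*. A gene's per-pathway feature value
is the mean influence over all other nodes of the pathway, 0 if the gene is
absent. Both the ratio definition and the mean aggregation are package
design choices — the influence notion is stated qualitatively in the
literature this mirrors, not as a formula — and they are isolated behind
`influence_profile` so an alternative is a drop-in replacement.

**Network measures.** Eighteen per-node measures on the undirected
interaction network: degree, closeness, betweenness (unnormalised pair
counts), eigenvector (dense leading eigenvector; robust on very small
graphs), per-component eccentricity, k-core number, clustering coefficient,
subgraph centrality, topological coefficient, leverage, Markov centrality
(inverse mean first-passage time via the fundamental matrix, per connected
component), maximum neighborhood component, Laplacian centrality
(unnormalised energy drop), diffusion degree (propagation probability 1),
semilocal centrality, geodesic k-path (k = 3), lobby index (h-index of
neighbour degrees), and the DR-ratio — the fraction of a node's direct
neighbours carrying the minority label. Isolated nodes take the natural
degenerate values (0 almost everywhere; subgraph centrality is 1 by its
closed-walk definition). Measures are computed on the full network,
including unlabeled interactors, then sliced to the labeled genes.

**Merge, imputation, intersection.** Merging takes the union of instances
and the concatenation of columns (prefixed per source); a gene absent from
a source gets missing cells there. 5NN imputation fills a gene's missing
feature from the 5 nearest training genes that observe it, with distance =
mean squared difference over the features both genes observe (the *mean*
rather than the sum keeps genes with different missingness comparable).
Continuous features impute the neighbour mean, binary features the
neighbour mode with ties resolving to 0 — absence is the majority state of
sparse annotations. Fewer than 5 eligible neighbours → use all (warning);
none → training-column mean/mode (warning). The complete-case alternative
(`intersect_complete`) keeps only genes observed everywhere.

## Preprocessing

Features route by realised values, not declared type: any column realising
only {0, 1} is treated as binary (two-valued continuous scores behave like
indicators). Binary features must be positive in at least *t* training
genes, with *t* tuned over the candidate set {3, 4, 5} inside the inner
cross-validation. Continuous features pass a one-way ANOVA-F top-k filter
(default k = 1000) and then a greedy correlation filter: walking columns in
order, a feature is dropped iff its absolute Pearson correlation with an
already-retained feature exceeds 0.99 ("keep the earlier column" — the
deterministic tie rule). Absolute correlation is used; zero-variance
columns are retained (correlation treated as 0) unless they duplicate an
already-retained constant exactly. All filters are fitted on training
instances only; the evaluation engine re-fits them inside every inner and
outer training set. Fitting them once on the full dataset is possible by
calling `plan_for_dataset` directly, but leaks label information into
feature selection and is not what the evaluator does.

## Evaluation

Nested cross-validation: 10 stratified outer folds (default) wrap a 5-fold
inner loop that scores every (hyperparameter configuration × occurrence
threshold) pair by mean validation Gmean and returns the argmax, ties
broken by grid order. The winner is refitted on the full outer training set
and scored on the untouched test fold; classification uses a fixed 0.5
probability threshold, AUC comes from the rank statistic on the test fold,
and fold metrics are averaged. Configurations that fail to fit (e.g. a
threshold that deletes every feature) simply lose the selection; an error
is raised only if all fail. With a `groups` series (e.g. several protein
rows per gene) folds are built at group level so no group straddles folds.

Class imbalance is handled by undersampling: all minority training genes
are kept and the majority is subsampled without replacement to the minority
count. The built-in `balanced-bagged-trees` ensemble (also exposed as
`balanced-random-forest`, which is the same balanced-bagging concept over
randomized trees) draws an independent balanced resample per member tree —
bootstrap of the minority plus a fresh majority undersample — and averages
member probabilities. `easy-ensemble` applies the same wrapper to AdaBoost
members. Gradient boosting (XGBoost; CatBoost if installed) has no internal
balancing, so the engine undersamples its training set once before fitting;
whether balancing happens per member or per training set is ambiguous in
the source procedure and this choice is documented rather than hidden.

Every run records an audit trail of exactly which instance ids were visible
to preprocessing fitting, the undersampling pool and each inner training
set, so the no-leakage property is a checkable assertion, not a promise.

## Importance and enrichment

Impurity importance passes through the ensemble's mean Gini importance.
Permutation importance is the mean drop in training-set Gmean over
`n_repeats` (default 10) independent permutations of one column, negative
drops floored at 0; Gmean (not plain accuracy) is used so the metric
matches the pipeline's selection criterion. Both are min-max rescaled to
[0, 100]. A constant raw vector has no spread to map: all-zero scores
rescale to 0, a constant positive vector to 100 (so a single-feature model
scores 100); both warn.

Binary features are tested by a two-sided pooled-variance two-proportion
z-test (degenerate pooled proportions return p = 1), continuous features by
a Welch t-test (chosen over the pooled-variance t-test for robustness).
The Benjamini–Hochberg family defaults to *all* features of the matrix,
with `adjust_within="selected"` as the configurable alternative — the
appropriate family is context-dependent and left explicit.

## Candidate inference

The outer test folds partition the gene set, so the fold probabilities
concatenate into one DR-probability vector per model. Candidates are
majority-annotated genes with probability ≥ 0.5, ranked descending with
lexicographic gene-id tie-break. For two models, each probability vector is
min-max normalised over that model's full gene set (not the intersection —
normalising first keeps each model's distribution shape), common genes get
the arithmetic mean of the two normalised scores, and majority-annotated
common genes above the mean cutoff (default 0.8) are reported with
per-model ranks among the common majority genes. Pearson correlations of
the normalised scores are reported overall and within each class.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
biology: exact `round(minority_fraction·n)` minority labels at uniform
positions; sparse binary matrices whose planted columns are positive with
probability `min(1, base_rate·odds)` in the minority class; layered random
DAGs with a single root and 1–2 parents per node; acyclic directed pathway
graphs (ordered nodes, forward edges only, guaranteeing a source);
preferential-attachment interaction networks with ~20% unlabeled extra
nodes; and Gaussian matrices whose planted columns shift the minority mean
by a standardized effect size. One integer seed drives everything through
per-artifact-kind substreams, so regenerating one artifact never perturbs
another. Defaults (n = 1137 genes, minority fraction 0.10, base positive
rate 0.04, enrichment odds 5, effect size 1 SD) reflect the scale and
sparsity of the curated-annotation setting the pipeline targets.

What passing tests on these data do show: the pipeline is calibrated under
the null (AUC ≈ 0.5 without planted signal), recovers planted signal
(Gmean > 0.7 and full importance-rank recovery at eightfold enrichment,
2000 genes, 1:10 imbalance), and never leaks test information. What they do
not show: performance on real curated databases, whose annotation
correlations, ontology topology and degree distributions are richer than
the generators'; published benchmark values require the original database
snapshots and are out of reach by construction.

## Problem sizes and numerical choices

Tests and examples run at deliberately modest sizes (hundreds to 2000
genes, tens to hundreds of features, 25–100 ensemble members) — large
enough for the statistical properties to be stable at the asserted
tolerances, small enough to iterate on. Null calibration uses 20
independent draws and a ±0.05 AUC band. Floating-point conventions:
probabilities of ensembles are plain member means; stratified fold
assignment operates on sorted ids so results depend only on the seed, not
input order; all writers sort identifiers for byte-stable output.

## Known limitations

- Protein-level sequence descriptors are out of scope; the gene-level
  grouped cross-validation they require is implemented and tested.
- The per-pathway aggregation of influence gives one column per pathway;
  pipelines that expand pathways into multiple columns per reference role
  will produce different column counts.
- The exotic centralities follow their standard literature definitions;
  known normalisation variants exist and the chosen conventions are fixed
  in the docstrings rather than configurable.
- CatBoost support is an optional adapter; it raises at construction if the
  library is absent.
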