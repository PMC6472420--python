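# Methods

## The model

`kgrepurpose` treats drug repurposing as binary classification of
drug–disease pairs. Given an undirected view of a heterogeneous
knowledge graph, a pair (d, s) is described by:

* `direct_path` ∈ {0, 1}: whether any triple joins d and s, in either
  direction and under any predicate;
* for each semantic group g, the number of unique intermediate concepts
  of (d, s) whose group is g;
* for each semantic type t, the number of unique intermediate concepts
  annotated with t.

An *intermediate concept* is any vertex adjacent to both d and s, i.e.
the middle of a length-two path. Uniqueness is at the concept level:
a concept reachable through five different predicates still counts once.
Because each concept has exactly one group, the group counts sum to the
number of intermediates; type counts can exceed that sum because
concepts may carry several types. Features are raw frequencies, not
proportions — the counts themselves (how richly a pair is embedded in the
graph, and in which semantic neighbourhoods) are the signal. No
normalization option is built in: the matrix is integer-valued by
contract, and if proportion features are wanted they should be derived
from it explicitly so the transformation's provenance stays in user
code.

The classifier is any of seven registry algorithms; the random forest is
the reference configuration. The prediction score is
100 × P(approved | x), by default the forest's mean of per-tree class
probabilities (a hard-vote fraction is available via
`predict_scores(..., method="vote")`). Classification uses a strict
cutoff: approved iff score > 50.

### Assumptions

* Path existence is direction-insensitive. Stored edges retain their
  direction, provenance and evidence counts, and a `directed=True` graph
  mode exists for sensitivity analysis, but all feature queries default
  to the undirected view.
* Predicates are ignored by features. Unlike metapath approaches, the
  representation uses only the semantic annotation of the intermediate
  concept, not the relation labels along the path.
* Pairs with neither a direct nor an indirect path are not classifiable
  and are excluded by `filter_connected` (counts logged).

## Reference-set cleaning

The pipeline order is: map raw drug identifiers to active-ingredient
concepts → deduplicate on (drug, disease, status) → keep only the
approved and terminated statuses → drop pairs without graph support.
Suspended and withdrawn trials are excluded because they say little
about efficacy: withdrawn trials never enrolled, suspended ones may
resume. The duplicate key deliberately includes status, so a combination
listed as both approved and terminated survives as two instances; the
data do not say which label should win, and the classifier should see
the conflict. Deduplication keeps the first occurrence, so the pipeline
is order-stable and idempotent.

## Cross-validation and metrics

`cross_validate` uses repeated stratified K-fold CV (default 10 × 10).
Stratification is used because the class balance is roughly 3:1 and
small folds could otherwise lose the minority class. Metrics (AUC,
AUPRC, F1, accuracy, Cohen's κ) are computed on each test fold; the
report gives mean and standard deviation over all repeats × folds
fold-level values. Pooling per repeat instead would shrink the sd; the
fold-level choice is the more conservative and is what the report's sd
means. `compare_models` evaluates every spec on identical fold
assignments (the splitter is seeded independently of the model), so
differences between algorithms are paired.

Registry defaults stand in for unstated conventions: random forest with
500 trees, √p features per split, unlimited depth, impurity-based
importances (rescaled so the top feature = 100); single-hidden-layer
perceptron (100 units); RBF-kernel SVM wrapped in probability
calibration; CART as a single unpruned decision tree; k-NN with k = 5;
Gaussian naive Bayes; L2 logistic regression. Scale-sensitive models are
preceded by standardization. All hyperparameters are overridable through
`ModelSpec`.

Kendall's tau-b (tie-corrected) with the asymptotic normal p-value is
used for score–connectivity correlations; with 21 observations and tied
scores an exact permutation p-value is not practical, and the normal
approximation is standard at this n.

## The synthetic generator

`synth.generate` emulates exactly the three statistical properties the
classifier exploits, at the package's standard conditions:

* **Direct-edge rates** 0.50 (approved) vs 0.45 (terminated). This gap
  is deliberately weak: on its own it moves AUC to ≈ 0.52.
* **Intermediate counts** ~ negative binomial with mean 30 and
  dispersion 1.5 for *both* classes. Real per-pair connectivity spans
  orders of magnitude, hence the overdispersed choice; the means are
  equal by default so counts carry no class signal and the semantic
  tilt below is the only strong discriminator. Class-specific means are
  available for confounding studies.
* **Semantic-group profiles**: each intermediate's group is drawn from
  (1 − δ)·background + δ·onehot(signal group), with background uniform
  over the groups that have mapped types and signal groups Physiology
  (approved) / Disorders (terminated). δ (`group_divergence`, default
  0.5) is the single knob that interpolates from exchangeable classes
  (δ = 0) to strongly divergent ones.

By default every pair receives dedicated drug and disease vertices, so
the realized intermediate set equals the planted one and generator
parameters are recoverable exactly; setting `n_drugs`/`n_diseases`
smaller shares vertices across pairs, which creates coincidental
two-edge paths and a messier, more graph-like regime. An optional
`degree_confounder` makes terminated pairs sample intermediates from a
small hub pool, reproducing the negative score–connectivity correlation
phenomenon. Disease classes (cancer/non-cancer) are assigned
independently of the features, so class-balance experiments on synthetic
data test the machinery, not a planted class difference.

What the generator does **not** emulate: real topology (degree
distributions, communities), meaningful predicates, concept-identity
structure across sources, or literature-scale evidence counts. Passing
tests on synthetic data therefore demonstrate that the pipeline recovers
planted feature-level structure and is deterministic — not that the
method's published performance transfers to any particular real graph.

`synth.verify` reloads the generated files through the ordinary loaders
and recomputes per-class direct rates, mean intermediate counts, and
L1 distance of group profiles against the ground-truth record, so file
tampering or loader regressions surface immediately.

## Numerical and design choices

* Percentages in set summaries are rounded to integers; an empty status
  yields an undefined (null) percentage rather than zero.
* Ranking ties are broken alphabetically by drug name for stable output.
* `subsample_to_ratio` downsamples exactly one class, uniformly without
  replacement from a seeded generator; the achieved ratio is within one
  pair of the target and reruns are bit-identical.
* The feature schema defaults to "observed" (features only for
  groups/types that occur among the reference pairs' intermediates);
  "full" mode keeps every vocabulary entry as a possibly all-zero
  column. Observed mode is the default because all-zero columns carry no
  information for tree ensembles and inflate the schema; the schema is
  stored with the model, and candidate featurization at prediction time
  drops novel labels with a warning rather than silently reshaping.
* The bundled vocabulary has the 15 real UMLS semantic-group names and a
  20-type subset; the full 137-type inventory is licensed and must be
  supplied by the user as a `type<TAB>group` table. The type→group map
  is advisory: concepts declare their own single group, since a concept
  with types from several groups cannot satisfy a per-type constraint.
* All stochastic operations take explicit integer seeds and are
  bit-reproducible; file writers use fixed formatting so repeated runs
  are byte-identical.

## Problem sizes

Unit tests run on toy graphs (≤ 100 edges) and synthetic worlds of a few
hundred pairs with reduced forests; the end-to-end recovery checks and
the acceptance script use 2000-pair worlds with the full 10 × 10 CV and
the 500-tree default, which completes in a few minutes on one core.

## Known limitations

* Indirect paths are length two only; longer metapaths and
  predicate-aware features are out of scope.
* No concept normalization across vocabularies: identifiers are opaque
  and must already be reconciled (the active-ingredient map is the only
  identifier translation provided).
* The shipped 21-drug ADPKD table is a fixed artifact for correlation
  and threshold analyses; reproducing its scores requires the original
  proprietary graph.
* Cohen's κ, F1 and accuracy depend on the 50 % cutoff; with
  well-separated classes the forest's calibration, not just its ranking,
  affects those three metrics.
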