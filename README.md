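# kgrepurpose

Drug-repurposing prioritization from the semantic properties of
knowledge-graph paths.

## What it does

A biomedical knowledge graph connects concepts — drugs, diseases, genes,
symptoms, organisms — by subject–predicate–object triples integrated from
many sources. For a drug *d* and a disease *s*, two kinds of paths carry
signal about whether the combination could succeed clinically:

* a **direct path**: any single triple joining *d* and *s*;
* **indirect paths** of length two, through an **intermediate concept**
  *c* adjacent to both *d* and *s*.

Every concept carries one or more UMLS *semantic types* (fine categories
such as "Enzyme" or "Sign or Symptom") and exactly one of 15 *semantic
groups* (coarse categories such as "Chemicals & Drugs"). `kgrepurpose`
represents each drug–disease pair by the feature vector

```
x(d, s) = [ 1{direct path} , n_g(d,s) for each group g , n_t(d,s) for each type t ]
```

where `n_g` counts the unique intermediate concepts whose group is `g`
and `n_t` counts those annotated with type `t` (a multi-typed concept
increments several type features but exactly one group feature, so
Σ_g n_g = |intermediates|). A classifier — random forest by default, six
other algorithms in the registry — is trained on a RepoDB-style reference
set of approved vs. terminated drug–disease combinations, evaluated with
10×10 repeated stratified cross-validation (AUC, AUPRC, F1, accuracy,
Cohen's κ), and then used to rank candidate drugs for a disease by their
*prediction score*, the pseudoprobability (0–100 %) of the approved class.
Supporting analyses cover feature importance, cancer/non-cancer class
balance, leave-one-pair-out retraining, Kendall tau-b correlation between
score and drug connectivity, and explanation subgraphs for individual
pairs.

Because the full commercial knowledge graph is not redistributable, the
package includes a seeded synthetic generator (`kgrepurpose.synth`) that
reproduces the statistical structure the method relies on —
class-dependent direct-edge rates (0.50 / 0.45), overdispersed
intermediate-concept counts, and class-tilted semantic-group profiles —
so the whole pipeline is testable end to end.

## Worked example

```python
from kgrepurpose import (
    SynthConfig, generate, load_graph, load_reference, filter_connected,
    build_schema, featurize_all, ModelSpec, RepurposingClassifier,
)

world = generate(SynthConfig(n_pairs=500, group_divergence=0.5, seed=5), "demo")
g = load_graph(world.concepts_path, world.triples_path)
rs = filter_connected(load_reference(world.reference_path), g)
m = featurize_all(g, rs, build_schema(g, rs))

model = RepurposingClassifier(m, ModelSpec(seed=5))
print(model.cross_validate(repeats=2, folds=5).summary())
```

prints

```
Cross-validation: random_forest
2 repeats x 5 folds (seed 5)
metric        mean %      sd %
auc            100.0       0.0
auprc          100.0       0.0
f1              99.5       0.6
accuracy        99.3       0.9
kappa           98.1       2.6
```

— with half the semantic-profile divergence planted (`group_divergence=0.5`)
the two classes are almost perfectly separable; at `group_divergence=0`
the same pipeline returns an AUC near 50 %, confirming that the direct-path
gap alone carries very limited discriminative value. The same steps are
available from the shell (`kgrepurpose simulate | summarize | featurize |
cv | compare | train | predict | rank | correlate | leaveout | explain`);
each run writes a `manifest.json` with parameters, seed and input
checksums.

The package also ships the 21-drug prioritization table for Autosomal
Dominant Polycystic Kidney Disease (ADPKD):

```python
from kgrepurpose.experiments import load_adpkd_table, correlate_connectivity
corr = correlate_connectivity(load_adpkd_table())
# {'intermediates': (-0.737, 3.2e-06), 'degree': (-0.530, 8.0e-04)}
```

The strong negative tau says the classifier systematically assigns higher
scores to weakly connected drugs in this candidate set.

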