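# cohortssm

Population-aware classification of clinical cohorts with bidirectional,
weight-shared selective state-space scans.

## The problem

Screening classifiers for neurodegenerative disease usually judge each
subject in isolation: encode the scan, threshold the features. Clinicians do
something else — they compare a case against the population of cases they
know, because absolute measurements carry scanner- and cohort-level nuisance
that only *relative* judgment removes. Modeling those inter-subject
dependencies explicitly (population graphs, pairwise attention) costs O(N²)
in cohort size and a hand-designed adjacency.

`cohortssm` implements the implicit alternative: treat a mini-batch of
subjects as an unordered set, serialize it in an arbitrary order, and let a
diagonal selective state-space scan — linear in N — exchange information
along the sequence in both directions with a single shared parameter set θ:

```
h_t = Ā_t h_{t-1} + B̄_t u_t,   y_t = C_t h_t + D u_t        (per channel)
H_fwd = SSM_θ(S),   H_bwd = Flip(SSM_θ(Flip(S)))
Z'    = Norm(Z + Linear(H_fwd + H_bwd))
```

A sequence model is order-sensitive while a cohort is a set, so training
adds a **shuffle-consistency** term: every batch is run twice, in its
arrival order and under a random permutation, and the mean squared
divergence between the aligned predictions (and latent rows) is penalized,

```
L_total = L_CE + λ · L_cons,   λ = 1.0,
```

with cost-sensitive cross-entropy (class weights 1.0 : 4.5) for the
imbalanced screening task. Weight sharing makes sequence *reversal* exactly
equivariant by construction; the regularizer handles all other permutations
empirically. Single subjects are classified by concatenating them with a
frozen support set of 16 training subjects and feeding the enriched
representation to a calibrated, cost-weighted RBF-SVM with a τ = 0.5
threshold.

Because real MRI cohorts are not shippable, the package includes a
first-class synthetic cohort generator whose labels are (tunably) *relative
to acquisition-group context* — the statistical situation the mechanism
exists for — plus closed-form oracles bounding what isolated and
context-aware classifiers can achieve on it, and a toy 3-D volume generator
with a small fixed convolutional encoder for end-to-end smoke tests.

## Worked example

```python
import numpy as np
from cohortssm.synthetic import SyntheticCohortConfig, generate_feature_cohort
from cohortssm.estimators import PopulationSSMClassifier
from cohortssm.diagnostics import stratified_subject_kfold, compute_metrics

# 355 subjects, 64-d features, labels = "top quarter of your own
# acquisition group" (context strength rho = 1): undecidable per subject
cohort = generate_feature_cohort(SyntheticCohortConfig(context_strength=1.0, seed=1))
folds = stratified_subject_kfold(cohort.subject_ids, cohort.labels, k=5, seed=0)
tr = np.flatnonzero(np.isin(cohort.subject_ids, folds.train_ids[0]))
te = np.flatnonzero(np.isin(cohort.subject_ids, folds.test_ids[0]))

clf = PopulationSSMClassifier(random_state=0)          # lambda_cons = 1.0
clf.fit(cohort.features[tr], cohort.labels[tr], groups=cohort.groups[tr])
pred = clf.predict(cohort.features[te], groups=cohort.groups[te])
m = compute_metrics(cohort.labels[te], pred)
print(f"balanced accuracy {m.balanced_accuracy:.3f}  "
      f"recall(abnormal) {m.recall[1]:.2f}")

iso = PopulationSSMClassifier(population="none", norm="identity", random_state=0)
iso.fit(cohort.features[tr], cohort.labels[tr], groups=cohort.groups[tr])
m_iso = compute_metrics(cohort.labels[te], iso.predict(cohort.features[te]))
print(f"isolated baseline  {m_iso.balanced_accuracy:.3f}")
```

```
balanced accuracy 0.878  recall(abnormal) 0.94
isolated baseline  0.504
```

The population-aware model recovers most of what the contextual oracle
(≈ 0.94 balanced accuracy at these conditions) allows, while the isolated
baseline sits near chance — on this cohort the label simply is not a
function of one subject's features. On a ρ = 0 cohort (absolute labels) the
two models agree to within a few points, as they should.

The same pipeline is scriptable:

```bash
cohortssm simulate --n 355 --rho 1.0 --seed 1 --out cohort.tsv
cohortssm crossval --cohort cohort.tsv --k 5 --seed 0 --report cv.json
cohortssm ablate   --cohort cohort.tsv --seed 0 --report ablation.json
cohortssm scaling  --report scaling.json
```

Every report embeds the resolved configuration and seed; identical inputs
give byte-identical reports.

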