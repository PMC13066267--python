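# Methods

## Problem setting

Clinical screening from structural brain MRI is usually framed per subject:
an encoder maps each scan to a feature vector and a classifier thresholds
it. Radiological practice is different — a scan is judged *relative to* a
mental library of previously seen cases, because absolute measurements carry
scanner-, site- and cohort-level nuisance that only comparison can remove.
`cohortssm` implements a population-aware classifier for exactly this
situation: an unordered set of subject feature vectors is processed jointly,
so that each subject's prediction can depend on the rest of the set, with
linear cost in the set size.

The classifier is shaped like any scikit-learn estimator
(`PopulationSSMClassifier.fit/predict/predict_proba`); the pieces it is
assembled from (the scan, the set plumbing, the losses, the diagnostics) are
ordinary module functions underneath.

## Model

### Diagonal selective state-space scan

The interaction mechanism is a discretized linear state-space recurrence per
channel with a diagonal state matrix,

    h_t = Ā_t ⊙ h_{t-1} + B̄_t u_t,      y_t = C_t · h_t + D ⊙ u_t,

with zero-order-hold discretization for the state matrix, `Ā = exp(ΔA)`, and
the simplified Euler rule for the input matrix, `B̄ = ΔB`. Selectivity means
the step size Δ (softplus of a low-rank projection), B and C are functions
of the input at each position. `A = -exp(A_log)` is strictly negative, so
`0 < Ā < 1` whenever Δ > 0 and the recurrence is unconditionally stable; a
10⁴-step input cannot overflow. `A_log` is initialized log-spaced
(`exp(A_log[n, s]) = s + 1`, identical across channel rows), Δ's bias is set
so its softplus lands log-uniformly in `[1e-3, 1e-1]`.

The scan sits inside a gated two-branch block: an input projection doubles
the width (expansion E = 2), the value branch passes through SiLU and the
scan, the gate branch multiplies the scan output through a SiLU gate, and an
output projection returns to the model width. Defaults: state dimension 16,
Δ-projection rank `ceil(inner/16)`. A causal depthwise convolution on the
value branch is available (`conv_width > 0`) but **off by default**: a causal
convolution is not symmetric under sequence reversal and would break the
exact reversal equivariance described next.

Two implementations exist: a plain float64 sequential loop
(`selective_scan_reference`, the oracle) and a vectorized float32 version
with a hand-derived analytic gradient (`selective_scan`), verified against
the oracle (≤1e-5 absolute) and against central finite differences.

### Bidirectional weight-shared set scanning

An unordered subject set is serialized under an arbitrary order, scanned
forward and backward **with the same parameter object**, and folded back
onto the per-subject features:

    H_fwd = SSM_θ(S),  H_bwd = Flip(SSM_θ(Flip(S))),
    Z' = Norm(Z + Linear(H_fwd + H_bwd)),

followed by a per-subject affine head and softmax. `Norm` is per-row layer
normalization with learnable scale and shift (an identity-norm variant is
kept for unit tests and for the isolated baseline, see below). Outputs are
always re-aligned to the input container order.

Weight sharing makes reversal the one permutation under which the
architecture is *exactly* equivariant: reversing the input set reverses the
outputs bit-for-bit. General permutations are not structurally equivariant —
that residual order sensitivity is what the training regularizer targets,
and what the permutation-variance diagnostic quantifies.

### Shuffle-consistency training

Each step draws a mini-batch, concatenates a frozen support set of 16
training subjects, and runs two forward views of the same sequence: the
arrival order (supervised view) and a fresh uniform random permutation. The
objective is

    L_total = L_CE + λ · L_cons,     λ = 1.0,

where `L_CE` is cost-sensitive cross-entropy (class weights 1.0 : 4.5,
minority disease class up-weighted) over the **non-support** positions only,
and `L_cons` is the squared L2 distance per subject between the two aligned
views, averaged over subjects. By default the divergence is measured both on
the probability rows and on the latent rows Z′ (`consistency_space="both"`);
the probability-only and latent-only variants are switchable. Both views
carry gradient. Shuffling permutes the *entire* concatenated sequence, so no
sequence position can become a stable cue for support membership.

Support selection is class-stratified proportional sampling from the
training pool (a class-prototype-nearest strategy is available), frozen for
the whole run, and reused verbatim at inference; a training/test subject
overlap or a support set touching test subjects raises immediately.

Because no automatic-differentiation framework is a dependency, the package
carries a small reverse-mode tape over numpy float32 arrays and a
hand-written AdamW (decoupled weight decay; `A_log`, biases, gains and norm
parameters are exempt from decay, as is usual for state-space models).

### Hybrid decision layer

For single-subject screening decisions, the subject is concatenated with the
frozen support set, the population block is run, and the subject's enriched
row Z′ (taken after the norm) is the "population-aware feature". These
features feed an RBF-kernel SVM with per-class penalty weights 1.0 : 4.5,
hyperparameters (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.1, 1, 10}/D) picked by an
internal stratified 5-fold search on balanced accuracy, and sigmoid (Platt)
calibration fitted on held-in folds. A subject is called positive when the
calibrated probability is ≥ τ = 0.5 (ties positive). The class weighting is
applied both in the network's cross-entropy and in the SVM penalty; each is
switchable independently.

`stability_test` is the one deliberate exception to the frozen-support rule:
it redraws the reference batch (30 trials by default) and reports the mean,
standard deviation and the fraction of trials above τ for one subject — a
direct measure of neighbor dependence.

## Synthetic cohort

Real cohort data is out of scope; the generator reproduces the statistical
shape the method assumes, not images. A cohort has 355 subjects, feature
dimension 64, and a positive fraction of 90/355 ≈ 0.254 (the 53 : 18
per-fold imbalance of the screening task). Each subject carries a latent
atrophy score `a ~ N(0, 1)`; subjects belong to acquisition groups of ~32
sharing an additive nuisance shift `c_g ~ N(0, 5²)` on the observed score
`s = a + c_g`. Labels blend an absolute and a relative rule through the
context strength ρ:

    label = 1  ⇔  (1-ρ)(s - t_global) + ρ(s - q_group) + ε > 0,

where `t_global` and `q_group` are the empirical (1 - positive fraction)
quantiles of `s` over the cohort and within the subject's group, and
`ε ~ N(0, 0.1²)`. At ρ = 0 a single threshold on the observed score decides;
at ρ = 1 the label is "top quarter of *its own group*", which no per-subject
function of the features can recover because the group shift (σ = 5) dwarfs
the within-group spread (σ = 1) — only comparison against group peers
de-confounds it. Features are a random rank-one embedding of `s` plus
isotropic distractor noise (σ = 0.2); the shift lies along the same
direction as the signal, so group identity is not decodable from a single
feature vector. Closed-form oracles on the generative model (best threshold
on `s`; `s` minus the within-group quantile) bound what isolated and
context-aware models can achieve; at the default conditions the contextual
oracle beats the isolated one by ≥ 0.3 balanced accuracy.

The shift magnitude (σ = 5) was chosen as the smallest round value at which
that oracle gap holds; smaller shifts leave too much of the label signal
recoverable from the absolute score.

The toy 3-D volumes (64³ by default) contain a bright "hippocampus"
ellipsoid whose radius shrinks with disease and a dark "ventricle" cavity
that enlarges, on a noisy background, min-max normalized to [0, 1]. They
exist for end-to-end smoke tests of the crop/normalize/encode path; the
bundled encoder (`TinyEncoder`) is a fixed-random strided 3-D convolution
tower behind the same interface a pretrained volumetric backbone would use.

**What the generator does not emulate:** real morphological covariance,
scanner texture, age/sex confounds, registration error, or any spatial
structure beyond the two ellipsoids. Passing tests show the *mechanism*
works where relative-to-cohort signal exists; they say nothing about MRI
image quality or encoder transferability.

## Training protocol and problem sizes

`LossConfig` keeps the reference protocol constants (60 epochs, constant
learning rate 4e-5, effective batch 32, support 16, λ = 1.0, weights
1.0 : 4.5) — appropriate for fine-tuning a large pretrained backbone. The
estimator's desk-scale defaults train the small randomly initialized model
this package ships: constant learning rate 1e-3, 500 epochs, batch 16 drawn
within acquisition groups (two random subsets per group per epoch), weight
decay 0.02, and train-time input jitter σ = 0.5. The jitter is load-bearing:
without it the per-position paths memorize individual noise fingerprints
instead of learning the relative rule (train balanced accuracy 1.0, test at
chance). Mini-batches never mix acquisition groups, since labels at ρ > 0
are only consistent with same-group statistics.

Prediction mirrors training composition: each subject is scored inside a
sequence of the frozen support set plus `batch_size - 1` same-group training
references plus the subject — one forward pass per subject. Evaluating test
subjects inside differently-sized sets measurably degrades accuracy (the
learned aggregation is calibrated to its operating length).

The permutation-variance diagnostic runs the model under K random
serializations (orders are drawn over the identity-sorted subject list, so
the result cannot depend on the container order), inverse-aligns the latent
rows, and reports the mean (and max) per-subject per-dimension variance.
Variant comparisons evaluate it at the operating set size (32 subjects) for
the same reason the prediction protocol matches the training composition.

## Numerical choices

- All model arithmetic is float32; the reference scan and all probability
  containers are float64. Equality tolerances in tests follow: 1e-5 for
  scan-vs-oracle and equivariance, 1e-6 for simplex checks.
- Cross-entropy clamps log-probabilities at log(1e-12) with a logged
  warning; gradients pass only through unclamped entries.
- Ties at the decision threshold are called positive (≥ τ).
- Degenerate inputs fail loudly: empty sets, duplicate subject ids,
  non-permutation orders, non-positive Δ, single-class pools.

## Known limitations

- The per-subject inference path contextualizes against the global support
  set only; when the discriminative signal is purely group-relative (ρ = 1)
  and the subject's group is unknown, its features carry little usable
  signal — the estimator's group-aware prediction path exists for exactly
  that case.
- Exact equivariance holds only for reversal; everything else is empirical
  and depends on the consistency regularizer having converged.
- The analytic activation counts substitute for hardware memory
  measurements; they support the asymptotic claim (linear vs quadratic), not
  absolute VRAM numbers.
- Training is single-threaded numpy; wall-clock scales roughly linearly in
  epochs × groups × batch size. The shipped sizes keep a full variant
  comparison within a few minutes on one CPU core.
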