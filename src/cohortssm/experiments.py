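"""Headline experiments: the measurements the package stands behind.

Each function recomputes one quantity from scratch — generating its own
inputs, training what needs training — and returns plain numbers.  They are
shared by the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import (activation_scaling, compute_metrics,
                          fit_isolated_baseline, permutation_variance,
                          stratified_subject_kfold)
from .estimators import PopulationSSMClassifier
from .inference import fit_decision_layer, predict_subject, stability_test
from .population import PopulationModel, SubjectFeatureSet, population_forward
from .ssm import SSMConfig, selective_scan, selective_scan_reference
from .synthetic import SyntheticCohortConfig, generate_feature_cohort
from .training import (PermutationOp, ShuffledViewPair, consistency_loss,
                       sample_permutation)

__all__ = [
    "scan_oracle_deviation",
    "lti_convolution_deviation",
    "reversal_equivariance_deviation",
    "consistency_law_values",
    "population_context_experiment",
    "protocol_arithmetic",
    "scaling_summary",
    "stability_experiment",
    "screening_metrics_example",
]


def scan_oracle_deviation(seed: int, n_instances: int = 100) -> float:
    """Worst absolute deviation between the vectorized scan and the
    sequential reference over random instances (N<=64, channels<=64)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(1, 65))
        ch = int(rng.integers(1, 65))
        st = 16
        u = rng.standard_normal((n, ch)).astype(np.float32)
        delta = rng.uniform(1e-3, 0.5, (n, ch)).astype(np.float32)
        B = rng.standard_normal((n, st)).astype(np.float32)
        C = rng.standard_normal((n, st)).astype(np.float32)
        A = -rng.uniform(0.05, 3.0, (ch, st)).astype(np.float32)
        skip = rng.standard_normal(ch).astype(np.float32)
        dev = np.abs(selective_scan(u, delta, B, C, A, skip)
                     - selective_scan_reference(u, delta, B, C, A, skip)).max()
        worst = max(worst, float(dev))
    return worst


def lti_convolution_deviation(seed: int, n_instances: int = 20) -> float:
    """With position-constant Delta/B/C the scan must equal the explicit
    convolution with kernel k_t = C . (A_bar^(t-1) B_bar)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n, ch, st = int(rng.integers(2, 33)), int(rng.integers(1, 9)), 8
        delta = np.tile(rng.uniform(0.05, 0.3, (1, ch)), (n, 1)).astype(np.float32)
        B = np.tile(rng.standard_normal((1, st)), (n, 1)).astype(np.float32)
        C = np.tile(rng.standard_normal((1, st)), (n, 1)).astype(np.float32)
        A = -rng.uniform(0.1, 2.0, (ch, st)).astype(np.float32)
        skip = rng.standard_normal(ch).astype(np.float32)
        u = rng.standard_normal((n, ch)).astype(np.float32)
        y = selective_scan(u, delta, B, C, A, skip)

        A_bar = np.exp(delta[0][:, None].astype(np.float64) * A)
        B_bar = delta[0][:, None].astype(np.float64) * B[0][None, :]
        kernel = np.stack([(A_bar ** k * B_bar) @ C[0] for k in range(n)])
        expected = np.stack([
            sum(kernel[k] * u[t - k] for k in range(t + 1)) + skip * u[t]
            for t in range(n)])
        worst = max(worst, float(np.abs(y - expected).max()))
    return worst


def reversal_equivariance_deviation(seed: int, n_models: int = 5) -> float:
    """Forward pass on the reversed set vs reversed forward pass, untrained
    random models; a structural property of the weight-shared design."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for m in range(n_models):
        model = PopulationModel.init(SSMConfig(model_dim=16), seed=seed + m)
        fset = SubjectFeatureSet(
            rng.standard_normal((12, 16)).astype(np.float32), np.arange(12))
        P = population_forward(fset, model)
        P_rev = population_forward(fset.reversed(), model)
        worst = max(worst, float(
            np.abs(P.probabilities[::-1] - P_rev.probabilities).max()))
    return worst


def consistency_law_values(seed: int) -> dict:
    """The three consistency-loss laws: identity permutation, the printed
    two-subject example, and a context-free model under a random shuffle."""
    from .population import PredictionSet

    def pred(probs):
        probs = np.asarray(probs, dtype=np.float64)
        return PredictionSet(probs, np.log(probs + 1e-300))

    identity = PermutationOp(np.arange(2), np.arange(2))
    P = pred([[0.6, 0.4], [0.2, 0.8]])
    identity_loss = consistency_loss(ShuffledViewPair(P, P, identity))

    P1 = pred([[1.0, 0.0], [0.0, 1.0]])
    P2 = pred([[1.0, 0.0], [1.0, 0.0]])
    hand_loss = consistency_loss(ShuffledViewPair(P1, P2, identity))

    rng = np.random.default_rng(seed)
    model = PopulationModel.init(SSMConfig(model_dim=8), seed=seed, mode="none")
    fset = SubjectFeatureSet(rng.standard_normal((10, 8)).astype(np.float32),
                             np.arange(10))
    perm = sample_permutation(10, rng)
    Pa = population_forward(fset, model)
    Pb = population_forward(fset, model, order=perm.forward)
    ident10 = PermutationOp(np.arange(10), np.arange(10))
    context_free_loss = consistency_loss(ShuffledViewPair(Pa, Pb, ident10))
    return {"identity": identity_loss, "hand_example": hand_loss,
            "context_free": context_free_loss}


def _fold_split(cohort: SubjectFeatureSet, seed: int, fold: int = 0):
    folds = stratified_subject_kfold(cohort.subject_ids, cohort.labels,
                                     k=5, seed=seed)
    tr = np.flatnonzero(np.isin(cohort.subject_ids, folds.train_ids[fold]))
    te = np.flatnonzero(np.isin(cohort.subject_ids, folds.test_ids[fold]))
    return tr, te


def _fit_variant(cohort, tr, seed, **overrides):
    clf = PopulationSSMClassifier(random_state=seed, **overrides)
    clf.fit(cohort.features[tr], cohort.labels[tr], groups=cohort.groups[tr])
    return clf


def _bacc(cohort, clf, te):
    pred = clf.predict(cohort.features[te], groups=cohort.groups[te])
    return compute_metrics(cohort.labels[te], pred).balanced_accuracy


def population_context_experiment(seed: int, variance_K: int = 20,
                                  variance_set_size: int = 32) -> dict:
    """The central desk-scale experiment.

    On a fully context-dependent cohort (rho = 1): train the full model
    (lambda = 1), the identical model with lambda = 0, and the isolated
    per-subject baseline; measure held-out balanced accuracy and the latent
    permutation variance of both trained scan models at the operating set
    size.  On an absolute-label cohort (rho = 0): full model vs isolated
    baseline.  Returns the numbers plus the trained rho=1 full model for
    reuse by the stability experiment.
    """
    out = {}
    cohort = generate_feature_cohort(
        SyntheticCohortConfig(context_strength=1.0, seed=seed))
    tr, te = _fold_split(cohort, seed)
    full = _fit_variant(cohort, tr, seed)
    lam0 = _fit_variant(cohort, tr, seed, lambda_cons=0.0)
    iso = fit_isolated_baseline(cohort.features[tr], cohort.labels[tr], seed=seed)

    out["bacc_full_rho1"] = _bacc(cohort, full, te)
    out["bacc_lambda0_rho1"] = _bacc(cohort, lam0, te)
    out["bacc_isolated_rho1"] = compute_metrics(
        cohort.labels[te], iso.predict(cohort.features[te])).balanced_accuracy

    pick = np.random.default_rng(seed + 2).choice(
        len(cohort), size=variance_set_size, replace=False)
    var_set = cohort.subset(pick)
    v1 = permutation_variance(full.model_, var_set, K=variance_K,
                              rng=np.random.default_rng(seed + 7))
    v0 = permutation_variance(lam0.model_, var_set, K=variance_K,
                              rng=np.random.default_rng(seed + 7))
    out["variance_lambda1"] = v1.mean_variance
    out["variance_lambda0"] = v0.mean_variance
    out["variance_ratio"] = v0.mean_variance / max(v1.mean_variance, 1e-300)

    cohort0 = generate_feature_cohort(
        SyntheticCohortConfig(context_strength=0.0, seed=seed))
    tr0, te0 = _fold_split(cohort0, seed)
    full0 = _fit_variant(cohort0, tr0, seed)
    iso0 = fit_isolated_baseline(cohort0.features[tr0], cohort0.labels[tr0],
                                 seed=seed)
    out["bacc_full_rho0"] = _bacc(cohort0, full0, te0)
    out["bacc_isolated_rho0"] = compute_metrics(
        cohort0.labels[te0], iso0.predict(cohort0.features[te0])).balanced_accuracy

    out["_reuse"] = {"cohort": cohort, "train_idx": tr, "test_idx": te,
                     "full": full}
    return out


def protocol_arithmetic(seed: int) -> dict:
    """Fold sizes of subject-level stratified 5-fold on 355 subjects."""
    cohort = generate_feature_cohort(SyntheticCohortConfig(seed=seed))
    folds = stratified_subject_kfold(cohort.subject_ids, cohort.labels,
                                     k=5, seed=seed)
    sizes = folds.test_fold_sizes
    return {"mean_test_fold_size": float(sizes.mean()),
            "fold_sizes": sizes.tolist()}


def scaling_summary() -> dict:
    """Linear fit quality for the scan model; score-term growth for the
    pairwise-attention baseline."""
    sizes = [4, 8, 16, 32, 64]
    ssm = activation_scaling("population_ssm", sizes)
    att = activation_scaling("pairwise_attention_baseline", sizes)
    D = 64
    scores = {n: c - (3 * n * D + n * D + n * 2)
              for n, c in zip(att["sizes"], att["counts"])}
    growth = [scores[2 * n] / scores[n] for n in (4, 8, 16, 32)]
    return {"linear_r2": ssm["linear_fit"]["r2"],
            "ssm_count_ratio_per_doubling":
                ssm["counts"][3] / ssm["counts"][2],
            "attention_score_growth_per_doubling": float(np.mean(growth))}


def stability_experiment(context: dict, seed: int, trials: int = 30) -> dict:
    """Support-set stability of the highest-margin positive test subject.

    Fits the hybrid decision layer on population-aware features of the
    training subjects (frozen support + same-group references, the package's
    standard inference composition), scores the test fold, picks the
    positive subject with the highest calibrated probability, and redraws
    the 16-subject support ``trials`` times while keeping the subject's
    group references fixed.
    """
    cohort = context["cohort"]
    tr, te = context["train_idx"], context["test_idx"]
    clf = context["full"]
    model, support = clf.model_, clf.support_set_

    support_rows = set(tr[support.subject_ids.astype(int)])
    tr_keep = np.array([i for i in tr if i not in support_rows])
    feats = clf.population_features(cohort.features[tr_keep],
                                    groups=cohort.groups[tr_keep])
    layer = fit_decision_layer(feats, cohort.labels[tr_keep], seed=seed)

    def group_context(i, rng):
        members = tr_keep[cohort.groups[tr_keep] == cohort.groups[i]]
        k = min(clf.batch_size - 1, len(members))
        return cohort.features[rng.choice(members, size=k, replace=False)]

    ctx_rng = np.random.default_rng(seed + 5)
    probs = np.array([
        predict_subject(cohort.features[i], support, model, layer,
                        context=group_context(i, ctx_rng))[1]
        for i in te])
    pos = te[cohort.labels[te] == 1]
    pos_probs = probs[cohort.labels[te] == 1]
    subject = pos[np.argmax(pos_probs)]
    fixed_context = group_context(subject, np.random.default_rng(seed + 6))
    report = stability_test(cohort.features[subject], cohort.subset(tr_keep),
                            model, layer, trials=trials,
                            rng=np.random.default_rng(seed + 13),
                            support_size=len(support), context=fixed_context)
    return {"mu": report.mu, "sigma": report.sigma,
            "fraction_above_tau": report.fraction_above_tau,
            "all_one_side": float(report.fraction_above_tau in (0.0, 1.0)),
            "selected_probability": float(pos_probs.max())}


def screening_metrics_example() -> dict:
    """Class-wise metrics from the screening confusion counts
    TN=46, FP=7, FN=2, TP=16 on a 53:18 test fold."""
    y_true = np.array([0] * 53 + [1] * 18)
    y_pred = np.array([0] * 46 + [1] * 7 + [0] * 2 + [1] * 16)
    m = compute_metrics(y_true, y_pred)
    return {"recall_abnormal": float(m.recall[1]),
            "precision_abnormal": float(m.precision[1]),
            "accuracy": float(m.accuracy),
            "balanced_accuracy": float(m.balanced_accuracy)}
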