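"""Evaluation protocol, imbalance-aware metrics, and the two architecture
diagnostics: permutation variance of the latent population representations
and analytic activation-count scaling.

The cross-validation protocol is subject-level and stratified: every subject
appears in exactly one test fold, and per-fold class ratios stay within one
subject of the global ratio.  ``run_ablations`` trains matched model
variants (isolated / unidirectional / bidirectional without consistency /
full) under identical seeds and folds to isolate the contribution of each
design choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (balanced_accuracy_score, confusion_matrix,
                             precision_recall_fscore_support)
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor
from .population import PopulationModel, SubjectFeatureSet
from .ssm import SSMConfig

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "VarianceReport",
    "stratified_subject_kfold",
    "compute_metrics",
    "permutation_variance",
    "activation_scaling",
    "run_ablations",
]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    k: int
    subject_ids: np.ndarray
    fold_index: np.ndarray                   # per-subject test-fold index
    train_ids: list = field(default_factory=list)   # per-fold id arrays
    test_ids: list = field(default_factory=list)

    def __post_init__(self):
        counts = np.bincount(self.fold_index, minlength=self.k)
        if counts.sum() != len(self.subject_ids) or np.any(self.fold_index < 0):
            raise ValueError("every subject must sit in exactly one test fold")
        for tr, te in zip(self.train_ids, self.test_ids):
            if np.intersect1d(tr, te).size:
                raise ValueError("leakage: train/test overlap within a fold")

    @property
    def test_fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_index, minlength=self.k)


def stratified_subject_kfold(subject_ids, labels, k: int = 5,
                             seed: int = 0) -> FoldAssignment:
    """Stratified K-fold over unique subjects; deterministic under seed."""
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.bincount(labels, minlength=2).min() < k:
        raise ValueError("each class needs at least k members")
    if len(np.unique(subject_ids)) != len(subject_ids):
        raise ValueError("subject_ids must be unique")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.full(len(subject_ids), -1, dtype=int)
    train_ids, test_ids = [], []
    for f, (tr, te) in enumerate(splitter.split(subject_ids, labels)):
        fold_index[te] = f
        train_ids.append(subject_ids[tr])
        test_ids.append(subject_ids[te])
    return FoldAssignment(k=k, subject_ids=subject_ids, fold_index=fold_index,
                          train_ids=train_ids, test_ids=test_ids)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    confusion: np.ndarray            # rows true, cols predicted
    accuracy: float
    balanced_accuracy: float
    precision: np.ndarray            # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]

    def __post_init__(self):
        if int(self.confusion.sum()) != int(self.support.sum()):
            raise ValueError("confusion counts must sum to the test size")

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "per_class": {
                str(c): {"precision": float(self.precision[c]),
                         "recall": float(self.recall[c]),
                         "f1": float(self.f1[c]),
                         "support": int(self.support[c])}
                for c in (0, 1)},
            "macro_avg": list(self.macro_avg),
            "weighted_avg": list(self.weighted_avg),
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Confusion matrix and the standard imbalance-aware summary metrics."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and matched")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    prec, rec, f1, sup = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    macro = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="macro", zero_division=0)[:3]
    weighted = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], average="weighted", zero_division=0)[:3]
    return MetricsReport(
        confusion=cm,
        accuracy=float((y_true == y_pred).mean()),
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        precision=prec, recall=rec, f1=f1, support=sup,
        macro_avg=tuple(float(x) for x in macro),
        weighted_avg=tuple(float(x) for x in weighted))


# ---------------------------------------------------------------------------
# permutation variance
# ---------------------------------------------------------------------------

@dataclass
class VarianceReport:
    """Variance of identity-aligned latent rows across K random orderings."""

    n_permutations: int
    per_element_variance: np.ndarray      # (N, D)
    mean_variance: float
    max_variance: float

    def __post_init__(self):
        if np.any(self.per_element_variance < 0):
            raise ValueError("variance must be non-negative")


def permutation_variance(model: PopulationModel, fset: SubjectFeatureSet,
                         K: int, rng: np.random.Generator,
                         space: str = "latent") -> VarianceReport:
    """Run the model under K random serializations and measure how much each
    subject's aligned representation moves.

    Outputs are inverse-aligned to subject identity before the variance is
    taken, so the result is invariant to the order of the input container.
    ``space`` selects latent rows Z' (default, the architecture diagnostic)
    or probability rows.
    """
    if K < 2:
        raise ValueError("need K >= 2 permutations")
    if space not in ("latent", "probs"):
        raise ValueError("space must be 'latent' or 'probs'")
    # serialization orders are drawn over the identity-sorted subject list,
    # so the realized subject sequences (and hence the result) do not depend
    # on the order of the input container
    canon = np.argsort(fset.subject_ids, kind="stable")
    views = []
    X = Tensor(fset.features)
    for _ in range(K):
        order = canon[rng.permutation(len(fset))]
        latent, logits = model.forward_tensor(X, order=order)
        if space == "latent":
            rows = latent.data
        else:
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            rows = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        views.append(rows[canon].astype(np.float64))
    stack = np.stack(views)                     # (K, N, D)
    var = stack.var(axis=0)
    return VarianceReport(n_permutations=K, per_element_variance=var,
                          mean_variance=float(var.mean()),
                          max_variance=float(var.max()))


# ---------------------------------------------------------------------------
# activation scaling
# ---------------------------------------------------------------------------

def _population_ssm_activation_count(n: int, config: SSMConfig) -> int:
    """Stored activation elements of one bidirectional forward pass."""
    inner, state, rank, D = (config.inner_dim, config.state_dim,
                             config.dt_rank, config.model_dim)
    per_dir = n * (inner          # value branch after SiLU
                   + rank + inner  # low-rank Delta
                   + 2 * state     # B_t, C_t
                   + inner * state  # scan states
                   + inner          # scan output
                   + inner          # gated output
                   + D)             # output projection
    shared = n * (2 * inner        # input projection (both branches)
                  + D              # residual mix
                  + D              # layer norm
                  + 2)             # head logits
    return 2 * per_dir + shared


def _attention_activation_count(n: int, config: SSMConfig) -> int:
    """Pairwise-attention population baseline: the N x N score matrix."""
    D = config.model_dim
    return n * 3 * D + 2 * n * n + n * D + n * 2


def activation_scaling(model_kind: str, sizes, config: SSMConfig | None = None) -> dict:
    """Analytic, hardware-independent activation counts versus set size.

    Fits both a linear and a quadratic model to the counts and reports which
    dominates, with the linear fit's R^2.
    """
    if config is None:
        config = SSMConfig(model_dim=64)
    counters = {"population_ssm": _population_ssm_activation_count,
                "pairwise_attention_baseline": _attention_activation_count}
    if model_kind not in counters:
        raise ValueError(f"unknown model kind {model_kind!r}")
    sizes = np.asarray(list(sizes), dtype=float)
    counts = np.array([counters[model_kind](int(n), config) for n in sizes], dtype=float)

    import warnings
    with warnings.catch_warnings():
        # exactly-linear counts make the quadratic fit rank-deficient
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        lin = np.polyfit(sizes, counts, 1)
        quad = np.polyfit(sizes, counts, 2)
    lin_pred = np.polyval(lin, sizes)
    ss_res = ((counts - lin_pred) ** 2).sum()
    ss_tot = ((counts - counts.mean()) ** 2).sum()
    r2_linear = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    quad_share = abs(quad[0]) * sizes.max() ** 2 / max(counts.max(), 1.0)
    return {
        "model_kind": model_kind,
        "sizes": sizes.astype(int).tolist(),
        "counts": counts.astype(int).tolist(),
        "linear_fit": {"slope": float(lin[0]), "intercept": float(lin[1]),
                       "r2": float(r2_linear)},
        "quadratic_coefficient": float(quad[0]),
        "dominant": "quadratic" if quad_share > 0.1 else "linear",
    }


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = {
    # the isolated baseline is the strongest per-subject learner on the raw
    # encoder features: a class-weighted logistic regression (a weaker,
    # handicapped baseline would overstate the population-context benefit)
    "isolated": None,
    "unidirectional": dict(population="forward", lambda_cons=1.0),
    "bidirectional_no_cons": dict(population="bidirectional", lambda_cons=0.0),
    "full": dict(population="bidirectional", lambda_cons=1.0),
}


def fit_isolated_baseline(features, labels, class_weights=(1.0, 4.5), seed=0):
    """Per-subject reference classifier (no population interaction)."""
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(
        class_weight={0: class_weights[0], 1: class_weights[1]},
        max_iter=2000, random_state=seed).fit(features, labels)


def run_ablations(cohort: SubjectFeatureSet, seed: int = 0, k: int = 5,
                  folds_to_run: int = 1, variance_K: int = 20,
                  variance_set_size: int = 32, **fit_params) -> dict:
    """Train and evaluate the four matched variants under identical folds.

    Returns ``{variant: {"metrics": MetricsReport, "variance": VarianceReport,
    "balanced_accuracy": float}}``.  ``fit_params`` are forwarded to every
    :class:`PopulationSSMClassifier` (e.g. epochs, learning_rate).  The
    permutation-variance diagnostic is evaluated on a seeded random subset of
    ``variance_set_size`` subjects — the model's operating set size (a
    training step processes support + batch, 32 positions by default).
    """
    from .estimators import PopulationSSMClassifier

    if cohort.labels is None:
        raise ValueError("ablations need a labeled cohort")
    folds = stratified_subject_kfold(cohort.subject_ids, cohort.labels, k=k, seed=seed)
    results = {}
    pick = np.random.default_rng(seed + 2).choice(
        len(cohort), size=min(variance_set_size, len(cohort)), replace=False)
    var_set = cohort.subset(pick)
    for name, overrides in ABLATION_VARIANTS.items():
        y_true_all, y_pred_all = [], []
        last_clf = None
        for f in range(min(folds_to_run, k)):
            tr = np.flatnonzero(np.isin(cohort.subject_ids, folds.train_ids[f]))
            te = np.flatnonzero(np.isin(cohort.subject_ids, folds.test_ids[f]))
            if overrides is None:
                clf = fit_isolated_baseline(cohort.features[tr], cohort.labels[tr],
                                            seed=seed)
                pred = clf.predict(cohort.features[te])
            else:
                clf = PopulationSSMClassifier(random_state=seed, **overrides,
                                              **fit_params)
                clf.fit(cohort.features[tr], cohort.labels[tr],
                        groups=None if cohort.groups is None else cohort.groups[tr])
                pred = clf.predict(
                    cohort.features[te],
                    groups=None if cohort.groups is None else cohort.groups[te])
            y_true_all.append(cohort.labels[te])
            y_pred_all.append(pred)
            last_clf = clf
        metrics = compute_metrics(np.concatenate(y_true_all), np.concatenate(y_pred_all))
        var_rng = np.random.default_rng(seed + 1)
        if overrides is None:
            # a per-subject classifier carries no order dependence at all
            variance = VarianceReport(
                n_permutations=variance_K,
                per_element_variance=np.zeros((len(var_set), cohort.n_features)),
                mean_variance=0.0, max_variance=0.0)
        else:
            variance = permutation_variance(last_clf.model_, var_set,
                                            K=variance_K, rng=var_rng)
        results[name] = {"metrics": metrics, "variance": variance,
                         "balanced_accuracy": metrics.balanced_accuracy}
    return results
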