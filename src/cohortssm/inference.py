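"""Support-set inference and the hybrid RBF-SVM decision layer.

A single test subject carries no population context of its own, so it is
concatenated with the frozen support set selected during training (the same
object, never redrawn) and run through the population block; the subject's
enriched row is its population-aware feature vector.  Those features feed a
cost-weighted RBF support-vector classifier whose hyperparameters are chosen
by an internal stratified 5-fold search and whose scores are turned into
probabilities by sigmoid (Platt) calibration.  ``stability_test`` is the one
place where the support set is deliberately redrawn, to measure how much a
prediction depends on the composition of the reference batch.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .autodiff import Tensor
from .population import PopulationModel, SubjectFeatureSet

__all__ = [
    "DecisionLayer",
    "StabilityReport",
    "extract_population_feature",
    "fit_decision_layer",
    "predict_subject",
    "stability_test",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class DecisionLayer:
    """Calibrated RBF-SVM decision layer with threshold tau.

    ``estimator`` emits calibrated probabilities; a subject is called
    positive when its positive-class probability is >= tau (ties positive).
    """

    estimator: object
    best_params: dict
    cv_balanced_accuracy: float
    class_weights: tuple[float, float] = (1.0, 4.5)
    tau: float = 0.5

    def __post_init__(self):
        if not (0 < self.tau < 1):
            raise ValueError("tau must lie in (0, 1)")

    def positive_probability(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        proba = self.estimator.predict_proba(features)
        return proba[:, list(self.estimator.classes_).index(1)]

    def decide(self, features: np.ndarray):
        p = self.positive_probability(features)
        return (p >= self.tau).astype(int), p


@dataclass
class StabilityReport:
    """Per-trial probabilities of one subject under redrawn reference batches."""

    probabilities: np.ndarray
    tau: float

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 1 or len(self.probabilities) < 1:
            raise ValueError("need at least one trial")

    @property
    def mu(self) -> float:
        return float(self.probabilities.mean())

    @property
    def sigma(self) -> float:
        return float(self.probabilities.std())

    @property
    def fraction_above_tau(self) -> float:
        return float((self.probabilities >= self.tau).mean())

    def to_json(self) -> str:
        return json.dumps({
            "trials": len(self.probabilities),
            "probabilities": self.probabilities.tolist(),
            "mu": self.mu, "sigma": self.sigma, "tau": self.tau,
            "fraction_above_tau": self.fraction_above_tau}, indent=2)


# ---------------------------------------------------------------------------
# population-aware features for a single subject
# ---------------------------------------------------------------------------

def extract_population_feature(subject_features: np.ndarray,
                               support: SubjectFeatureSet,
                               model: PopulationModel,
                               subject_id=None,
                               context: np.ndarray | None = None) -> np.ndarray:
    """Enriched feature row of one subject placed after the support set.

    The subject must not already be a member of the support set (checked by
    id when given, and by exact feature-row identity always).  ``context``
    optionally inserts additional reference rows (e.g. same-acquisition-group
    training subjects) between the support set and the subject.
    """
    subject_features = np.asarray(subject_features, dtype=np.float32).reshape(-1)
    if subject_features.shape[0] != support.n_features:
        raise ValueError("subject feature dimension does not match support")
    if subject_id is not None and subject_id in support.subject_ids:
        raise ValueError(f"subject {subject_id!r} duplicated in support set")
    if np.any(np.all(support.features == subject_features, axis=1)):
        raise ValueError("subject feature row duplicated in support set")
    rows = [support.features]
    if context is not None:
        rows.append(np.asarray(context, dtype=np.float32))
    rows.append(subject_features[None, :])
    latent, _ = model.forward_tensor(Tensor(np.concatenate(rows)))
    return latent.data[-1].copy()


def extract_population_features(features: np.ndarray, support: SubjectFeatureSet,
                                model: PopulationModel) -> np.ndarray:
    """Vector-per-subject convenience loop over :func:`extract_population_feature`."""
    return np.stack([extract_population_feature(f, support, model)
                     for f in np.atleast_2d(features)])


# ---------------------------------------------------------------------------
# decision layer
# ---------------------------------------------------------------------------

def fit_decision_layer(features: np.ndarray, labels, seed: int = 0,
                       class_weights: tuple[float, float] = (1.0, 4.5),
                       tau: float = 0.5) -> DecisionLayer:
    """Grid-searched, cost-weighted, sigmoid-calibrated RBF-SVM.

    Penalty C in {0.1, 1, 10, 100} and kernel width gamma in
    {0.1, 1, 10}/D are searched by stratified 5-fold balanced accuracy;
    probability calibration is fitted on held-in folds.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    D = features.shape[1]
    n_splits = int(min(5, counts.min()))
    if n_splits < 2:
        raise ValueError("need at least two members per class")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    weight_map = {0: class_weights[0], 1: class_weights[1]}
    grid = GridSearchCV(
        SVC(kernel="rbf", class_weight=weight_map),
        param_grid={"C": [0.1, 1.0, 10.0, 100.0],
                    "gamma": [0.1 / D, 1.0 / D, 10.0 / D]},
        scoring="balanced_accuracy", cv=cv, n_jobs=1)
    grid.fit(features, labels)
    calibrated = CalibratedClassifierCV(
        SVC(kernel="rbf", class_weight=weight_map, **grid.best_params_),
        method="sigmoid", cv=cv)
    calibrated.fit(features, labels)
    return DecisionLayer(estimator=calibrated, best_params=dict(grid.best_params_),
                         cv_balanced_accuracy=float(grid.best_score_),
                         class_weights=class_weights, tau=tau)


def predict_subject(subject_features: np.ndarray, support: SubjectFeatureSet,
                    model: PopulationModel, layer: DecisionLayer,
                    subject_id=None,
                    context: np.ndarray | None = None) -> tuple[int, float]:
    """Contextual prediction for one subject with the frozen support set."""
    if not isinstance(layer, DecisionLayer):
        raise ValueError("layer must be a fitted DecisionLayer")
    feat = extract_population_feature(subject_features, support, model,
                                      subject_id, context=context)
    label, prob = layer.decide(feat[None, :])
    return int(label[0]), float(prob[0])


def stability_test(subject_features: np.ndarray, reference_pool: SubjectFeatureSet,
                   model: PopulationModel, layer: DecisionLayer,
                   trials: int = 30, rng: np.random.Generator | None = None,
                   support_size: int = 16,
                   context: np.ndarray | None = None) -> StabilityReport:
    """Redraw the reference batch ``trials`` times and track the probability.

    Each trial draws a fresh class-stratified support set of ``support_size``
    subjects from ``reference_pool`` (excluding any row equal to the subject)
    and recomputes the calibrated probability.  Fixed ``context`` rows (the
    subject's group references, when the protocol uses them) are kept
    identical across trials: the test isolates sensitivity to the support.
    """
    from .training import build_support_set

    if rng is None:
        rng = np.random.default_rng(0)
    subject_features = np.asarray(subject_features, dtype=np.float32).reshape(-1)
    keep = ~np.all(reference_pool.features == subject_features, axis=1)
    pool = reference_pool.subset(np.flatnonzero(keep))
    if len(pool) < support_size:
        raise ValueError("reference pool too small for the requested support size")
    probs = np.empty(trials)
    for t in range(trials):
        seed = int(rng.integers(0, 2**31 - 1))
        support = build_support_set(pool, support_size, strategy="stratified", seed=seed)
        _, probs[t] = predict_subject(subject_features, support, model, layer,
                                      context=context)
    return StabilityReport(probabilities=probs, tau=layer.tau)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: PopulationModel, support: SubjectFeatureSet,
                    layer: DecisionLayer | None = None) -> None:
    """Single self-describing archive: model + frozen support + decision layer."""
    payload = {
        "schema_version": CHECKPOINT_SCHEMA,
        "model": model.state_dict(),
        "support": {
            "features": support.features,
            "subject_ids": support.subject_ids,
            "labels": support.labels,
            "groups": support.groups,
        },
        "decision_layer": layer,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("schema_version") != CHECKPOINT_SCHEMA:
        raise ValueError("unsupported checkpoint schema")
    model = PopulationModel.from_state_dict(payload["model"])
    s = payload["support"]
    support = SubjectFeatureSet(s["features"], s["subject_ids"], s["labels"], s["groups"])
    return model, support, payload["decision_layer"]
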