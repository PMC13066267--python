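"""Scikit-learn style estimators over the population model.

``PopulationSSMClassifier`` is the primary user surface: a binary classifier
whose decision for each subject depends on the whole processed set (the
subject's batch peers plus a frozen support set of training subjects).
Setting ``population="none"`` yields the isolated per-subject baseline with
the identical head and training loop, which is the controlled comparison for
measuring the value of population context.

The desk-scale training defaults (constant learning rate 2e-3, 40 epochs)
are tuned for the small randomly initialized models this package trains from
scratch; :class:`~cohortssm.training.LossConfig` retains the published
protocol constants for reference.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .population import PopulationModel, SubjectFeatureSet, prediction_set_from_logits
from .ssm import SSMConfig
from .training import LossConfig, train

__all__ = ["PopulationSSMClassifier"]


class PopulationSSMClassifier(BaseEstimator, ClassifierMixin):
    """Population-aware binary classifier built on a bidirectional shared
    selective state-space scan with shuffle-consistency training.

    Parameters
    ----------
    population : "bidirectional" | "forward" | "none"
        Population mechanism; "none" bypasses the block (isolated baseline).
    lambda_cons : weight of the shuffle-consistency regularizer.
    consistency_space : "probs" | "latent" | "both" — where the two shuffled
        views are compared.
    class_weight : per-class cross-entropy weights (NC, Abnormal).
    support_size : size of the frozen support set concatenated to every
        batch at train and prediction time.

    Attributes (after fit)
    ----------------------
    model_ : the trained :class:`PopulationModel`.
    support_set_ : the frozen support :class:`SubjectFeatureSet`.
    history_ : per-epoch loss terms.
    classes_ : ``array([0, 1])``.
    """

    def __init__(self, expansion: int = 2, state_dim: int = 16,
                 conv_width: int = 0, population: str = "bidirectional",
                 norm: str = "layer", lambda_cons: float = 1.0,
                 consistency_space: str = "both",
                 class_weight: tuple[float, float] = (1.0, 4.5),
                 epochs: int = 500, learning_rate: float = 1e-3,
                 batch_size: int = 16, support_size: int = 16,
                 weight_decay: float = 0.02, input_noise_sd: float = 0.5,
                 random_state: int = 0):
        self.expansion = expansion
        self.state_dim = state_dim
        self.conv_width = conv_width
        self.population = population
        self.norm = norm
        self.lambda_cons = lambda_cons
        self.consistency_space = consistency_space
        self.class_weight = class_weight
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.support_size = support_size
        self.weight_decay = weight_decay
        self.input_noise_sd = input_noise_sd
        self.random_state = random_state

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_subjects, D) with matching y")
        if not np.isin(y, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        cohort = SubjectFeatureSet(
            X, np.arange(len(X)), y,
            None if groups is None else np.asarray(groups))
        config = SSMConfig(model_dim=X.shape[1], expansion=self.expansion,
                           state_dim=self.state_dim, conv_width=self.conv_width)
        model = PopulationModel.init(config, seed=self.random_state,
                                     mode=self.population, norm=self.norm)
        loss_config = LossConfig(
            lambda_cons=self.lambda_cons, class_weights=self.class_weight,
            epochs=self.epochs, learning_rate=self.learning_rate,
            effective_batch=self.batch_size, support_size=self.support_size,
            seed=self.random_state, weight_decay=self.weight_decay,
            consistency_space=self.consistency_space,
            input_noise_sd=self.input_noise_sd)
        self.model_, self.history_, self.support_set_ = train(
            model, cohort, loss_config)
        self.context_pool_ = cohort
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _context_rows(self, subject_row: np.ndarray, group,
                      rng: np.random.Generator) -> np.ndarray:
        """Training-pool context matching the training batch composition.

        A subject is predicted inside a sequence shaped exactly like a
        training step: the frozen support set plus ``batch_size - 1``
        reference rows drawn from the subject's own group when groups were
        given (from the whole pool otherwise), excluding the subject itself.
        """
        pool = self.context_pool_
        if group is not None and pool.groups is not None:
            candidates = np.flatnonzero(pool.groups == group)
            if candidates.size == 0:
                candidates = np.arange(len(pool))
        else:
            candidates = np.arange(len(pool))
        rows = pool.features[candidates]
        keep = ~np.all(rows == subject_row, axis=1)
        rows = rows[keep]
        k = min(self.batch_size - 1, len(rows))
        if k > 0:
            rows = rows[rng.choice(len(rows), size=k, replace=False)]
        return rows

    def predict_proba(self, X, groups=None):
        """Contextual probabilities, one forward pass per subject.

        Each subject is concatenated with the frozen support set and a
        deterministic draw of same-group training references, mirroring the
        composition of a training batch.
        """
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("X has the wrong shape")
        groups = None if groups is None else np.asarray(groups)
        rng = np.random.default_rng(self.random_state)
        out = np.empty((len(X), 2))
        support = self.support_set_.features
        for i in range(len(X)):
            if self.population == "none":
                seq = X[i][None, :]
            else:
                ctx = self._context_rows(X[i], None if groups is None else groups[i], rng)
                seq = np.concatenate([support, ctx, X[i][None, :]])
            _, logits = self.model_.forward_tensor(Tensor(seq))
            out[i] = prediction_set_from_logits(logits.data[-1:]).probabilities[0]
        return out

    def predict(self, X, groups=None):
        proba = self.predict_proba(X, groups=groups)
        return (proba[:, 1] >= 0.5).astype(int)

    def population_features(self, X, groups=None) -> np.ndarray:
        """Enriched per-subject representations Z' under the same protocol."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        groups = None if groups is None else np.asarray(groups)
        rng = np.random.default_rng(self.random_state)
        out = np.empty((len(X), self.n_features_in_), dtype=np.float32)
        for i in range(len(X)):
            if self.population == "none":
                seq = X[i][None, :]
            else:
                ctx = self._context_rows(X[i], None if groups is None else groups[i], rng)
                seq = np.concatenate([self.support_set_.features, ctx, X[i][None, :]])
            latent, _ = self.model_.forward_tensor(Tensor(seq))
            out[i] = latent.data[-1]
        return out

    def _more_tags(self):
        return {"binary_only": True}
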