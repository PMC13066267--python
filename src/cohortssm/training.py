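"""Shuffle-consistency training.

Each step draws a mini-batch of subjects, concatenates the frozen support
set, and runs two forward views of the same concatenated sequence: the
arrival order and a uniformly random permutation.  The objective is

    L_total = L_CE(P, Y) + lambda * L_cons,

where L_CE is cost-sensitive cross-entropy restricted to the non-support
positions and L_cons penalizes the divergence between the two aligned views.
By default the divergence is measured both on the probability rows and on
the latent population representations (``consistency_space="both"``); it can
be restricted to either space.  Gradient flows through both views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .autodiff import Tensor
from .population import PopulationModel, PredictionSet, SubjectFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationOp",
    "ShuffledViewPair",
    "LossConfig",
    "TotalLoss",
    "sample_permutation",
    "consistency_loss",
    "weighted_cross_entropy",
    "total_loss",
    "build_support_set",
    "AdamW",
    "train",
]

_LOG_CLAMP = float(np.log(1e-12))


# ---------------------------------------------------------------------------
# permutations and loss terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationOp:
    """A permutation of 0..N-1 together with its precomputed inverse."""

    forward: np.ndarray
    inverse: np.ndarray

    def __post_init__(self):
        n = len(self.forward)
        if not np.array_equal(np.sort(self.forward), np.arange(n)):
            raise ValueError("not a permutation")
        if not np.array_equal(self.forward[self.inverse], np.arange(n)):
            raise ValueError("inverse does not invert forward")

    def __len__(self) -> int:
        return len(self.forward)


def sample_permutation(n: int, rng: np.random.Generator) -> PermutationOp:
    """Uniformly random permutation of 0..n-1, deterministic under ``rng``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    perm = rng.permutation(n)
    return PermutationOp(forward=perm, inverse=np.argsort(perm))


@dataclass
class ShuffledViewPair:
    """Predictions from the original and a permuted serialization."""

    P: PredictionSet
    P_pi: PredictionSet
    perm: PermutationOp

    def __post_init__(self):
        if len(self.P) != len(self.P_pi) or len(self.P) != len(self.perm):
            raise ValueError("views and permutation must share N")


def consistency_loss(pair: ShuffledViewPair) -> float:
    """Mean squared error between aligned probability rows.

    Row i of the shuffled view holds subject perm.forward[i], so the row
    aligned with subject i is ``P_pi[perm.inverse[i]]``; the loss is
    ``(1/N) sum_i ||p_i - p'_{pi^-1(i)}||_2^2`` and is zero iff the aligned
    rows coincide.
    """
    aligned = pair.P_pi.probabilities[pair.perm.inverse]
    diff = pair.P.probabilities - aligned
    return float((diff ** 2).sum(axis=1).mean())


def weighted_cross_entropy(P: PredictionSet, Y, weights=(1.0, 4.5)) -> float:
    """Cost-sensitive cross-entropy: mean_i -w_{y_i} log p_i[y_i]."""
    Y = np.asarray(Y, dtype=np.int64)
    if Y.shape[0] != len(P):
        raise ValueError("labels must match predictions")
    p_true = P.probabilities[np.arange(len(P)), Y]
    if np.any(p_true < 1e-12):
        logger.warning("clamping %d zero probabilities in cross-entropy",
                       int((p_true < 1e-12).sum()))
        p_true = np.maximum(p_true, 1e-12)
    w = np.asarray(weights, dtype=np.float64)[Y]
    return float(-(w * np.log(p_true)).mean())


class TotalLoss(NamedTuple):
    total: float
    ce: float
    cons: float


@dataclass
class LossConfig:
    """Training protocol constants.

    Defaults mirror the published protocol: lambda = 1.0 on the consistency
    term, 1.0:4.5 class weighting, 60 epochs of AdamW at a constant 4e-5
    learning rate, effective batch 32, a fixed support set of 16 subjects.
    """

    lambda_cons: float = 1.0
    class_weights: tuple[float, float] = (1.0, 4.5)
    epochs: int = 60
    learning_rate: float = 4e-5
    effective_batch: int = 32
    support_size: int = 16
    seed: int = 0
    weight_decay: float = 0.01
    consistency_space: str = "both"   # "probs" | "latent" | "both"
    support_strategy: str = "stratified"
    input_noise_sd: float = 0.0       # train-time feature jitter (augmentation)
    group_draws: int = 2              # random batch subsets drawn per group per epoch

    def __post_init__(self):
        if self.lambda_cons < 0:
            raise ValueError("lambda_cons must be non-negative")
        if min(self.class_weights) <= 0:
            raise ValueError("class weights must be positive")
        if self.consistency_space not in ("probs", "latent", "both"):
            raise ValueError("consistency_space must be probs|latent|both")


def total_loss(P: PredictionSet, P_pi: PredictionSet, perm: PermutationOp,
               Y, config: LossConfig) -> TotalLoss:
    """Eq-level objective on prediction sets: CE + lambda * consistency."""
    ce = weighted_cross_entropy(P, Y, config.class_weights)
    cons = consistency_loss(ShuffledViewPair(P, P_pi, perm))
    total = ce + config.lambda_cons * cons
    logger.debug("total_loss: ce=%.6f cons=%.6f total=%.6f", ce, cons, total)
    return TotalLoss(total, ce, cons)


# ---------------------------------------------------------------------------
# support set
# ---------------------------------------------------------------------------

def build_support_set(pool: SubjectFeatureSet, n: int,
                      strategy: str = "stratified", seed: int = 0) -> SubjectFeatureSet:
    """Select a frozen population context of n representative subjects.

    "stratified" draws classes proportionally to the pool (rounded, at least
    one of each); "prototype" takes, per class, the members closest to the
    class mean feature vector.  Deterministic under ``seed``.
    """
    if pool.labels is None:
        raise ValueError("support pool must be labeled")
    if len(pool) < n:
        raise ValueError("pool smaller than requested support size")
    labels = pool.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("support pool must contain both classes")
    if n == len(pool):
        return pool.subset(np.arange(len(pool)))

    n_pos = int(round(n * labels.mean()))
    n_pos = min(max(n_pos, 1), n - 1)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if strategy == "stratified":
        rng = np.random.default_rng(seed)
        chosen = np.concatenate([
            rng.choice(neg_idx, size=n - n_pos, replace=False),
            rng.choice(pos_idx, size=n_pos, replace=False)])
    elif strategy == "prototype":
        chosen_parts = []
        for idx, count in ((neg_idx, n - n_pos), (pos_idx, n_pos)):
            center = pool.features[idx].mean(axis=0)
            dist = np.linalg.norm(pool.features[idx] - center, axis=1)
            chosen_parts.append(idx[np.argsort(dist, kind="stable")[:count]])
        chosen = np.concatenate(chosen_parts)
    else:
        raise ValueError(f"unknown support strategy {strategy!r}")
    return pool.subset(np.sort(chosen))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay, constant learning rate.

    Decay applies to projection matrices only; state dynamics (A_log), the
    Delta bias, gains/biases and norm parameters are exempt, as is standard
    for state-space models (decaying A_log would drag the dynamics toward a
    fixed decay rate instead of letting the data choose it).
    """

    _NO_DECAY = ("A_log", "b_", "ln.", "skip_D", ".b")

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.decay_mask = {k: not any(tag in k for tag in self._NO_DECAY)
                           for k in params}
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            wd = self.wd if self.decay_mask[k] else 0.0
            p.data = p.data - self.lr * (update + wd * p.data)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _consistency_terms(latent1, logits1, latent2, logits2, space: str):
    """Squared divergence between two aligned views (Tensor graph)."""
    terms = []
    if space in ("probs", "both"):
        d = logits1.log_softmax().exp() - logits2.log_softmax().exp()
        terms.append((d * d).sum(axis=1).mean())
    if space in ("latent", "both"):
        # same form as the probability term: squared L2 norm per subject,
        # mean over subjects
        d = latent1 - latent2
        terms.append((d * d).sum(axis=1).mean())
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def _ce_term(logits: Tensor, labels: np.ndarray, weights) -> Tensor:
    logp = logits.log_softmax().maximum(_LOG_CLAMP)
    n = labels.shape[0]
    onehot = np.zeros((n, 2), dtype=np.float32)
    onehot[np.arange(n), labels] = np.asarray(weights, dtype=np.float32)[labels]
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def _iter_batches(train_idx: np.ndarray, groups, batch: int,
                  rng: np.random.Generator, group_draws: int = 1):
    """Yield index arrays: within-group batches when groups exist.

    Subjects sharing a group tag share cohort context, so batches never mix
    groups; each group contributes ``group_draws`` random subsets per epoch
    so that every subject is seen against varying peer compositions.
    """
    if groups is not None:
        uniq = np.unique(groups[train_idx])
        plan = np.repeat(rng.permutation(len(uniq)), group_draws)
        for gi in plan:
            members = train_idx[groups[train_idx] == uniq[gi]]
            if len(members) > batch:
                members = rng.choice(members, size=batch, replace=False)
            if len(members) >= 2:
                yield members
    else:
        shuffled = rng.permutation(train_idx)
        for start in range(0, len(shuffled), batch):
            chunk = shuffled[start:start + batch]
            if len(chunk) >= 2:
                yield chunk


def train(model: PopulationModel, cohort: SubjectFeatureSet, config: LossConfig,
          train_ids=None, test_ids=None, support: SubjectFeatureSet | None = None):
    """Fit the population model with shuffle-consistency regularization.

    Returns ``(model, history, support)`` with per-epoch mean loss terms.
    ``train_ids``/``test_ids`` are subject-id arrays; the support set is
    drawn from the training pool only.  Raises on any train/test overlap.
    """
    if cohort.labels is None:
        raise ValueError("training requires labels")
    all_ids = cohort.subject_ids
    if train_ids is None:
        train_idx = np.arange(len(cohort))
    else:
        train_idx = np.flatnonzero(np.isin(all_ids, np.asarray(train_ids)))
    if test_ids is not None:
        if np.intersect1d(np.asarray(train_ids if train_ids is not None else all_ids),
                          np.asarray(test_ids)).size:
            raise ValueError("leakage: train and test subjects overlap")

    rng = np.random.default_rng(config.seed)
    if support is None:
        support = build_support_set(cohort.subset(train_idx), config.support_size,
                                    strategy=config.support_strategy, seed=config.seed)
    if test_ids is not None and np.intersect1d(support.subject_ids,
                                               np.asarray(test_ids)).size:
        raise ValueError("leakage: support set contains test subjects")

    optimizer = AdamW(model.parameters(), lr=config.learning_rate,
                      weight_decay=config.weight_decay)
    n_support = len(support)
    support_X = support.features
    history = {"ce": [], "cons": [], "total": []}

    for _epoch in range(config.epochs):
        ep_ce, ep_cons, n_steps = 0.0, 0.0, 0
        for batch_idx in _iter_batches(train_idx, cohort.groups,
                                       config.effective_batch, rng,
                                       group_draws=config.group_draws):
            X_rows = np.concatenate([support_X, cohort.features[batch_idx]])
            if config.input_noise_sd > 0:
                X_rows = X_rows + rng.normal(
                    0.0, config.input_noise_sd, X_rows.shape).astype(np.float32)
            X = Tensor(X_rows)
            labels = cohort.labels[batch_idx]
            seq_n = X.shape[0]

            # CE view keeps the arrival order; the consistency view draws a
            # fresh permutation of the whole concatenated sequence each step
            latent1, logits1 = model.forward_tensor(X)
            perm = sample_permutation(seq_n, rng)

            ce = _ce_term(logits1.slice_rows(n_support, seq_n), labels,
                          config.class_weights)
            loss = ce
            cons_val = 0.0
            if config.lambda_cons > 0 and model.mode != "none":
                latent2, logits2 = model.forward_tensor(X, order=perm.forward)
                cons = _consistency_terms(latent1, logits1, latent2, logits2,
                                          config.consistency_space)
                loss = loss + cons * config.lambda_cons
                cons_val = float(cons.data)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            ep_ce += float(ce.data)
            ep_cons += cons_val
            n_steps += 1
        if n_steps:
            history["ce"].append(ep_ce / n_steps)
            history["cons"].append(ep_cons / n_steps)
            history["total"].append((ep_ce + config.lambda_cons * ep_cons) / n_steps)
            logger.info("epoch %d: ce=%.4f cons=%.6f", _epoch,
                        history["ce"][-1], history["cons"][-1])
    return model, history, support
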