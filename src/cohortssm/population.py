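"""Population-aware representation of an unordered subject set.

A cohort mini-batch is an unordered set of per-subject feature vectors.  To
let a sequence model exchange information between subjects, the set is
serialized under an arbitrary order, scanned in both directions with a single
shared parameter set (weight sharing makes the interaction symmetric), and
folded back onto the per-subject features through a residual connection:

    Z' = Norm(Z + Linear(H_fwd + H_bwd)),
    H_fwd = SSM(S),  H_bwd = Flip(SSM(Flip(S))).

A per-subject affine head on Z' produces two-class logits.  Outputs are
always re-aligned to the input container order, whatever serialization order
was used.  Reversal of the input order is the one permutation under which the
architecture is exactly equivariant by construction; general permutations are
handled by the shuffle-consistency regularizer during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .ssm import (ChannelSequence, SSMConfig, SSMParameters, init_parameters,
                  ssm_block_forward)

__all__ = [
    "SubjectFeatureSet",
    "PopulationRepresentation",
    "PredictionSet",
    "PopulationModel",
    "serialize",
    "flip",
    "bidirectional_shared_scan",
    "aggregate",
    "population_forward",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectFeatureSet:
    """An unordered batch of N subject feature vectors with optional labels.

    ``groups`` is optional acquisition-batch metadata (subjects sharing a
    group share cohort-level nuisance structure); it plays no role in the
    forward pass itself.
    """

    features: np.ndarray                  # (N, D)
    subject_ids: np.ndarray               # (N,) unique
    labels: np.ndarray | None = None      # (N,) in {0, 1}
    groups: np.ndarray | None = None      # (N,) optional

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty (N, D) matrix")
        self.subject_ids = np.asarray(self.subject_ids)
        if self.subject_ids.shape[0] != self.features.shape[0]:
            raise ValueError("subject_ids length must match features")
        if len(np.unique(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject_ids are rejected (set semantics)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != len(self) or not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary and match N")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != len(self):
                raise ValueError("groups length must match features")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, index) -> "SubjectFeatureSet":
        index = np.asarray(index)
        return SubjectFeatureSet(
            self.features[index], self.subject_ids[index],
            None if self.labels is None else self.labels[index],
            None if self.groups is None else self.groups[index])

    def reversed(self) -> "SubjectFeatureSet":
        return self.subset(np.arange(len(self))[::-1])


@dataclass
class PopulationRepresentation:
    """Context-enriched features, index-aligned with the input set."""

    Z_prime: np.ndarray

    def __post_init__(self):
        self.Z_prime = np.asarray(self.Z_prime)
        if not np.all(np.isfinite(self.Z_prime)):
            raise ValueError("enriched features must be finite")


@dataclass
class PredictionSet:
    """Per-subject class probabilities (rows on the simplex) and logits."""

    probabilities: np.ndarray   # (N, 2)
    logits: np.ndarray          # (N, 2)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        self.logits = np.asarray(self.logits, dtype=np.float64)
        if self.probabilities.shape != self.logits.shape:
            raise ValueError("probabilities and logits must share shape")
        if np.any(self.probabilities < -1e-9) or np.any(self.probabilities > 1 + 1e-9):
            raise ValueError("probabilities outside [0, 1]")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def __len__(self) -> int:
        return self.probabilities.shape[0]


# ---------------------------------------------------------------------------
# set <-> sequence plumbing
# ---------------------------------------------------------------------------

def _check_permutation(order, n: int) -> np.ndarray:
    order = np.asarray(order)
    if order.shape != (n,) or not np.array_equal(np.sort(order), np.arange(n)):
        raise ValueError("order must be a permutation of 0..N-1")
    return order


def serialize(fset: SubjectFeatureSet, order) -> ChannelSequence:
    """Impose an ordering on the set: row i of the output is feature row
    ``order[i]``."""
    order = _check_permutation(order, len(fset))
    return ChannelSequence(fset.features[order].copy(), ordering_tag="forward")


def flip(S):
    """Sequence reversal; an exact involution."""
    if isinstance(S, ChannelSequence):
        tag = "flipped" if S.ordering_tag == "forward" else "forward"
        return ChannelSequence(S.values[::-1].copy(), ordering_tag=tag)
    if isinstance(S, Tensor):
        return S.flip0()
    return np.asarray(S)[::-1].copy()


def bidirectional_shared_scan(S, params: SSMParameters):
    """Scan the sequence in both directions with the SAME parameter object.

    ``H_fwd = SSM(S)`` and ``H_bwd = Flip(SSM(Flip(S)))``; weight sharing is
    by identity, not by copy.
    """
    H_fwd = ssm_block_forward(S, params)
    H_bwd = flip(ssm_block_forward(flip(S), params))
    return H_fwd, H_bwd


def aggregate(Z, H_fwd, H_bwd, mix, norm="identity"):
    """Residual aggregation ``Z' = Norm(Z + Linear(H_fwd + H_bwd))``.

    ``mix`` is ``(W, b)``; ``norm`` is ``"identity"`` or
    ``("layer", gamma, beta)`` for per-row layer normalization.
    """
    as_tensor = isinstance(Z, Tensor)
    Z = Z if as_tensor else Tensor(np.asarray(Z))
    Hf = H_fwd if isinstance(H_fwd, Tensor) else Tensor(
        H_fwd.values if isinstance(H_fwd, ChannelSequence) else np.asarray(H_fwd))
    Hb = H_bwd if isinstance(H_bwd, Tensor) else Tensor(
        H_bwd.values if isinstance(H_bwd, ChannelSequence) else np.asarray(H_bwd))
    if Z.shape != Hf.shape or Z.shape != Hb.shape:
        raise ValueError("Z, H_fwd, H_bwd must share shape (N, D)")
    W, b = mix
    W = W if isinstance(W, Tensor) else Tensor(np.asarray(W))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b))
    out = Z + ((Hf + Hb) @ W + b)
    if norm != "identity":
        kind, gamma, beta = norm
        if kind != "layer":
            raise ValueError(f"unknown norm {kind!r}")
        gamma = gamma if isinstance(gamma, Tensor) else Tensor(np.asarray(gamma))
        beta = beta if isinstance(beta, Tensor) else Tensor(np.asarray(beta))
        out = out.layer_norm(gamma, beta)
    if as_tensor:
        return out
    return PopulationRepresentation(out.data.copy())


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class PopulationModel:
    """Shared scan + residual aggregation + per-subject affine head.

    ``mode`` selects the population mechanism: "bidirectional" (default),
    "forward" (unidirectional ablation) or "none" (population block bypassed;
    a context-free per-subject model).  ``norm`` is "layer" or "identity".
    """

    def __init__(self, ssm: SSMParameters, W_mix: Tensor, b_mix: Tensor,
                 ln_gamma: Tensor, ln_beta: Tensor, W_head: Tensor, b_head: Tensor,
                 mode: str = "bidirectional", norm: str = "layer"):
        if mode not in ("bidirectional", "forward", "none"):
            raise ValueError(f"unknown mode {mode!r}")
        if norm not in ("layer", "identity"):
            raise ValueError(f"unknown norm {norm!r}")
        self.ssm = ssm
        self.W_mix, self.b_mix = W_mix, b_mix
        self.ln_gamma, self.ln_beta = ln_gamma, ln_beta
        self.W_head, self.b_head = W_head, b_head
        self.mode = mode
        self.norm = norm

    # -- construction ---------------------------------------------------------
    @classmethod
    def init(cls, config: SSMConfig, seed: int, mode: str = "bidirectional",
             norm: str = "layer") -> "PopulationModel":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
        D = config.model_dim
        bound = 1.0 / np.sqrt(D)
        return cls(
            ssm=init_parameters(config, seed),
            W_mix=Tensor(rng.uniform(-bound, bound, (D, D)), requires_grad=True),
            b_mix=Tensor(np.zeros(D), requires_grad=True),
            ln_gamma=Tensor(np.ones(D), requires_grad=True),
            ln_beta=Tensor(np.zeros(D), requires_grad=True),
            W_head=Tensor(rng.uniform(-bound, bound, (D, 2)), requires_grad=True),
            b_head=Tensor(np.zeros(2), requires_grad=True),
            mode=mode, norm=norm)

    @property
    def config(self) -> SSMConfig:
        return self.ssm.config

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        if self.mode != "none":
            out.update(self.ssm.parameters())
            out.update({"mix.W": self.W_mix, "mix.b": self.b_mix})
        if self.norm == "layer":
            out.update({"ln.gamma": self.ln_gamma, "ln.beta": self.ln_beta})
        out.update({"head.W": self.W_head, "head.b": self.b_head})
        return out

    # -- forward --------------------------------------------------------------
    def forward_tensor(self, features: Tensor, order=None):
        """Returns (latent Z', logits), both re-aligned to container order."""
        n = features.shape[0]
        if n == 0:
            raise ValueError("empty subject set")
        order = np.arange(n) if order is None else _check_permutation(order, n)
        seq = features.take_rows(order)

        if self.mode == "none":
            mixed = seq
        else:
            H_fwd = ssm_block_forward(seq, self.ssm)
            if self.mode == "bidirectional":
                H_bwd = flip(ssm_block_forward(flip(seq), self.ssm))
                H = H_fwd + H_bwd
            else:
                H = H_fwd
            mixed = seq + (H @ self.W_mix + self.b_mix)

        if self.norm == "layer":
            latent = mixed.layer_norm(self.ln_gamma, self.ln_beta)
        else:
            latent = mixed
        logits = latent @ self.W_head + self.b_head

        inverse = np.argsort(order)
        return latent.take_rows(inverse), logits.take_rows(inverse)

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict:
        cfg = self.config
        return {
            "mode": self.mode,
            "norm": self.norm,
            "config": {"model_dim": cfg.model_dim, "expansion": cfg.expansion,
                       "state_dim": cfg.state_dim, "dt_rank": cfg.dt_rank,
                       "conv_width": cfg.conv_width,
                       "dt_init_range": list(cfg.dt_init_range)},
            "params": {k: v.data.copy() for k, v in self._all_tensors().items()},
        }

    def _all_tensors(self) -> dict[str, Tensor]:
        out = dict(self.ssm.parameters())
        out.update({"mix.W": self.W_mix, "mix.b": self.b_mix,
                    "ln.gamma": self.ln_gamma, "ln.beta": self.ln_beta,
                    "head.W": self.W_head, "head.b": self.b_head})
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "PopulationModel":
        c = state["config"]
        cfg = SSMConfig(model_dim=c["model_dim"], expansion=c["expansion"],
                        state_dim=c["state_dim"], dt_rank=c["dt_rank"],
                        conv_width=c["conv_width"],
                        dt_init_range=tuple(c["dt_init_range"]))
        model = cls.init(cfg, seed=0, mode=state["mode"], norm=state["norm"])
        for name, value in state["params"].items():
            model._all_tensors()[name].data = np.asarray(value, dtype=np.float32).copy()
        return model


def population_forward(fset: SubjectFeatureSet, model: PopulationModel,
                     order=None) -> PredictionSet:
    """Run the population model on a subject set.

    Output row i always refers to ``fset.subject_ids[i]`` regardless of the
    serialization order used internally.
    """
    _, logits = model.forward_tensor(Tensor(fset.features), order=order)
    return prediction_set_from_logits(logits.data)


def prediction_set_from_logits(logits: np.ndarray) -> PredictionSet:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return PredictionSet(probabilities=p, logits=np.asarray(logits, dtype=np.float64))
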