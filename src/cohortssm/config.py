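"""Schema-validated run configuration.

A run configuration merges the model dimensions, the training protocol, the
synthetic cohort conditions and the evaluation settings.  Unknown keys are
rejected so that typos fail before any computation starts; every report
embeds the fully resolved configuration for auditability.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

from .ssm import SSMConfig
from .synthetic import SyntheticCohortConfig
from .training import LossConfig

__all__ = ["ModelSection", "TrainingSection", "CohortSection", "RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    expansion: int = 2
    state_dim: int = 16
    conv_width: int = 0
    population: str = "bidirectional"
    norm: str = "layer"


class TrainingSection(_Strict):
    lambda_cons: float = 1.0
    class_weights: tuple[float, float] = (1.0, 4.5)
    epochs: int = 500
    learning_rate: float = 1e-3
    effective_batch: int = 16
    support_size: int = 16
    weight_decay: float = 0.02
    input_noise_sd: float = 0.5
    consistency_space: str = "both"


class CohortSection(_Strict):
    n_subjects: int = 355
    feature_dim: int = 64
    positive_fraction: float = 90 / 355
    context_strength: float = 1.0
    noise_sd: float = 0.1
    cohort_shift_sd: float = 5.0
    group_size: int = 32
    feature_noise_sd: float = 0.2


class RunConfig(_Strict):
    """Top-level, schema-validated configuration tree."""

    seed: int = 0
    k_folds: int = 5
    verbosity: str = "info"
    model: ModelSection = ModelSection()
    training: TrainingSection = TrainingSection()
    cohort: CohortSection = CohortSection()

    def ssm_config(self, model_dim: int) -> SSMConfig:
        return SSMConfig(model_dim=model_dim, expansion=self.model.expansion,
                         state_dim=self.model.state_dim,
                         conv_width=self.model.conv_width)

    def loss_config(self) -> LossConfig:
        t = self.training
        return LossConfig(lambda_cons=t.lambda_cons, class_weights=t.class_weights,
                          epochs=t.epochs, learning_rate=t.learning_rate,
                          effective_batch=t.effective_batch,
                          support_size=t.support_size, seed=self.seed,
                          weight_decay=t.weight_decay,
                          consistency_space=t.consistency_space,
                          input_noise_sd=t.input_noise_sd)

    def cohort_config(self) -> SyntheticCohortConfig:
        c = self.cohort
        return SyntheticCohortConfig(
            n_subjects=c.n_subjects, feature_dim=c.feature_dim,
            positive_fraction=c.positive_fraction,
            context_strength=c.context_strength, noise_sd=c.noise_sd,
            cohort_shift_sd=c.cohort_shift_sd, group_size=c.group_size,
            feature_noise_sd=c.feature_noise_sd, seed=self.seed)

    def resolved(self) -> dict:
        return self.model_dump()
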