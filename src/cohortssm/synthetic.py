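"""Synthetic cohorts with population-context-dependent labels.

The generator emulates the statistical shape of a screening cohort of ~355
subjects with a ~75:25 class imbalance, plus the one property the population
mechanism exists to exploit: part of the label signal is *relative* to the
cohort context.  Subjects belong to acquisition groups; every group carries a
shared additive nuisance shift (scanner/site effect) on the latent atrophy
score, and as ``context_strength`` (rho) goes to 1 the diagnostic label
becomes "is this subject in the top quantile of *its group*" — undecidable
from one subject's features alone, trivially decidable given the group.

A toy 3-D volume generator (bright "hippocampus" ellipsoid whose radius
shrinks with disease, dark "ventricle" cavity that enlarges) and a tiny fixed
random convolutional encoder allow end-to-end smoke tests without any real
imaging data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .population import SubjectFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticCohortConfig",
    "ToyVolumeConfig",
    "generate_feature_cohort",
    "generate_toy_volumes",
    "intensity_normalize",
    "crop_roi",
    "TinyEncoder",
    "oracle_balanced_accuracies",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the feature-level cohort.

    ``positive_fraction`` defaults to 90/355 (the 53:18 per-fold imbalance of
    the screening task).  ``context_strength`` rho blends absolute (rho=0)
    and purely relative (rho=1) label rules.  ``cohort_shift_sd`` is the
    standard deviation of the per-group nuisance shift that only population
    context can remove.
    """

    n_subjects: int = 355
    feature_dim: int = 64
    positive_fraction: float = 90 / 355
    context_strength: float = 1.0
    noise_sd: float = 0.1
    cohort_shift_sd: float = 5.0
    group_size: int = 32
    feature_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.positive_fraction < 1):
            raise ValueError("positive_fraction must be in (0, 1)")
        if not (0 <= self.context_strength <= 1):
            raise ValueError("context_strength must be in [0, 1]")
        if self.n_subjects < 4 or self.feature_dim < 1 or self.group_size < 2:
            raise ValueError("degenerate cohort dimensions")


def _latent_scores(config: SyntheticCohortConfig, rng: np.random.Generator):
    n = config.n_subjects
    n_groups = max(1, int(np.ceil(n / config.group_size)))
    groups = np.repeat(np.arange(n_groups), config.group_size)[:n]
    atrophy = rng.standard_normal(n)
    shifts = rng.normal(0.0, config.cohort_shift_sd, size=n_groups)
    s = atrophy + shifts[groups]
    return s, groups


def _context_labels(s, groups, config: SyntheticCohortConfig,
                    rng: np.random.Generator) -> np.ndarray:
    q = 1.0 - config.positive_fraction
    rho = config.context_strength
    t_global = np.quantile(s, q)
    q_group = np.empty_like(s)
    for g in np.unique(groups):
        mask = groups == g
        q_group[mask] = np.quantile(s[mask], q)
    score = (1 - rho) * (s - t_global) + rho * (s - q_group)
    score = score + config.noise_sd * rng.standard_normal(len(s))
    labels = (score > 0).astype(np.int64)
    rate = labels.mean()
    if rate == 0.0 or rate == 1.0:
        raise ValueError("label calibration failed: single-class cohort")
    return labels


def generate_feature_cohort(config: SyntheticCohortConfig) -> SubjectFeatureSet:
    """Draw a fully seeded cohort of labeled feature vectors.

    Features are a random linear embedding of the observed score
    (atrophy + group shift) plus isotropic distractor noise; the marginal
    positive rate is calibrated to ``positive_fraction`` through empirical
    quantile thresholds.
    """
    rng = np.random.default_rng(config.seed)
    s, groups = _latent_scores(config, rng)
    labels = _context_labels(s, groups, config, rng)

    D = config.feature_dim
    w = rng.standard_normal(D)
    w /= np.linalg.norm(w)
    features = np.outer(s, w) + config.feature_noise_sd * rng.standard_normal(
        (config.n_subjects, D))
    ids = np.array([f"SUBJ{i:04d}" for i in range(config.n_subjects)])
    return SubjectFeatureSet(features.astype(np.float32), ids, labels, groups)


def oracle_balanced_accuracies(config: SyntheticCohortConfig,
                               seed: int | None = None) -> tuple[float, float]:
    """Analytic oracles on the generative model itself (noise-free features).

    Returns (isolated, contextual) balanced accuracy: the isolated oracle is
    the best single threshold on the observed score; the contextual oracle
    thresholds the score relative to its within-group quantile.  The gap
    between the two is the signal a population-aware model can capture.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    s, groups = _latent_scores(config, rng)
    labels = _context_labels(s, groups, config, rng)

    def bacc(pred):
        p0 = (pred[labels == 0] == 0).mean()
        p1 = (pred[labels == 1] == 1).mean()
        return 0.5 * (p0 + p1)

    thresholds = np.quantile(s, np.linspace(0.01, 0.99, 197))
    isolated = max(bacc((s > t).astype(int)) for t in thresholds)

    q = 1.0 - config.positive_fraction
    rel = np.empty_like(s)
    for g in np.unique(groups):
        mask = groups == g
        rel[mask] = s[mask] - np.quantile(s[mask], q)
    contextual = bacc((rel > 0).astype(int))
    return float(isolated), float(contextual)


# ---------------------------------------------------------------------------
# toy volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyVolumeConfig:
    """Phantom "hippocampal ROI" volumes.

    One bright ellipsoid (hippocampus; atrophied = smaller radius in the
    disease class) and one dark cavity (ventricle; enlarged in disease) on a
    noisy background, on a ``grid_size``^3 voxel grid.
    """

    grid_size: int = 64
    n_subjects: int = 20
    positive_fraction: float = 0.5
    hippo_radius_control: float = 10.0
    hippo_radius_disease: float = 8.0
    ventricle_radius_control: float = 5.0
    ventricle_radius_disease: float = 7.0
    radius_sd: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        radii = (self.hippo_radius_control, self.hippo_radius_disease,
                 self.ventricle_radius_control, self.ventricle_radius_disease)
        if min(radii) <= 0 or max(radii) >= self.grid_size / 2:
            raise ValueError("radii must be positive and inside the grid")


def generate_toy_volumes(config: ToyVolumeConfig):
    """Returns ``(volumes, labels)``: float32 (n, G, G, G) in [0, 1]."""
    rng = np.random.default_rng(config.seed)
    G = config.grid_size
    n = config.n_subjects
    n_pos = int(round(n * config.positive_fraction))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    ax = np.arange(G)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    c_h = G // 2 - G // 8          # hippocampus center, off-center (x, y, z alike)
    c_v = G // 2 + G // 8          # ventricle center
    d_h = np.sqrt((X - c_h) ** 2 + (Y - c_h) ** 2 + (Z - c_h) ** 2)
    d_v = np.sqrt((X - c_v) ** 2 + (Y - c_v) ** 2 + (Z - c_v) ** 2)

    volumes = np.empty((n, G, G, G), dtype=np.float32)
    for i in range(n):
        if labels[i] == 1:
            r_h = config.hippo_radius_disease
            r_v = config.ventricle_radius_disease
        else:
            r_h = config.hippo_radius_control
            r_v = config.ventricle_radius_control
        r_h = max(1.0, r_h + config.radius_sd * rng.standard_normal())
        r_v = max(1.0, r_v + config.radius_sd * rng.standard_normal())
        vol = 0.3 + config.noise_sd * rng.standard_normal((G, G, G))
        vol[d_h <= r_h] = 1.0
        vol[d_v <= r_v] = 0.0
        volumes[i] = intensity_normalize(vol)
    return volumes, labels


def intensity_normalize(volume: np.ndarray) -> np.ndarray:
    """Affine rescale of voxel values to [0, 1] (min -> 0, max -> 1)."""
    volume = np.asarray(volume, dtype=np.float32)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        warnings.warn("constant volume: normalizing to all zeros")
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo)


def crop_roi(volume: np.ndarray, center, size: int, pad: bool = False) -> np.ndarray:
    """The ``size``^3 box centered at ``center`` (0-based, half-open boxes).

    Without padding the box must lie inside the volume; with ``pad=True`` it
    is zero-padded to the exact requested size.  The center itself must be a
    voxel of the volume.
    """
    volume = np.asarray(volume)
    center = np.asarray(center, dtype=int)
    if volume.ndim != 3 or center.shape != (3,):
        raise ValueError("need a 3-D volume and a 3-vector center")
    if np.any(center < 0) or np.any(center >= np.array(volume.shape)):
        raise ValueError("center outside volume")
    lo = center - size // 2
    hi = lo + size
    if not pad and (np.any(lo < 0) or np.any(hi > np.array(volume.shape))):
        raise ValueError("crop box outside volume (use pad=True to zero-pad)")
    out = np.zeros((size, size, size), dtype=volume.dtype)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, np.array(volume.shape))
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
        volume[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    return out


class TinyEncoder:
    """A small fixed-weight strided 3-D convolutional tower to D features.

    Weights are drawn once from ``seed`` and never trained; the class is a
    drop-in stand-in for any volumetric backbone exposing
    ``encoder(volume) -> (D,)``.  Deterministic by construction.
    """

    def __init__(self, feature_dim: int, grid_size: int = 64, seed: int = 0,
                 channels: tuple[int, int] = (8, 32)):
        if grid_size % 16 != 0:
            raise ValueError("grid_size must be divisible by 16")
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.grid_size = grid_size
        self.feature_dim = feature_dim
        k = 4
        self.W1 = (rng.standard_normal((c1, k, k, k)) / k ** 1.5).astype(np.float32)
        self.W2 = (rng.standard_normal((c2, k, k, k, c1)) /
                   (k ** 1.5 * np.sqrt(c1))).astype(np.float32)
        self.W3 = (rng.standard_normal((c2, feature_dim)) / np.sqrt(c2)).astype(np.float32)

    @staticmethod
    def _blocks(x: np.ndarray, k: int) -> np.ndarray:
        # (G, G, G, C) -> (G/k, G/k, G/k, k, k, k, C) non-overlapping blocks
        G = x.shape[0]
        C = x.shape[3]
        x = x.reshape(G // k, k, G // k, k, G // k, k, C)
        return x.transpose(0, 2, 4, 1, 3, 5, 6)

    @staticmethod
    def _silu(x: np.ndarray) -> np.ndarray:
        return x / (1.0 + np.exp(-x))

    def __call__(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=np.float32)
        if volume.shape != (self.grid_size,) * 3:
            raise ValueError(f"expected a {self.grid_size}^3 volume")
        x = volume[..., None]
        x = self._silu(np.einsum("xyzijkc,oijk->xyzo", self._blocks(x, 4), self.W1))
        x = self._silu(np.einsum("xyzijkc,oijkc->xyzo", self._blocks(x, 4), self.W2))
        pooled = x.mean(axis=(0, 1, 2))
        return (pooled @ self.W3).astype(np.float32)

    def encode_volumes(self, volumes: np.ndarray) -> np.ndarray:
        return np.stack([self(v) for v in volumes])
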