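"""Desk-scale synthetic cohorts with planted connectopic structure.

Each subject shares a set of K latent network timecourses.  Target voxels
mix the networks through a smooth weighting along a planted spatial axis;
seed voxels do the same with a subject-specific monotone warp of the axis,
plus white noise.  Seed-to-target connectivity therefore varies smoothly
along the planted axis, which is what every estimation module in this
package is meant to recover.  A toy 6-nucleus parcellation bins the seed
along the first axis, and phenotypes are noisy linear functions of the
subject-level latent parameters that shape each subject's gradient.

Ground truth (planted coordinates, labels, generating weights) is carried
separately and never consumed by estimation code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TimeseriesMatrix
from .prediction import AtlasLabels, NUCLEUS_NAMES
from .spatial_stats import VoxelGeometry

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "truth_recovery_score",
]


@dataclass
class SyntheticConfig:
    """Generator parameters.  Defaults run the full pipeline in seconds."""

    n_subjects: int = 20
    seed_shape: tuple = (8, 8, 8)
    seed_radius: float = 3.9  # ellipsoid radius in voxels -> ~250 voxels
    n_target: int = 600
    t: int = 120
    K: int = 6
    gradient_axes: tuple = ((1.0, 0.0, 0.0),)
    mixing_sharpness: float = 5.0
    noise_sd: float = 0.5
    subject_warp_sd: float = 0.25
    voxel_size_mm: float = 2.0
    n_latent: int = 3
    phenotype_loadings: dict = field(
        default_factory=lambda: {
            "anat_metric": (1.0, 0.0, 0.0),
            "cog_metric": (0.0, 1.0, 0.5),
            "null_metric": (0.0, 0.0, 0.0),
        }
    )
    phenotype_noise_sd: float = 0.1
    master_seed: int = 2024
    require_full_rank: bool = True

    def __post_init__(self):
        if self.t < 10:
            raise ValueError("need at least 10 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.require_full_rank and self.n_target < self.t - 1:
            raise ValueError(
                f"equivalence mode needs at least t-1={self.t - 1} target "
                f"voxels, got {self.n_target}"
            )


@dataclass
class SyntheticTruth:
    """Planted structure; for evaluation only, never for estimation."""

    planted_coords: np.ndarray  # m x n_axes, in [0, 1]
    subject_coords: np.ndarray  # n_subjects x m, axis-1 coordinate after warp
    labels: np.ndarray
    subject_latents: np.ndarray  # n_subjects x n_latent
    phenotype_weights: dict
    network_centers: np.ndarray


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    seed_ts: list  # per-subject TimeseriesMatrix
    target_ts: list
    labels: AtlasLabels
    phenotypes: pd.DataFrame
    truth: SyntheticTruth
    geometry: VoxelGeometry


def _ellipsoid_mask(shape: tuple, radius: float) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape).reshape(3, -1).T
    dist = np.linalg.norm((idx - center) / radius, axis=1)
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(idx[dist <= 1.0].T)] = True
    return vol


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _mixing_weights(coord01: np.ndarray, centers: np.ndarray, sharpness: float):
    """Smooth voxel-by-network weights along a unit coordinate."""
    d2 = (coord01[:, None] - centers[None, :]) ** 2
    return _softmax(-sharpness * d2, axis=1)


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a cohort with planted gradients, labels, and phenotypes.

    Deterministic in ``config.master_seed``: every stochastic draw comes
    from a seed-sequence spawn of the master seed.
    """
    cfg = config if config is not None else SyntheticConfig()
    root = np.random.SeedSequence(cfg.master_seed)
    subj_seqs = root.spawn(cfg.n_subjects)
    rng_global = np.random.default_rng(root.spawn(1)[0])

    mask = _ellipsoid_mask(cfg.seed_shape, cfg.seed_radius)
    voxel_ids = np.flatnonzero(mask.ravel())
    ijk = np.argwhere(mask)
    m = len(voxel_ids)
    coords_mm = ijk * cfg.voxel_size_mm
    geometry = VoxelGeometry(
        coordinates=coords_mm, space="synthetic", voxel_ids=voxel_ids
    )

    axes = np.asarray(cfg.gradient_axes, dtype=float)
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    proj = ijk @ axes.T  # m x n_axes
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    planted = (proj - lo) / np.where(hi > lo, hi - lo, 1.0)

    centers = (np.arange(cfg.K) + 0.5) / cfg.K
    target_coord = rng_global.uniform(0.0, 1.0, size=cfg.n_target)
    target_coord.sort()
    w_target = _mixing_weights(target_coord, centers, cfg.mixing_sharpness)

    # toy parcellation: 6 contiguous bins along planted axis 1
    edges = np.linspace(0.0, 1.0, len(NUCLEUS_NAMES) + 1)
    labels = np.digitize(planted[:, 0], edges[1:-1]) + 1
    atlas = AtlasLabels(
        labels=labels, names={i + 1: n for i, n in enumerate(NUCLEUS_NAMES)}
    )

    seed_ts, target_ts = [], []
    subject_coords = np.empty((cfg.n_subjects, m))
    latents = np.empty((cfg.n_subjects, cfg.n_latent))
    for s, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq)
        z = rng.standard_normal(cfg.n_latent)
        latents[s] = z
        warp = np.exp(cfg.subject_warp_sd * z[0])  # monotone coordinate warp
        c_subj = planted[:, 0] ** warp
        subject_coords[s] = c_subj

        h = rng.standard_normal((cfg.t, cfg.K))
        w_seed = _mixing_weights(c_subj, centers, cfg.mixing_sharpness)
        if axes.shape[0] > 1:
            # extra axes modulate the mixture multiplicatively
            for ax in range(1, axes.shape[0]):
                w_extra = _mixing_weights(
                    planted[:, ax], centers, cfg.mixing_sharpness
                )
                w_seed = w_seed * w_extra
                w_seed /= w_seed.sum(axis=1, keepdims=True)
        a = h @ w_seed.T + cfg.noise_sd * rng.standard_normal((cfg.t, m))
        b = h @ w_target.T + cfg.noise_sd * rng.standard_normal(
            (cfg.t, cfg.n_target)
        )
        if cfg.noise_sd == 0:
            # guarantee non-constant columns even in the noiseless regime
            a = a + 1e-12 * rng.standard_normal(a.shape)
            b = b + 1e-12 * rng.standard_normal(b.shape)
        seed_ts.append(
            TimeseriesMatrix(data=a, voxel_ids=voxel_ids, region_tag="seed")
        )
        target_ts.append(
            TimeseriesMatrix(
                data=b,
                voxel_ids=np.arange(cfg.n_target),
                region_tag="target",
            )
        )

    rng_ph = np.random.default_rng(root.spawn(2)[1])
    pheno = {"subject_id": [f"sub-{s:03d}" for s in range(cfg.n_subjects)]}
    weights = {}
    for name, loading in cfg.phenotype_loadings.items():
        lv = np.zeros(cfg.n_latent)
        lv[: len(loading)] = np.asarray(loading, dtype=float)[: cfg.n_latent]
        weights[name] = lv
        pheno[name] = latents @ lv + cfg.phenotype_noise_sd * rng_ph.standard_normal(
            cfg.n_subjects
        )
    phenotypes = pd.DataFrame(pheno)

    truth = SyntheticTruth(
        planted_coords=planted,
        subject_coords=subject_coords,
        labels=labels,
        subject_latents=latents,
        phenotype_weights=weights,
        network_centers=centers,
    )
    return SyntheticCohort(
        config=cfg,
        seed_ts=seed_ts,
        target_ts=target_ts,
        labels=atlas,
        phenotypes=phenotypes,
        truth=truth,
        geometry=geometry,
    )


def truth_recovery_score(estimated, truth: SyntheticTruth) -> np.ndarray:
    """Absolute Spearman correlation between estimated gradients and each
    planted axis, reporting the best gradient-to-axis assignment."""
    from scipy.optimize import linear_sum_assignment
    from scipy.stats import spearmanr

    g = estimated.gradients if hasattr(estimated, "gradients") else np.asarray(
        estimated
    )
    axes = truth.planted_coords
    n_axes = axes.shape[1]
    if n_axes > g.shape[1]:
        import warnings

        warnings.warn(
            f"{n_axes} planted axes but only {g.shape[1]} gradients; scoring "
            "the available pairs only",
            stacklevel=2,
        )
        n_axes = g.shape[1]
    rho = np.zeros((g.shape[1], n_axes))
    for i in range(g.shape[1]):
        for j in range(n_axes):
            rho[i, j] = abs(spearmanr(g[:, i], axes[:, j]).statistic)
    rows, cols = linear_sum_assignment(-rho)
    out = np.zeros(n_axes)
    for i, j in zip(rows, cols):
        if j < n_axes:
            out[j] = rho[i, j]
    return out
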