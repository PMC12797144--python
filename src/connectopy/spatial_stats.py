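"""Geometry analyses: gradient-vs-distance RSA and map correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata

from .manifold import GradientSet

__all__ = [
    "VoxelGeometry",
    "RsaResult",
    "gradient_dissimilarity",
    "rsa_geometry",
    "spatial_map_correlation",
]


@dataclass
class VoxelGeometry:
    """Millimeter coordinates of seed voxels (one triplet per voxel)."""

    coordinates: np.ndarray
    space: str = "unknown"
    voxel_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an m x 3 matrix")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_voxels(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class RsaResult:
    observed_r: float
    null_distribution: np.ndarray
    p_value: float

    def __post_init__(self):
        if not -1 <= self.observed_r <= 1:
            raise ValueError("observed r must lie in [-1, 1]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def gradient_dissimilarity(G: GradientSet | np.ndarray) -> np.ndarray:
    """Voxel-to-voxel Pearson distance of gradient coordinate vectors.

    ``D[i, j] = 1 - corr(G[i, :], G[j, :])``; requires at least two
    gradients per voxel and non-constant rows.
    """
    x = G.gradients if isinstance(G, GradientSet) else np.asarray(G, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("Pearson distance needs at least 2 gradients per voxel")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        rows = np.flatnonzero(sd == 0).tolist()
        raise ValueError(
            f"voxels {rows} have constant gradient vectors; Pearson distance "
            "is undefined"
        )
    xc = x - x.mean(axis=1, keepdims=True)
    xn = xc / np.linalg.norm(xc, axis=1, keepdims=True)
    r = np.clip(xn @ xn.T, -1.0, 1.0)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def rsa_geometry(
    G: GradientSet | np.ndarray,
    geom: VoxelGeometry,
    n_perm: int = 999,
    seed: int | None = None,
    correlation: str = "pearson",
) -> RsaResult:
    """Mantel-style RSA of gradient dissimilarity against physical distance.

    The observed statistic is the correlation between the vectorized upper
    triangles of the gradient Pearson-distance matrix and the Euclidean
    distance matrix of the voxel coordinates.  The null is built by jointly
    permuting the voxels of G (equivalently, rows and columns of its
    dissimilarity matrix), which preserves the internal structure of both
    matrices.  ``p = (count(null >= observed) + 1) / (n_perm + 1)``.
    """
    x = G.gradients if isinstance(G, GradientSet) else np.asarray(G, dtype=float)
    m = x.shape[0]
    if m < 4:
        raise ValueError("RSA needs at least 4 voxels")
    if geom.n_voxels != m:
        raise ValueError("geometry and gradients must cover the same voxels")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    if correlation not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation {correlation!r}")

    d_grad = gradient_dissimilarity(x)
    d_phys = squareform(pdist(geom.coordinates))
    v_phys = _upper(d_phys)
    if correlation == "spearman":
        v_phys = rankdata(v_phys)

    def stat(dg):
        v = _upper(dg)
        if correlation == "spearman":
            v = rankdata(v)
        return pearsonr(v, v_phys).statistic

    observed = float(stat(d_grad))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(m)
        null[b] = stat(d_grad[np.ix_(perm, perm)])
    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return RsaResult(observed_r=observed, null_distribution=null, p_value=float(p))


def spatial_map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation between two voxel maps on the same support."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share voxel support")
    ok = np.isfinite(a) & np.isfinite(b)
    if np.count_nonzero(ok) < 3:
        raise ValueError("need at least 3 common voxels")
    return float(pearsonr(a[ok], b[ok]).statistic)
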