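"""Connectivity fingerprints and voxel-to-voxel similarity matrices.

This module implements the four fingerprinting routes used throughout the
package:

``original``
    Seed timeseries are correlated against SVD-derived spatial modes of the
    target region; similarity between seed voxels is computed on those
    correlation profiles.
``rescaled``
    Same as ``original`` but each mode column is multiplied by its singular
    value, restoring the variance structure the correlation step discards.
``voxelwise``
    Seed timeseries are correlated directly against every target voxel
    (no SVD).
``within_seed``
    The seed-voxel-by-seed-voxel Pearson correlation matrix is used directly
    as the similarity matrix (no fingerprints at all).

With cosine similarity these routes satisfy two exact identities on
full-rank data: ``original`` reproduces ``within_seed``, and ``rescaled``
reproduces ``voxelwise``.  Both identities are exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeseriesMatrix",
    "SpatialModes",
    "FingerprintMatrix",
    "SimilarityMatrix",
    "compute_spatial_modes",
    "fingerprints",
    "within_seed_fc",
    "similarity",
    "build_similarity",
    "VARIANTS",
    "MEASURES",
]

VARIANTS = ("original", "rescaled", "voxelwise", "within_seed")
MEASURES = ("eta2", "cosine", "pearson_fc")

#: above this many fingerprint elements (m*q) the similarity is computed
#: from accumulated Gram statistics instead of the dense fingerprint matrix
DEFAULT_DENSE_BUDGET = 50_000_000


@dataclass
class TimeseriesMatrix:
    """Time-by-voxel signal matrix for one region.

    Parameters
    ----------
    data : ndarray, shape (t, v)
        One column per voxel, one row per timepoint.
    voxel_ids : sequence of int
        Linear voxel indices into the source mask, one per column.
    region_tag : str
        Free-form label, conventionally ``"seed"`` or ``"target"``.
    excluded_voxel_ids : list of int
        Voxels dropped at extraction time (e.g. constant signal), kept for
        provenance.
    """

    data: np.ndarray
    voxel_ids: np.ndarray
    region_tag: str = "seed"
    excluded_voxel_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("timeseries data must be 2-D (timepoints x voxels)")
        t, v = self.data.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if v < 1:
            raise ValueError("need at least one voxel")
        if self.voxel_ids.shape != (v,):
            raise ValueError(
                f"voxel_ids length {self.voxel_ids.shape} does not match "
                f"{v} data columns"
            )
        if len(np.unique(self.voxel_ids)) != v:
            raise ValueError("voxel_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contain non-finite values")
        sd = self.data.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            ids = self.voxel_ids[dead].tolist()
            raise ValueError(
                f"zero-variance (constant) signal in voxels {ids}; "
                "remove these voxels from the mask or extract with "
                "constant-voxel exclusion enabled"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def zscored(self) -> np.ndarray:
        """Columns standardized to zero mean, unit (population) SD."""
        x = self.data - self.data.mean(axis=0)
        return x / x.std(axis=0)


@dataclass
class SpatialModes:
    """SVD-reduced target representation ``B_tilde = U @ diag(s)``.

    ``modes`` columns are mutually orthogonal with norms equal to the
    singular values; ``right_vectors`` (V) is retained so the standardized
    target can be reconstructed as ``modes @ right_vectors.T``.
    """

    modes: np.ndarray
    singular_values: np.ndarray
    p: int
    right_vectors: np.ndarray | None = None

    def __post_init__(self):
        if self.modes.shape[1] != self.p:
            raise ValueError("mode count does not match p")
        if self.singular_values.shape != (self.p,):
            raise ValueError("singular value count does not match p")
        if np.any(self.singular_values < 0):
            raise ValueError("singular values must be non-negative")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")


@dataclass
class FingerprintMatrix:
    """Seed-voxel-by-feature connectivity fingerprints."""

    data: np.ndarray
    variant: str

    def __post_init__(self):
        if self.variant not in ("original", "rescaled", "voxelwise"):
            raise ValueError(f"unknown fingerprint variant {self.variant!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fingerprints contain non-finite values")
        if self.variant == "original" and np.any(np.abs(self.data) > 1 + 1e-9):
            raise ValueError("original-variant fingerprints must lie in [-1, 1]")

    @property
    def n_seed_voxels(self) -> int:
        return self.data.shape[0]


@dataclass
class SimilarityMatrix:
    """Symmetric seed-voxel-by-seed-voxel similarity with unit diagonal."""

    data: np.ndarray
    measure: str
    variant: str | None = None

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown similarity measure {self.measure!r}")
        m, m2 = self.data.shape
        if m != m2:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.data, self.data.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 1.0, atol=1e-6):
            raise ValueError("similarity diagonal must be 1")
        if self.measure == "eta2" and (
            self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9
        ):
            raise ValueError("eta2 similarities must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# operations


def compute_spatial_modes(
    target: TimeseriesMatrix, p: int | None = None
) -> SpatialModes:
    """SVD of the standardized target timeseries, truncated to ``p`` modes.

    Target columns are z-scored (centered and scaled to unit variance)
    before the decomposition.  Standardization rather than plain centering
    is what makes the rescaled-vs-voxelwise cosine identity exact on
    heteroscedastic data; centering alone already fixes the rank at
    ``t - 1``.

    Parameters
    ----------
    target : TimeseriesMatrix
        Target-region timeseries, t x n.
    p : int, optional
        Number of modes to keep.  Defaults to ``min(t - 1, n)``, the full
        rank of the standardized matrix.

    Returns
    -------
    SpatialModes
        ``modes = U @ diag(s)`` (t x p) together with the singular values
        and right singular vectors.
    """
    z = target.zscored()
    t, n = z.shape
    p_max = min(t - 1, n)
    if p is None:
        p = p_max
    elif p > p_max:
        raise ValueError(f"p={p} exceeds available rank min(t-1, n)={p_max}")
    elif p < 1:
        raise ValueError("p must be >= 1")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return SpatialModes(
        modes=u[:, :p] * s[:p],
        singular_values=s[:p],
        p=p,
        right_vectors=vt[:p].T,
    )


def _pearson_cross(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation between two t x * matrices."""
    xz = x - x.mean(axis=0)
    yz = y - y.mean(axis=0)
    xn = np.linalg.norm(xz, axis=0)
    yn = np.linalg.norm(yz, axis=0)
    if np.any(xn == 0) or np.any(yn == 0):
        raise ValueError("zero-variance column encountered in correlation")
    r = (xz / xn).T @ (yz / yn)
    return np.clip(r, -1.0, 1.0)


def fingerprints(
    seed: TimeseriesMatrix,
    target: TimeseriesMatrix,
    variant: str,
    modes: SpatialModes | None = None,
) -> FingerprintMatrix:
    """Connectivity fingerprints of each seed voxel.

    ``original``: Pearson correlation of seed voxels against the target's
    spatial modes (m x p).  ``rescaled``: the original matrix with column j
    multiplied by singular value s_j.  ``voxelwise``: Pearson correlation of
    seed voxels against raw target voxels (m x n).

    A precomputed ``modes`` object may be passed to avoid repeating the SVD.
    """
    if variant not in ("original", "rescaled", "voxelwise"):
        raise ValueError(f"unknown fingerprint variant {variant!r}")
    if seed.n_timepoints != target.n_timepoints:
        raise ValueError(
            f"seed has {seed.n_timepoints} timepoints but target has "
            f"{target.n_timepoints}"
        )
    if variant == "voxelwise":
        c = _pearson_cross(seed.data, target.data)
        return FingerprintMatrix(data=c, variant=variant)
    if modes is None:
        modes = compute_spatial_modes(target)
    c = _pearson_cross(seed.data, modes.modes)
    if variant == "rescaled":
        c = c * modes.singular_values
    return FingerprintMatrix(data=c, variant=variant)


def within_seed_fc(seed: TimeseriesMatrix) -> SimilarityMatrix:
    """Within-seed Pearson FC matrix, used directly as a similarity matrix."""
    if seed.n_voxels < 2:
        raise ValueError("within-seed FC needs at least 2 voxels")
    r = _pearson_cross(seed.data, seed.data)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(data=r, measure="pearson_fc", variant="within_seed")


def _similarity_from_gram(
    gram: np.ndarray, rowsum: np.ndarray, q: int, measure: str
) -> np.ndarray:
    """Similarity matrix from row Gram statistics of a fingerprint matrix.

    ``gram = C @ C.T``, ``rowsum = C @ 1``.  Both cosine and eta2 depend on
    the fingerprints only through these quantities, which allows a blockwise
    path over features without materializing C.
    """
    ss = np.diag(gram).copy()  # row sums of squares
    if measure == "cosine":
        norms = np.sqrt(ss)
        if np.any(norms == 0):
            rows = np.flatnonzero(norms == 0).tolist()
            raise ValueError(
                f"all-zero fingerprint rows {rows}: cosine similarity undefined"
            )
        s = gram / np.outer(norms, norms)
    elif measure == "eta2":
        # numerator: within-pair SS around pairwise means = ||x_i - x_j||^2 / 2
        sqdist = ss[:, None] + ss[None, :] - 2.0 * gram
        np.maximum(sqdist, 0.0, out=sqdist)
        mu = rowsum / q
        grand = (mu[:, None] + mu[None, :]) / 2.0
        denom = ss[:, None] + ss[None, :] - 2.0 * q * grand**2
        num = sqdist / 2.0
        bad = denom <= 0
        if np.any(bad):
            # identical constant pair: zero variance around the grand mean
            denom = np.where(bad, 1.0, denom)
            s = 1.0 - num / denom
            s[bad] = 1.0
        else:
            s = 1.0 - num / denom
        np.clip(s, 0.0, 1.0, out=s)
    else:
        raise ValueError(f"unsupported measure {measure!r} for fingerprints")
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return s


def similarity(fp: FingerprintMatrix, measure: str = "cosine") -> SimilarityMatrix:
    """Seed-voxel similarity from fingerprint rows.

    ``eta2`` follows the two-profile formulation: 1 minus the within-pair
    sum of squares around pairwise means, over the total sum of squares
    around the pair grand mean.  ``cosine`` is the normalized inner product
    of fingerprint rows.
    """
    c = fp.data
    if c.shape[0] < 2:
        raise ValueError("similarity needs at least 2 seed voxels")
    gram = c @ c.T
    s = _similarity_from_gram(gram, c.sum(axis=1), c.shape[1], measure)
    return SimilarityMatrix(data=s, measure=measure, variant=fp.variant)


def build_similarity(
    seed: TimeseriesMatrix,
    target: TimeseriesMatrix | None,
    variant: str,
    measure: str | None = None,
    modes: SpatialModes | None = None,
    dense_budget: int = DEFAULT_DENSE_BUDGET,
) -> SimilarityMatrix:
    """Dispatch seed/target timeseries to a similarity matrix.

    Parameters
    ----------
    variant : {"original", "rescaled", "voxelwise", "within_seed"}
    measure : {"eta2", "cosine"}, optional
        Defaults to cosine for the fingerprint variants.  ``within_seed``
        ignores ``target`` and accepts only ``pearson_fc`` (or None).
    dense_budget : int
        If the fingerprint matrix would exceed this many elements the
        similarity is accumulated blockwise from Gram statistics, with
        results identical to the dense path.
    """
    if variant == "within_seed":
        if measure not in (None, "pearson_fc"):
            raise ValueError(
                "within_seed variant defines its own measure (pearson_fc); "
                f"got {measure!r}"
            )
        return within_seed_fc(seed)
    if variant not in ("original", "rescaled", "voxelwise"):
        raise ValueError(f"unknown variant {variant!r}")
    if target is None:
        raise ValueError(f"variant {variant!r} requires a target region")
    if measure is None:
        measure = "cosine"
    if measure not in ("eta2", "cosine"):
        raise ValueError(f"unsupported measure {measure!r} for variant {variant!r}")

    m = seed.n_voxels
    q = target.n_voxels if variant == "voxelwise" else min(
        seed.n_timepoints - 1, target.n_voxels
    )
    if m * q > dense_budget:
        s = _blockwise_similarity(seed, target, variant, measure, modes)
    else:
        fp = fingerprints(seed, target, variant, modes=modes)
        s = similarity(fp, measure).data
    return SimilarityMatrix(data=s, measure=measure, variant=variant)


def _blockwise_similarity(
    seed: TimeseriesMatrix,
    target: TimeseriesMatrix,
    variant: str,
    measure: str,
    modes: SpatialModes | None,
    block: int = 4096,
) -> np.ndarray:
    """Gram accumulation over feature blocks; never materializes m x q."""
    t = seed.n_timepoints
    za = seed.zscored() / np.sqrt(t)  # rows of C are za.T @ zb
    if variant == "voxelwise":
        zb = target.zscored() / np.sqrt(t)
    else:
        if modes is None:
            modes = compute_spatial_modes(target)
        zb = modes.modes - modes.modes.mean(axis=0)
        norms = np.linalg.norm(zb, axis=0)
        zb = zb / norms  # correlation against each mode
        if variant == "rescaled":
            zb = zb * modes.singular_values
        za = seed.zscored()
        za = za / np.linalg.norm(za, axis=0)
    m = za.shape[1]
    q = zb.shape[1]
    gram = np.zeros((m, m))
    rowsum = np.zeros(m)
    for lo in range(0, q, block):
        cb = za.T @ zb[:, lo : lo + block]
        gram += cb @ cb.T
        rowsum += cb.sum(axis=1)
    return _similarity_from_gram(gram, rowsum, q, measure)
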