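"""Gradient embeddings: row sparsification plus LE / DE / PCA.

The similarity matrix is first sparsified row-wise (keeping only the
strongest fraction of connections per row, default top 10%), symmetrized,
and then embedded with one of three manifold techniques:

- ``LE``  — Laplacian eigenmap on the symmetric normalized graph Laplacian
- ``DE``  — diffusion map embedding (anisotropic normalization alpha=0.5,
  automatic diffusion time)
- ``PCA`` — principal axes of the column-centered similarity matrix

All three are deterministic up to per-column sign; a fixed convention
(the largest-magnitude coordinate of each gradient is positive) makes the
output bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import SimilarityMatrix

__all__ = [
    "GradientSet",
    "VarianceProfile",
    "sparsify_rows",
    "embed",
    "variance_explained",
    "gradients_from_similarity",
    "METHODS",
]

METHODS = ("LE", "DE", "PCA")

#: matrices at or below this size use a dense eigensolver
DENSE_LIMIT = 2000


@dataclass
class GradientSet:
    """Voxel-by-gradient embedding coordinates with provenance."""

    gradients: np.ndarray
    eigenvalues: np.ndarray
    method: str
    variant: str | None = None
    aligned: bool = False
    voxel_ids: np.ndarray | None = None

    def __post_init__(self):
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.gradients.ndim != 2 or self.gradients.shape[1] < 1:
            raise ValueError("gradients must be an m x g matrix with g >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown manifold method {self.method!r}")
        if not np.all(np.isfinite(self.gradients)):
            raise ValueError("gradients contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.gradients.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.gradients.shape[1]


@dataclass
class VarianceProfile:
    """Explained-variance ratios per gradient (non-increasing, sum <= 1)."""

    explained_ratio: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        r = np.asarray(self.explained_ratio, dtype=float)
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-9):
            raise ValueError("explained ratios must lie in [0, 1]")
        if np.any(np.diff(r) > 1e-9):
            raise ValueError("explained ratios must be non-increasing")
        if r.sum() > 1 + 1e-6:
            raise ValueError("explained ratios must sum to at most 1")
        self.explained_ratio = np.clip(r, 0.0, 1.0)


def sparsify_rows(
    S: SimilarityMatrix | np.ndarray,
    sparsity: float = 0.9,
    clip_negative: bool = True,
) -> np.ndarray:
    """Row-wise top-fraction sparsification of a similarity matrix.

    Per row, off-diagonal entries outside the top ``(1 - sparsity)``
    fraction (by value) are zeroed; the diagonal is excluded from the
    ranking and retained.  The result is symmetrized by averaging with its
    transpose.  Negative surviving entries are clipped to zero when
    ``clip_negative`` (required for the Laplacian-based embeddings).
    """
    a = S.data if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    m = a.shape[0]
    if a.shape != (m, m):
        raise ValueError("similarity matrix must be square")
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must lie in [0, 1)")
    n_off = m - 1
    keep = int(np.ceil((1.0 - sparsity) * n_off))
    if keep < 1:
        raise ValueError(
            f"sparsity {sparsity} leaves no off-diagonal entries in rows of "
            f"size {n_off}"
        )
    out = a.copy()
    if keep < n_off:
        work = a.copy()
        np.fill_diagonal(work, -np.inf)  # diagonal never competes
        # threshold at the keep-th largest off-diagonal entry per row
        part = np.partition(work, m - keep, axis=1)
        thresh = part[:, m - keep]
        mask = work >= thresh[:, None]
        np.fill_diagonal(mask, True)
        out[~mask] = 0.0
    out = (out + out.T) / 2.0
    if clip_negative:
        np.maximum(out, 0.0, out=out)
    return out


def _check_connected(w: np.ndarray) -> None:
    n_comp, labels = connected_components(csr_matrix(w), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components of sizes "
            f"{sizes}); lower the sparsity or repair the mask"
        )


def _fix_signs(g: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude coordinate is positive."""
    idx = np.argmax(np.abs(g), axis=0)
    signs = np.sign(g[idx, np.arange(g.shape[1])])
    signs[signs == 0] = 1.0
    return g * signs


def variance_explained(
    eigenvalues: np.ndarray, method: str, total: float | None = None
) -> VarianceProfile:
    """Normalize an eigenvalue spectrum to explained-variance ratios.

    ``eigenvalues`` are the per-gradient spectrum values on each method's
    own scale (PCA: component variances; DE: diffusion-operator
    eigenvalues; LE: ``1 - lambda`` of the normalized Laplacian).  ``total``
    is the normalizing mass of the full non-trivial spectrum; it defaults
    to the sum of the given values.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if method == "PCA" and np.any(lam < -1e-8 * max(1.0, np.abs(lam).max())):
        raise ValueError("negative PCA eigenvalues beyond numerical tolerance")
    lam = np.clip(lam, 0.0, None)
    tot = float(lam.sum()) if total is None else float(total)
    if tot <= 0:
        return VarianceProfile(np.zeros_like(lam))
    return VarianceProfile(np.clip(lam / tot, 0.0, 1.0))


def embed(
    S: SimilarityMatrix | np.ndarray,
    method: str,
    g: int = 3,
    sparsity: float | None = None,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    variant: str | None = None,
) -> tuple[GradientSet, VarianceProfile]:
    """Embed a (pre-sparsified) similarity matrix into ``g`` gradients.

    Parameters
    ----------
    S : SimilarityMatrix or ndarray
        Affinity matrix.  If ``sparsity`` is given, :func:`sparsify_rows`
        is applied first (with negative clipping for LE/DE only).
    method : {"LE", "DE", "PCA"}
    g : int
        Number of gradients to keep (the trivial constant component of
        LE/DE is dropped before counting).
    alpha : float
        Anisotropic normalization exponent for DE.
    diffusion_time : float
        DE diffusion time; ``0`` selects the automatic eigenvalue weighting
        ``lambda / (1 - lambda)``.

    Returns
    -------
    (GradientSet, VarianceProfile)
    """
    if method not in METHODS:
        raise ValueError(f"unknown manifold method {method!r}")
    var = variant if variant is not None else (
        S.variant if isinstance(S, SimilarityMatrix) else None
    )
    a = S.data if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if sparsity is not None:
        a = sparsify_rows(a, sparsity, clip_negative=(method != "PCA"))
    m = a.shape[0]

    if method == "PCA":
        if g > min(m - 1, a.shape[1]):
            raise ValueError(f"g={g} exceeds available components")
        x = a - a.mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        lam_full = s**2 / m  # component variances
        grads = _fix_signs(u[:, :g] * s[:g])
        ev = lam_full[:g]
        profile = variance_explained(ev, "PCA", total=float(lam_full.sum()))
        return (
            GradientSet(grads, ev, method, variant=var),
            profile,
        )

    # LE / DE operate on a non-negative affinity graph
    w = np.clip(a, 0.0, None)
    _check_connected(w)
    if g > m - 1:
        raise ValueError(f"g={g} exceeds the {m - 1} non-trivial dimensions")

    if method == "LE":
        d = w.sum(axis=1)
        inv_sqrt_d = 1.0 / np.sqrt(d)
        lap = -(w * inv_sqrt_d[:, None] * inv_sqrt_d[None, :])
        lap[np.diag_indices(m)] += 1.0
        lam, vec = eigh(lap)
        lam = np.clip(lam, 0.0, None)
        # drop the trivial (near-zero) component, keep the next g
        grads = _fix_signs(vec[:, 1 : g + 1])
        ev = lam[1 : g + 1]
        weights = np.clip(1.0 - lam[1:], 0.0, None)  # full non-trivial spectrum
        profile = variance_explained(
            weights[:g], "LE", total=float(weights.sum())
        )
        return GradientSet(grads, ev, method, variant=var), profile

    # DE: anisotropic kernel normalization, then symmetric diffusion operator
    d = w.sum(axis=1)
    k = w / np.outer(d**alpha, d**alpha)
    dk = k.sum(axis=1)
    inv_sqrt_dk = 1.0 / np.sqrt(dk)
    p_sym = k * inv_sqrt_dk[:, None] * inv_sqrt_dk[None, :]
    lam, vec = eigh(p_sym)
    lam = lam[::-1]
    vec = vec[:, ::-1]
    psi = vec * inv_sqrt_dk[:, None]
    psi = psi / psi[0, 0]  # normalize out the constant trivial component scale
    lam_nt = lam[1:]
    if diffusion_time <= 0:
        denom = np.where(np.abs(1.0 - lam_nt) < 1e-12, 1e-12, 1.0 - lam_nt)
        weights = lam_nt / denom
    else:
        weights = np.sign(lam_nt) * np.abs(lam_nt) ** diffusion_time
    grads = _fix_signs(psi[:, 1 : g + 1] * weights[:g])
    ev = lam_nt[:g]
    spectrum = np.clip(lam_nt, 0.0, None)
    profile = variance_explained(
        spectrum[:g], "DE", total=float(spectrum.sum())
    )
    return GradientSet(grads, ev, method, variant=var), profile


def gradients_from_similarity(
    S: SimilarityMatrix | np.ndarray,
    method: str = "DE",
    g: int = 3,
    sparsity: float = 0.9,
    **kwargs,
) -> tuple[GradientSet, VarianceProfile]:
    """Standard pipeline step: sparsify then embed (defaults: 0.9, g=3)."""
    return embed(S, method=method, g=g, sparsity=sparsity, **kwargs)
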