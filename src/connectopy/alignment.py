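"""Group templates, Hungarian gradient matching, and Procrustes alignment.

Group-level gradients come from embedding the element-wise mean of the
individual similarity matrices.  Each individual's gradients are then
matched to the group components with the Hungarian algorithm (cost
``1 - |r|``, which handles the sign indeterminacy of eigenvector-based
embeddings) and rotated onto the template with orthogonal Procrustes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import SimilarityMatrix
from .manifold import GradientSet, VarianceProfile, gradients_from_similarity

__all__ = [
    "GradientMatch",
    "GroupTemplate",
    "group_template",
    "match_hungarian",
    "apply_match",
    "procrustes_align",
    "gradient_stability",
    "cross_variant_similarity",
    "unaligned_cross_variant_similarity",
    "zscore_and_difference",
]


@dataclass
class GradientMatch:
    """Bijection from individual gradient columns to group components.

    ``permutation[j]`` is the individual column matched to group component
    j; ``signs[j]`` flips it so the matched correlation is positive.
    """

    permutation: np.ndarray
    signs: np.ndarray
    match_scores: np.ndarray

    def __post_init__(self):
        g = len(self.permutation)
        if sorted(self.permutation.tolist()) != list(range(g)):
            raise ValueError("permutation must be a bijection")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signs must be +/-1")
        if np.any(self.match_scores < -1e-9) or np.any(self.match_scores > 1 + 1e-9):
            raise ValueError("match scores must lie in [0, 1]")


@dataclass
class GroupTemplate:
    mean_similarity: SimilarityMatrix
    group_gradients: GradientSet
    variance: VarianceProfile
    per_gradient_stability: np.ndarray | None = None


def group_template(
    similarities: list[SimilarityMatrix],
    method: str = "DE",
    g: int = 3,
    sparsity: float = 0.9,
    **embed_kwargs,
) -> GroupTemplate:
    """Average individual similarity matrices, then embed the mean."""
    if not similarities:
        raise ValueError("need at least one similarity matrix")
    m = similarities[0].n_voxels
    measure = similarities[0].measure
    variant = similarities[0].variant
    mean = np.zeros((m, m))
    for s in similarities:
        if s.n_voxels != m:
            raise ValueError(
                f"similarity size mismatch: {s.n_voxels} voxels vs {m}"
            )
        mean += s.data
    mean /= len(similarities)
    mean_sim = SimilarityMatrix(data=mean, measure=measure, variant=variant)
    grads, var = gradients_from_similarity(
        mean_sim, method=method, g=g, sparsity=sparsity, **embed_kwargs
    )
    return GroupTemplate(mean_similarity=mean_sim, group_gradients=grads, variance=var)


def _column_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation matrix between columns of a and b."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    an = np.linalg.norm(az, axis=0)
    bn = np.linalg.norm(bz, axis=0)
    an[an == 0] = np.inf
    bn[bn == 0] = np.inf
    return (az / an).T @ (bz / bn)


def match_hungarian(individual: GradientSet, group: GradientSet) -> GradientMatch:
    """Assign individual gradients to group components.

    Solves the linear assignment problem maximizing the summed absolute
    Pearson correlation between matched columns; signs are chosen so every
    matched correlation is non-negative.
    """
    if individual.n_gradients != group.n_gradients:
        raise ValueError(
            f"gradient count mismatch: {individual.n_gradients} vs "
            f"{group.n_gradients}"
        )
    if individual.n_voxels != group.n_voxels:
        raise ValueError("voxel count mismatch between gradient sets")
    r = _column_corr(individual.gradients, group.gradients)  # ind x group
    rows, cols = linear_sum_assignment(1.0 - np.abs(r))
    perm = np.empty(len(rows), dtype=int)
    signs = np.empty(len(rows), dtype=int)
    scores = np.empty(len(rows))
    for i, j in zip(rows, cols):
        perm[j] = i
        raw = r[i, j]
        signs[j] = 1 if raw >= 0 else -1
        scores[j] = abs(raw)
    return GradientMatch(permutation=perm, signs=signs, match_scores=scores)


def apply_match(individual: GradientSet, match: GradientMatch) -> GradientSet:
    """Reorder and sign-flip individual gradients per a Hungarian match."""
    g = individual.gradients[:, match.permutation] * match.signs
    return GradientSet(
        gradients=g,
        eigenvalues=np.asarray(individual.eigenvalues)[match.permutation],
        method=individual.method,
        variant=individual.variant,
        aligned=individual.aligned,
        voxel_ids=individual.voxel_ids,
    )


def procrustes_align(
    individual: GradientSet,
    group: GradientSet,
    match: GradientMatch | None = None,
) -> GradientSet:
    """Orthogonal Procrustes rotation of individual gradients onto the group.

    Columns of both sets are centered; the closed-form orthogonal
    (rotation + reflection, no scaling) transform minimizing the Frobenius
    distance to the template is applied.  If ``match`` is given it is
    applied first.
    """
    x = individual.gradients
    if match is not None:
        x = x[:, match.permutation] * match.signs
    y = group.gradients
    if x.shape != y.shape:
        raise ValueError("individual and group gradients must share shape")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if np.linalg.matrix_rank(xc) < x.shape[1]:
        raise ValueError("rank-degenerate gradient matrix cannot be aligned")
    u, _, vt = np.linalg.svd(xc.T @ yc)
    q = u @ vt
    return GradientSet(
        gradients=xc @ q,
        eigenvalues=np.asarray(individual.eigenvalues),
        method=individual.method,
        variant=individual.variant,
        aligned=True,
        voxel_ids=individual.voxel_ids,
    )


def align_to_template(
    individual: GradientSet, group: GradientSet
) -> tuple[GradientSet, GradientMatch]:
    """Convenience: Hungarian match followed by Procrustes alignment."""
    match = match_hungarian(individual, group)
    return procrustes_align(individual, group, match), match


def gradient_stability(
    aligned_individuals: list[GradientSet], group: GradientSet
) -> np.ndarray:
    """Per-gradient mean absolute spatial correlation with the template.

    Used to decide how many gradients to retain (the first-three rule
    requires each mean |r| to exceed 0.5).
    """
    if not aligned_individuals:
        raise ValueError("need at least one aligned individual")
    g = group.n_gradients
    acc = np.zeros(g)
    for ind in aligned_individuals:
        r = _column_corr(ind.gradients, group.gradients)
        acc += np.abs(np.diag(r))
    return acc / len(aligned_individuals)


def retained_gradients(stability: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean retention mask: stability above threshold."""
    return np.asarray(stability) > threshold


def cross_variant_similarity(
    gsets_a: list[GradientSet], gsets_b: list[GradientSet]
) -> np.ndarray:
    """Per-gradient mean |r| between two per-subject lists of unaligned
    gradient sets, Hungarian-matched per subject.

    Raises if any input is aligned: the statistic is defined on unaligned
    gradients so it is not confounded by the shared group template.
    """
    if len(gsets_a) != len(gsets_b) or not gsets_a:
        raise ValueError("need equal-length, non-empty gradient set lists")
    g = gsets_a[0].n_gradients
    acc = np.zeros(g)
    for ga, gb in zip(gsets_a, gsets_b):
        if ga.aligned or gb.aligned:
            raise ValueError(
                "cross-variant similarity is defined on unaligned gradients"
            )
        match = match_hungarian(ga, gb)
        acc += match.match_scores
    return acc / len(gsets_a)


def unaligned_cross_variant_similarity(
    gsets_by_variant: dict[str, list[GradientSet]],
) -> dict[tuple[str, str], np.ndarray]:
    """All pairwise cross-variant similarity summaries.

    Input maps variant name to a per-subject list of unaligned gradient
    sets (all sharing voxel ordering).  For each unordered variant pair the
    per-gradient mean absolute matched correlation across subjects is
    returned.  Averaging across manifold methods, if desired, is the
    caller's responsibility (subjects first, then methods).
    """
    names = list(gsets_by_variant)
    out: dict[tuple[str, str], np.ndarray] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            out[(a, b)] = cross_variant_similarity(
                gsets_by_variant[a], gsets_by_variant[b]
            )
    return out


def zscore_and_difference(
    local: GradientSet, global_: GradientSet
) -> np.ndarray:
    """Per-gradient z-scored difference map (local minus global)."""
    if local.gradients.shape != global_.gradients.shape:
        raise ValueError("gradient shape mismatch")

    def _z(x):
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant gradient column cannot be z-scored")
        return (x - mu) / sd

    return _z(local.gradients) - _z(global_.gradients)
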