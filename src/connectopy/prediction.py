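"""Gradient-based prediction: nucleus discriminant analysis and sparse
phenotype regression with nested cross-validation.

Classification: the group-level gradient coordinates of each seed voxel are
fed to a linear discriminant model predicting its nucleus label, scored by
stratified 5-fold CV accuracy over 20 re-randomized repetitions, with a
permutation-based chance level.

Regression: per-subject gradient features (first g aligned gradients
flattened and z-scored within subject) enter a LASSO with 10-by-10-fold
nested CV repeated 20 times; performance is the Spearman correlation
between concatenated held-out predictions and the true phenotype.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning; per-repetition sub-seeds are logged
on the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "AtlasLabels",
    "PredictionReport",
    "classify_nuclei",
    "chance_accuracy",
    "lasso_predict",
    "significance_summary",
    "nucleus_contribution",
    "weight_consistency",
    "NUCLEUS_NAMES",
]

NUCLEUS_NAMES = (
    "anterior",
    "lateral",
    "ventral",
    "intralaminar",
    "medial",
    "posterior",
)


@dataclass
class AtlasLabels:
    """Integer nucleus label per seed voxel (0 reserved for background)."""

    labels: np.ndarray
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a flat per-voxel vector")
        fg = self.labels[self.labels != 0]
        if len(np.unique(fg)) < 2:
            raise ValueError("need at least 2 non-empty label classes")

    @property
    def foreground(self) -> np.ndarray:
        return self.labels != 0


@dataclass
class PredictionReport:
    """Per-repetition performance plus weight/contribution summaries."""

    per_repetition: np.ndarray
    metric: str  # "accuracy" | "spearman_rho"
    chance_level: float | None = None
    weight_map: np.ndarray | None = None
    sub_seeds: list = field(default_factory=list)
    fold_log: list = field(default_factory=list)

    def __post_init__(self):
        self.per_repetition = np.asarray(self.per_repetition, dtype=float)
        if not np.all(np.isfinite(self.per_repetition)):
            raise ValueError("non-finite performance values")

    @property
    def mean(self) -> float:
        return float(self.per_repetition.mean())


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def classify_nuclei(
    G_group,
    labels: AtlasLabels,
    k_folds: int = 5,
    repetitions: int = 20,
    seed: int = 0,
) -> PredictionReport:
    """Stratified k-fold CV accuracy of LDA on group gradient coordinates.

    Fold splits are re-randomized each repetition from spawned sub-seeds.
    No confound adjustment is applied.
    """
    x = G_group.gradients if hasattr(G_group, "gradients") else np.asarray(G_group)
    y = labels.labels
    keep = labels.foreground
    x, y = x[keep], y[keep]
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_folds:
        small = classes[counts < k_folds].tolist()
        raise ValueError(
            f"classes {small} have fewer members than k_folds={k_folds}"
        )
    sub_seeds = _spawn_seeds(seed, repetitions)
    accs = np.empty(repetitions)
    for rep, s in enumerate(sub_seeds):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=s % 2**32)
        correct = 0
        for train, test in skf.split(x, y):
            lda = LinearDiscriminantAnalysis()
            lda.fit(x[train], y[train])
            correct += int(np.sum(lda.predict(x[test]) == y[test]))
        accs[rep] = correct / len(y)
    return PredictionReport(per_repetition=accs, metric="accuracy", sub_seeds=sub_seeds)


def chance_accuracy(
    labels: AtlasLabels,
    G_group,
    n_perm: int = 100,
    seed: int = 0,
    k_folds: int = 5,
) -> tuple[float, np.ndarray]:
    """Permutation chance level for nucleus classification.

    Each iteration permutes the label vector and re-runs a single
    repetition of the CV classifier; the chance level is the mean of the
    null accuracies.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    perm_seeds = _spawn_seeds(seed + 1, n_perm)
    null = np.empty(n_perm)
    base = labels.labels.copy()
    for b in range(n_perm):
        shuffled = base.copy()
        fg = labels.foreground
        shuffled[fg] = rng.permutation(base[fg])
        rep = classify_nuclei(
            G_group,
            AtlasLabels(shuffled, names=labels.names),
            k_folds=k_folds,
            repetitions=1,
            seed=perm_seeds[b],
        )
        null[b] = rep.per_repetition[0]
    return float(null.mean()), null


def subject_gradient_features(gradient_sets: list) -> np.ndarray:
    """Stack per-subject gradients into a subject x (m*g) feature matrix,
    z-scored within subject across all features."""
    rows = []
    for gs in gradient_sets:
        v = (gs.gradients if hasattr(gs, "gradients") else np.asarray(gs)).ravel()
        v = (v - v.mean()) / v.std()
        rows.append(v)
    return np.vstack(rows)


def lasso_predict(
    features: np.ndarray,
    y: np.ndarray,
    outer: int = 10,
    inner: int = 10,
    repetitions: int = 20,
    seed: int = 0,
    n_alphas: int = 50,
    eps: float = 1e-4,
    min_subjects: int = 30,
    pooling: str = "per_fold",
) -> PredictionReport:
    """Nested-CV LASSO phenotype prediction.

    The inner ``inner``-fold loop selects the L1 penalty by minimum mean
    squared error over a log-spaced grid of ``n_alphas`` values spanning
    the data-driven maximum down to ``eps`` times it; the outer loop
    produces held-out predictions.  Per-repetition performance is the
    Spearman rho between held-out predictions and the true phenotype:
    with ``pooling="per_fold"`` (default) rho is computed per outer fold
    and averaged, with constant-prediction folds (fully shrunk model)
    contributing 0; ``pooling="concatenate"`` pools all held-out
    predictions first, which carries a negative fold-intercept bias under
    the null.  The returned weight map is the mean coefficient vector over
    all outer folds and repetitions.
    """
    if pooling not in ("per_fold", "concatenate"):
        raise ValueError(f"unknown pooling {pooling!r}")
    x = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    n_dropped = int(np.sum(~keep))
    x, y = x[keep], y[keep]
    n = len(y)
    if n < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects, got {n}")
    if np.std(y) == 0:
        raise ValueError("constant phenotype cannot be predicted")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")

    sub_seeds = _spawn_seeds(seed, repetitions)
    rhos = np.empty(repetitions)
    weights = np.zeros(x.shape[1])
    n_models = 0
    fold_log = []
    for rep, s in enumerate(sub_seeds):
        okf = KFold(n_splits=outer, shuffle=True, random_state=s % 2**32)
        preds = np.empty(n)
        fold_rhos = []
        for fold_i, (train, test) in enumerate(okf.split(x)):
            ikf = KFold(
                n_splits=inner, shuffle=True, random_state=(s + fold_i + 1) % 2**32
            )
            model = LassoCV(
                alphas=n_alphas,
                eps=eps,
                cv=ikf,
                max_iter=5000,
                tol=1e-4,
            )
            model.fit(x[train], y[train])
            preds[test] = model.predict(x[test])
            if pooling == "per_fold":
                if np.ptp(preds[test]) == 0:
                    fold_rhos.append(0.0)  # fully shrunk: no rank structure
                else:
                    fold_rhos.append(
                        stats.spearmanr(y[test], preds[test]).statistic
                    )
            weights += model.coef_
            n_models += 1
            fold_log.append(
                {
                    "repetition": rep,
                    "outer_fold": fold_i,
                    "test_index": test.tolist(),
                    "alpha": float(model.alpha_),
                }
            )
        if pooling == "per_fold":
            rhos[rep] = float(np.mean(fold_rhos))
        else:
            rhos[rep] = stats.spearmanr(y, preds).statistic
    report = PredictionReport(
        per_repetition=rhos,
        metric="spearman_rho",
        weight_map=weights / n_models,
        sub_seeds=sub_seeds,
        fold_log=fold_log,
    )
    report.n_dropped_subjects = n_dropped
    return report


def significance_summary(
    per_rep_rho: np.ndarray,
    n_subjects: int,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> float:
    """Fraction of repetitions with a significant positive correlation.

    Per repetition, a one-sided p-value for rho > 0 is computed with the
    t approximation ``t = rho * sqrt((n-2)/(1-rho^2))``; significance is
    assessed at ``alpha`` after Bonferroni correction over
    ``n_comparisons``.
    """
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    rho = np.asarray(per_rep_rho, dtype=float)
    rho = np.clip(rho, -0.999999, 0.999999)
    t = rho * np.sqrt((n_subjects - 2) / (1.0 - rho**2))
    p = stats.t.sf(t, df=n_subjects - 2)
    p_corr = np.minimum(p * n_comparisons, 1.0)
    sig = (p_corr < alpha) & (rho > 0)
    return float(np.mean(sig))


def nucleus_contribution(
    weight_map: np.ndarray, labels: AtlasLabels
) -> dict[int, float]:
    """Per-nucleus share of the prediction weights.

    Mean absolute weight across each nucleus's voxels and gradients,
    normalized to sum to 1 over non-empty nuclei.  Empty nuclei are
    excluded.
    """
    w = np.asarray(weight_map, dtype=float)
    if w.ndim == 1:
        raise ValueError("weight_map must be voxels x gradients")
    if w.shape[0] != len(labels.labels):
        raise ValueError("weight map and labels must share voxel support")
    raw = {}
    for lab in np.unique(labels.labels):
        if lab == 0:
            continue
        mask = labels.labels == lab
        if not mask.any():
            continue
        raw[int(lab)] = float(np.abs(w[mask]).mean())
    total = sum(raw.values())
    if total == 0:
        return {k: 0.0 for k in raw}
    return {k: v / total for k, v in raw.items()}


def weight_consistency(weight_map_a: np.ndarray, weight_map_b: np.ndarray) -> float:
    """Spearman correlation between two vectorized weight maps."""
    a = np.asarray(weight_map_a, dtype=float).ravel()
    b = np.asarray(weight_map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("weight maps must share support")
    if np.all(a == 0) or np.all(b == 0):
        raise ValueError("all-zero weight map has no rank structure")
    return float(stats.spearmanr(a, b).statistic)
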