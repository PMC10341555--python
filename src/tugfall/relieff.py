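"""Feature ranking: from-scratch Relief-F and tree-ensemble importance.

Relief-F iteratively samples a subject, finds its nearest hits (same
class) and nearest misses (each other class) under Manhattan distance
over min-max-scaled features, and moves each feature weight down for
hits and up for prior-weighted misses, with every update divided by the
sample pair's distance and the iteration budget.

The extremely-randomized-trees importance is delegated to scikit-learn
behind the same ranking contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

__all__ = [
    "FeatureMatrix",
    "RelieffParams",
    "RankedFeatures",
    "relieff_weights",
    "etc_importance",
    "top_k",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Imputed feature matrix with aligned class labels and names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError(f"y length {y.shape} does not match {X.shape[0]} rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries; impute before ranking")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        names = tuple(self.feature_names)
        if len(names) != X.shape[1]:
            raise ValueError(
                f"{len(names)} feature names for {X.shape[1]} columns"
            )
        object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RelieffParams:
    """k nearest neighbours per class, iteration budget, and RNG seed.

    ``m_iters=None`` means one iteration per sample (the classic
    ``m = n`` usage).  ``k`` is clipped to ``class size - 1`` when a
    class is too small (with a warning).
    """

    k: int = 10
    m_iters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.m_iters is not None and self.m_iters < 1:
            raise ValueError(f"m_iters must be >= 1, got {self.m_iters}")


@dataclass(frozen=True)
class RankedFeatures:
    """Per-feature weights and the deterministic descending ranking."""

    weights: np.ndarray
    ranking: np.ndarray  # feature indices, best first
    feature_names: tuple
    selector: str

    def top_names(self, k: int) -> list:
        return [self.feature_names[i] for i in self.ranking[:k]]


def _rank_descending(weights: np.ndarray) -> np.ndarray:
    # ties broken by lower feature index
    return np.lexsort((np.arange(weights.size), -weights))


def relieff_weights(data: FeatureMatrix, params: RelieffParams = RelieffParams()) -> RankedFeatures:
    """Relief-F feature weights.

    Sample indices for the iterations are drawn up-front as
    ``default_rng(seed).integers(0, n_samples, size=m_iters)`` (uniform
    with replacement), which fixes the update sequence for a given seed.
    Feature differences are normalised by the feature's min-max span
    (zero-span features contribute nothing); each neighbour update is
    ``delta / (m * d)`` with ``d`` the Manhattan distance between the
    scaled sample pair, and is skipped for duplicate samples (``d = 0``).
    Miss updates carry the prior weight ``p(class_miss) / (1 -
    p(class_sample))``.  Neighbour ties break toward the lower sample
    index; ranking ties toward the lower feature index.
    """
    X, y = data.X, data.y
    n, p = X.shape
    m = params.m_iters if params.m_iters is not None else n

    span = X.max(axis=0) - X.min(axis=0)
    nonzero = span > 0
    Xs = np.zeros_like(X)
    Xs[:, nonzero] = (X[:, nonzero] - X[:, nonzero].min(axis=0)) / span[nonzero]

    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    if max(counts) < 2 and len(classes) == 2:
        raise ValueError("each class needs at least 2 members for hits")
    clipped = params.k > min(counts) - 1
    if clipped:
        warnings.warn(
            f"k={params.k} clipped to class size - 1 (smallest class has {min(counts)})",
            stacklevel=2,
        )

    rng = np.random.default_rng(params.seed)
    chosen = rng.integers(0, n, size=m)

    weights = np.zeros(p)
    for r in chosen:
        dist = np.abs(Xs - Xs[r]).sum(axis=1)
        for c in classes:
            pool = np.flatnonzero((y == c) & (np.arange(n) != r))
            k_eff = min(params.k, pool.size)
            if k_eff < 1:
                continue
            order = np.lexsort((pool, dist[pool]))
            for q in pool[order[:k_eff]]:
                d_rq = dist[q]
                if d_rq == 0.0:
                    continue
                delta = np.abs(Xs[r] - Xs[q])
                if c == y[r]:
                    weights -= delta / (m * d_rq)
                else:
                    factor = priors[c] / (1.0 - priors[y[r]])
                    weights += factor * delta / (m * d_rq)

    return RankedFeatures(
        weights=weights,
        ranking=_rank_descending(weights),
        feature_names=data.feature_names,
        selector="relieff",
    )


def etc_importance(data: FeatureMatrix, n_trees: int = 100, seed: int = 0) -> RankedFeatures:
    """Impurity-decrease importances of an extremely-randomized-trees
    ensemble, normalised to sum to 1."""
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    model = ExtraTreesClassifier(n_estimators=n_trees, random_state=int(seed))
    model.fit(data.X, data.y)
    importances = np.asarray(model.feature_importances_, dtype=float)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return RankedFeatures(
        weights=importances,
        ranking=_rank_descending(importances),
        feature_names=data.feature_names,
        selector="etc",
    )


def top_k(ranked: RankedFeatures, k: int) -> list:
    """First ``k`` feature names of the ranking."""
    if not 1 <= k <= len(ranked.feature_names):
        raise ValueError(f"k must be in [1, {len(ranked.feature_names)}], got {k}")
    return ranked.top_names(k)
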