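"""Feature relevance ranking, top-fraction selection and class screening.

ReliefF weighs each feature by how well it separates nearest neighbours of
different classes while staying stable within a class: for each sampled
instance the k nearest hits (same class) pull the weight down by the
feature's hit differences, and the k nearest misses of every other class
(prior-weighted) push it up. Selection keeps the top fraction of the
ranking. A per-feature Mann-Whitney U screen with Benjamini-Hochberg
correction quantifies univariate class differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FeatureMatrix:
    """Cohort-level feature values with names and per-sample class labels."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 0:
            self.values = self.values.reshape(0, len(self.names))
        self.labels = np.asarray(self.labels, dtype=str)
        if self.values.shape[1] != len(self.names):
            raise ValueError("values width must match number of names")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("one label per sample required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        return df

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None):
        values = self.values
        labels = self.labels
        names = self.names
        if rows is not None:
            values = values[rows]
            labels = labels[rows]
        if cols is not None:
            values = values[:, cols]
            names = [names[i] for i in np.asarray(cols)]
        return FeatureMatrix(values=values, names=list(names), labels=labels)


@dataclass
class SelectionResult:
    """Ranked feature weights and the retained prefix."""

    weights: np.ndarray
    ranking: np.ndarray
    kept: np.ndarray
    fraction: float


def relieff_weights(
    X: FeatureMatrix,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """ReliefF relevance weights, one per feature.

    Features are internally max-min scaled to [0, 1] so the diff function
    is scale-free; constant features get weight exactly 0. If
    ``n_iterations`` is None or >= n_samples every sample is visited once
    in order (the deterministic full pass); otherwise ``n_iterations``
    distinct samples are drawn with the given seed. Distances are Euclidean
    in the scaled space. Miss contributions from each other class are
    weighted by that class's prior probability (renormalized over the
    non-self classes), the standard multi-class extension.
    """
    values = X.values
    labels = X.labels
    n, d = values.shape
    classes = np.unique(labels)
    y = np.searchsorted(classes, labels)
    counts = np.bincount(y, minlength=classes.size)
    if np.any(counts < k_neighbors + 1):
        small = classes[counts < k_neighbors + 1]
        raise ValueError(
            f"every class needs >= k_neighbors + 1 = {k_neighbors + 1} samples; "
            f"too small: {small.tolist()}"
        )

    span = values.max(axis=0) - values.min(axis=0)
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (values - values.min(axis=0)) / safe_span
    scaled[:, constant] = 0.0
    priors = counts / n

    if n_iterations is None or n_iterations >= n:
        chosen = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(n, size=n_iterations, replace=False))
    n_it = chosen.size

    # full pairwise distances; cohorts here are small (hundreds of samples)
    dists = np.sqrt(((scaled[:, None, :] - scaled[None, :, :]) ** 2).sum(axis=2))
    weights = np.zeros(d)
    for i in chosen:
        order = np.argsort(dists[i], kind="stable")
        same = order[(y[order] == y[i]) & (order != i)][:k_neighbors]
        weights -= np.abs(scaled[i] - scaled[same]).sum(axis=0) / (n_it * k_neighbors)
        for c in range(classes.size):
            if c == y[i]:
                continue
            miss = order[y[order] == c][:k_neighbors]
            w_c = priors[c] / (1.0 - priors[y[i]])
            weights += w_c * np.abs(scaled[i] - scaled[miss]).sum(axis=0) / (n_it * k_neighbors)
    weights[constant] = 0.0
    return weights


def select_top(weights: np.ndarray, fraction: float) -> SelectionResult:
    """Keep the top ``max(1, round(fraction * n))`` features by weight.

    Sort is descending by weight with ties broken by ascending feature
    index (stable and reproducible across calls).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty weights")
    if not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ranking = np.argsort(-weights, kind="stable")
    n_keep = max(1, int(np.floor(fraction * weights.size + 0.5)))
    return SelectionResult(
        weights=weights, ranking=ranking, kept=ranking[:n_keep], fraction=fraction
    )


def mann_whitney_screen(X: FeatureMatrix) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per feature between the two classes.

    Uses exact enumeration when both groups have <= 8 samples and no ties,
    otherwise the tie-corrected normal approximation. Returns a DataFrame
    with columns ``name``, ``U``, ``p_value`` and Benjamini-Hochberg
    ``q_value``.
    """
    classes = X.classes
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    g0 = X.values[X.labels == classes[0]]
    g1 = X.values[X.labels == classes[1]]
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    u_stats = np.empty(X.n_features)
    p_values = np.empty(X.n_features)
    for j in range(X.n_features):
        a, b = g0[:, j], g1[:, j]
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:  # all values tied: no rank information
            u_stats[j] = a.size * b.size / 2.0
            p_values[j] = 1.0
            continue
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u_stats[j] = res.statistic
        p_values[j] = res.pvalue
    q_values = multipletests(p_values, method="fdr_bh")[1]
    return pd.DataFrame(
        {"name": X.names, "U": u_stats, "p_value": p_values, "q_value": q_values}
    )
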