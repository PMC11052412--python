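"""Resampling-based feature selection: LBFS and PBFS.

Both procedures address class imbalance by down-sampling the majority class
to the minority size in every repetition and tallying, over many repetitions,
which five features come out on top.

LBFS (LDA-based): per repetition, a stratified 70/30 train/validation split;
for each feature alone a one-dimensional LDA threshold is fit on the training
part and the feature is scored by its validation *sensitivity* (recall of the
non-survivor class); the five most sensitive features are tallied.

PBFS (PCA-based): per repetition, features are standardized and a PCA is
computed; each feature is scored by the mean absolute Pearson correlation
between its column and the first four principal-component score vectors, and
the five highest-scoring features are tallied. The labels enter only through
the down-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

DEFAULT_N_REPS = 1000
TOP_K = 5
TRAIN_FRACTION = 0.7
DEFAULT_N_PCS = 4


@dataclass
class SelectionTally:
    """Per-feature counts of top-5 membership over repetitions."""

    method: str
    counts: dict[str, int]
    n_reps: int
    feature_order: list[str]
    explained_variance: float | None = None  # PBFS: mean over reps
    top5: list[str] = field(init=False)

    def __post_init__(self) -> None:
        order = {name: i for i, name in enumerate(self.feature_order)}
        ranked = sorted(self.counts, key=lambda f: (-self.counts[f], order[f]))
        self.top5 = ranked[:TOP_K]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.counts), "count": list(self.counts.values())}
        ).sort_values("count", ascending=False, ignore_index=True)


def lda_threshold_1d(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """One-dimensional LDA with equal priors and shared within-class variance.

    Returns (threshold, orientation); orientation is +1 if values above the
    threshold are classified as died (class 1), −1 otherwise. With a shared
    variance and equal priors the boundary is the midpoint of the class means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both classes must be present")
    m0, m1 = float(np.mean(x0)), float(np.mean(x1))
    within = np.concatenate([x0 - m0, x1 - m1])
    if np.all(within == 0) and m0 == m1:
        raise ValueError("degenerate feature: zero within-class variance, equal means")
    threshold = 0.5 * (m0 + m1)
    orientation = 1 if m1 >= m0 else -1
    return threshold, orientation


def _predict_1d(x: np.ndarray, threshold: float, orientation: int) -> np.ndarray:
    return (orientation * (np.asarray(x, dtype=float) - threshold) > 0).astype(int)


def _downsample_majority(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of all minority subjects plus an equal-size majority draw."""
    classes, counts = np.unique(y, return_counts=True)
    minority = classes[np.argmin(counts)]
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y != minority)
    pick = rng.choice(idx_maj, size=len(idx_min), replace=False)
    return np.sort(np.concatenate([idx_min, pick]))


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split (both classes in both parts)."""
    train, val = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        val.extend(idx[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(val))


def _rank_top5(
    scores: dict[str, float],
    feature_order: list[str],
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Five best-scoring features; within-repetition ties broken at random.

    Random (seed-derived) tie-breaking keeps the all-noise tally uniform —
    a fixed-order tie-break would systematically favour early features when
    scores are discrete (e.g. validation sensitivities).
    """
    if rng is None:
        pos = {name: i for i, name in enumerate(feature_order)}
        jitter = {name: pos[name] for name in scores}
    else:
        draws = rng.random(len(scores))
        jitter = {name: draws[i] for i, name in enumerate(scores)}
    ranked = sorted(scores, key=lambda f: (-scores[f], jitter[f]))
    return ranked[:TOP_K]


def lbfs(
    X: pd.DataFrame,
    y: np.ndarray,
    n_reps: int = DEFAULT_N_REPS,
    train_frac: float = TRAIN_FRACTION,
    seed: int = 0,
) -> SelectionTally:
    """LDA-based feature selection over down-sampled repetitions."""
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need >= 2 subjects per class")
    features = list(X.columns)
    counts = {name: 0 for name in features}
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    for _ in range(n_reps):
        sub = _downsample_majority(y, rng)
        y_sub = y[sub]
        tr, va = _stratified_split(y_sub, train_frac, rng)
        scores = {}
        for j, name in enumerate(features):
            col = Xv[sub, j]
            try:
                thr, orient = lda_threshold_1d(col[tr], y_sub[tr])
            except ValueError:
                scores[name] = -np.inf
                continue
            pred = _predict_1d(col[va], thr, orient)
            died = y_sub[va] == 1
            scores[name] = float(np.mean(pred[died] == 1))  # sensitivity
        for name in _rank_top5(scores, features, rng):
            counts[name] += 1
    return SelectionTally(method="LBFS", counts=counts, n_reps=n_reps, feature_order=features)


def pbfs_scores(Z: np.ndarray, n_pcs: int = DEFAULT_N_PCS) -> tuple[np.ndarray, float]:
    """One repetition's PBFS feature scores on standardized data.

    Returns (mean |Pearson r| between each feature column and the first
    ``n_pcs`` principal-component score vectors, explained variance of those
    components). Identical columns receive identical scores by construction.
    """
    k = min(n_pcs, np.linalg.matrix_rank(Z))
    pca = PCA(n_components=k)
    scores_mat = pca.fit_transform(Z)
    sc = (scores_mat - scores_mat.mean(axis=0)) / scores_mat.std(axis=0)
    r = np.abs(Z.T @ sc) / len(Z)  # features × k
    return r.mean(axis=1), float(np.sum(pca.explained_variance_ratio_))


def pbfs(
    X: pd.DataFrame,
    y: np.ndarray,
    n_reps: int = DEFAULT_N_REPS,
    n_pcs: int = DEFAULT_N_PCS,
    seed: int = 0,
) -> SelectionTally:
    """PCA-based feature selection over down-sampled repetitions."""
    y = np.asarray(y, dtype=int)
    features = list(X.columns)
    counts = {name: 0 for name in features}
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    ev = []
    for _ in range(n_reps):
        sub = _downsample_majority(y, rng)
        if len(sub) < n_pcs + 1:
            raise ValueError("need more than n_pcs subjects after down-sampling")
        Z = Xv[sub]
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd
        r_mean, evr = pbfs_scores(Z, n_pcs)
        ev.append(evr)
        mean_r = {name: float(r_mean[j]) for j, name in enumerate(features)}
        for name in _rank_top5(mean_r, features, rng):
            counts[name] += 1
    return SelectionTally(
        method="PBFS",
        counts=counts,
        n_reps=n_reps,
        feature_order=features,
        explained_variance=float(np.mean(ev)),
    )
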