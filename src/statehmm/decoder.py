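"""Performance-state decoding from physiological features.

A cross-validated RBF-kernel support vector machine discriminates trials
of the optimal state from trials of a disengaged or sub-optimal state,
using six features: the three pre-stimulus measures (pupil, face,
locomotion) and their 10-trial standard deviations (or, in the
movement-index variant, pupil and movement-index values plus their SDs).
Significance is calibrated by z-scoring the empirical test accuracy
against classifiers trained on label-permuted training sets; feature
contributions are probed by shuffling the complementary feature subset
within the training folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .glmhmm import ValidationError

FEATURE_GROUPS = {
    "pupil": ("pupil", "pupil_sd10"),
    "face": ("face", "face_sd10"),
    "locomotion": ("locomotion", "locomotion_sd10"),
    "movement_index": ("movement_index", "movement_index_sd10"),
}
DEFAULT_FEATURES = ("pupil", "face", "locomotion")
MIN_CLASS_TRIALS = 25


@dataclass
class DecoderResult:
    """Cross-validated decoding accuracy with its permutation calibration."""

    comparison: tuple  # (positive class, negative class)
    accuracy: float
    z_score: float
    shuffle_accuracies: np.ndarray
    n_per_class: int
    feature_names: list
    fold_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise ValidationError("accuracy must lie in [0, 1]")


def _feature_columns(groups) -> list:
    cols = []
    for g in groups:
        if g not in FEATURE_GROUPS:
            raise ValidationError(f"unknown feature group {g!r}")
        cols.extend(FEATURE_GROUPS[g])
    return cols


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise distance: gamma = 1 / (2 m^2)."""
    n = len(X)
    sub = X if n <= 500 else X[:: max(1, n // 500)]
    m = float(np.median(pdist(sub)))
    return 1.0 / (2 * m * m) if m > 0 else 1.0


def _balanced_subsample(X, y, rng):
    classes = np.unique(y)
    n_min = min(int((y == c).sum()) for c in classes)
    keep = np.concatenate(
        [rng.choice(np.flatnonzero(y == c), size=n_min, replace=False) for c in classes]
    )
    keep.sort()
    return X[keep], y[keep], n_min


def _cv_accuracy(X, y, folds, C, rng, shuffle_train_labels=False, shuffle_cols=None):
    """Mean test accuracy over stratified folds; all standardization,
    label permutation and feature shuffling touch the training fold only."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    accs = []
    for train, test in skf.split(X, y):
        Xtr, Xte = X[train].copy(), X[test]
        ytr = y[train].copy()
        if shuffle_train_labels:
            ytr = ytr[rng.permutation(len(ytr))]
        if shuffle_cols is not None and len(shuffle_cols):
            for c in shuffle_cols:
                Xtr[:, c] = Xtr[rng.permutation(len(Xtr)), c]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr_s, Xte_s = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = SVC(C=C, kernel="rbf", gamma=_median_heuristic_gamma(Xtr_s))
        clf.fit(Xtr_s, ytr)
        accs.append(float(np.mean(clf.predict(Xte_s) == y[test])))
    return np.asarray(accs)


def _prepare(features, stereotype_labels, comparison, feature_groups, rng):
    pos, neg = comparison
    cols = _feature_columns(feature_groups)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValidationError(f"feature column(s) missing: {missing}")
    lab = np.asarray(stereotype_labels, dtype=object)
    X_all = features[cols].to_numpy(dtype=float)
    complete = np.isfinite(X_all).all(axis=1)
    sel = complete & np.isin(lab, [pos, neg])
    X, y = X_all[sel], (lab[sel] == pos).astype(int)
    for c, name in ((1, pos), (0, neg)):
        if int((y == c).sum()) < MIN_CLASS_TRIALS:
            warnings.warn(
                f"class {name!r} has fewer than {MIN_CLASS_TRIALS} complete trials; skipping",
                stacklevel=3,
            )
            return None, None, cols
    Xb, yb, n_min = _balanced_subsample(X, y, rng)
    return (Xb, yb, n_min), cols, cols


def decode_state(
    features,
    stereotype_labels,
    comparison=("optimal", "disengaged"),
    feature_groups=DEFAULT_FEATURES,
    n_shuffles: int = 1000,
    folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> DecoderResult | None:
    """Decode performance state from pre-stimulus features.

    Classes are balanced by seeded subsampling to the minority count;
    features are standardized with training-fold statistics; the RBF
    kernel width comes from the median pairwise distance heuristic
    (C = 1 by default). The z-score compares the empirical mean test
    accuracy with ``n_shuffles`` classifiers whose training labels were
    permuted. Returns None (with a warning) when either class has fewer
    than 25 complete trials.
    """
    rng = np.random.default_rng(seed)
    prep, cols, _ = _prepare(features, stereotype_labels, comparison, feature_groups, rng)
    if prep is None:
        return None
    Xb, yb, n_min = prep
    fold_acc = _cv_accuracy(Xb, yb, folds, C, np.random.default_rng(rng.integers(2**31)))
    acc = float(fold_acc.mean())
    sh = np.array(
        [
            _cv_accuracy(
                Xb, yb, folds, C, np.random.default_rng(rng.integers(2**31)),
                shuffle_train_labels=True,
            ).mean()
            for _ in range(n_shuffles)
        ]
    )
    sd = sh.std(ddof=1)
    z = (acc - sh.mean()) / sd if sd > 0 else float("inf") if acc > sh.mean() else 0.0
    return DecoderResult(
        comparison=tuple(comparison),
        accuracy=acc,
        z_score=float(z),
        shuffle_accuracies=sh,
        n_per_class=n_min,
        feature_names=cols,
        fold_accuracies=fold_acc,
    )


def feature_contribution(
    features,
    stereotype_labels,
    comparison=("optimal", "disengaged"),
    keep_set=("pupil",),
    feature_groups=DEFAULT_FEATURES,
    n_shuffles: int = 1000,
    folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> DecoderResult | None:
    """Decoding with every feature group outside ``keep_set`` shuffled
    across trials within the training folds (test folds untouched).

    Each group name stands for its value + 10-trial-SD pair. With
    ``keep_set`` equal to all groups this reduces exactly to
    :func:`decode_state`.
    """
    keep_set = tuple(keep_set)
    if not keep_set:
        raise ValidationError("keep_set must not be empty")
    bad = set(keep_set) - set(FEATURE_GROUPS)
    if bad:
        raise ValidationError(f"unknown feature group(s) in keep_set: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    prep, cols, _ = _prepare(features, stereotype_labels, comparison, feature_groups, rng)
    if prep is None:
        return None
    Xb, yb, n_min = prep
    keep_cols = set(_feature_columns([g for g in feature_groups if g in keep_set]))
    shuffle_cols = [i for i, c in enumerate(cols) if c not in keep_cols]
    fold_acc = _cv_accuracy(
        Xb, yb, folds, C, np.random.default_rng(rng.integers(2**31)), shuffle_cols=shuffle_cols
    )
    acc = float(fold_acc.mean())
    sh = np.array(
        [
            _cv_accuracy(
                Xb, yb, folds, C, np.random.default_rng(rng.integers(2**31)),
                shuffle_train_labels=True, shuffle_cols=shuffle_cols,
            ).mean()
            for _ in range(n_shuffles)
        ]
    )
    sd = sh.std(ddof=1)
    z = (acc - sh.mean()) / sd if sd > 0 else float("inf") if acc > sh.mean() else 0.0
    return DecoderResult(
        comparison=tuple(comparison),
        accuracy=acc,
        z_score=float(z),
        shuffle_accuracies=sh,
        n_per_class=n_min,
        feature_names=[c for c in cols if c in keep_cols],
        fold_accuracies=fold_acc,
    )
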