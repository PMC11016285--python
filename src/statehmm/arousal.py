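"""Arousal/movement analyses of performance states.

Implements the inverted-U analyses: binned state probabilities along an
arousal measure, the per-subject optimal pupil diameter (argmax of a
cross-validated polynomial fit of optimal-state probability versus
pupil), trial alignment to the optimal pupil, quadratic regressions of
state probability on measures (with variability and interaction terms),
state-conditioned pupil-movement correlations, and the change in
10-trial variability around entries into and exits from the optimal
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .annotate import INDETERMINATE, StateLabelSequence, StereotypeMap
from .glmhmm import ValidationError


@dataclass
class BinnedStateProb:
    """State probabilities in bins of one measure."""

    measure: str
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray
    probs: pd.DataFrame  # rows = bins, columns = stereotypes + indeterminate
    min_count: int = 20

    def __post_init__(self) -> None:
        occupied = self.counts > 0
        if not np.allclose(self.probs.to_numpy()[occupied].sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("per-bin probabilities must sum to 1")

    @property
    def usable(self) -> np.ndarray:
        return self.counts >= self.min_count


def binned_state_prob(
    features: pd.DataFrame,
    stereotype_labels: np.ndarray,
    measure: str,
    n_bins: int = 10,
    min_count: int = 20,
) -> BinnedStateProb:
    """Proportion of trials in each performance state per measure bin.

    Bins are equal-count (quantile) bins of the measure's per-trial
    values; trials with a missing measure value are dropped. Bins with
    fewer than ``min_count`` trials are reported but flagged unusable for
    downstream fits.
    """
    if measure not in features.columns:
        raise ValidationError(f"feature column {measure!r} not present")
    x = features[measure].to_numpy(dtype=float)
    lab = np.asarray(stereotype_labels, dtype=object)
    ok = np.isfinite(x)
    x, lab = x[ok], lab[ok]
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValidationError("measure has too few distinct values to bin")
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    names = sorted(set(lab))
    rows, counts, centers = [], [], []
    for b in range(len(edges) - 1):
        in_bin = which == b
        n = int(in_bin.sum())
        counts.append(n)
        centers.append(float(x[in_bin].mean()) if n else 0.5 * (edges[b] + edges[b + 1]))
        rows.append({s: (float(np.mean(lab[in_bin] == s)) if n else 0.0) for s in names})
    return BinnedStateProb(
        measure=measure,
        bin_edges=edges,
        bin_centers=np.asarray(centers),
        counts=np.asarray(counts),
        probs=pd.DataFrame(rows),
        min_count=min_count,
    )


def stationary_mask(features: pd.DataFrame, threshold: float = 0.01) -> np.ndarray:
    """Trials where the animal was stationary before the stimulus
    (pre-stimulus locomotion speed < ``threshold`` m/s); used to check
    that pupil relationships survive without locomotion."""
    loco = features["locomotion"].to_numpy(dtype=float)
    return np.isfinite(loco) & (loco < threshold)


# ---------------------------------------------------------------------------
# Optimal pupil


@dataclass
class OptimalPupilFit:
    """Polynomial fit of optimal-state probability versus pupil diameter."""

    degree: int
    coefficients: np.ndarray  # numpy polyfit order (highest degree first)
    optimal_diameter: float
    cv_r2_by_degree: dict
    data_range: tuple

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def _cv_r2(x, y, w, degree, folds, rng, n_repeats=5):
    """Weighted CV r² for a polynomial degree, pooled over held-out bins.

    Residuals are pooled across folds into one r² (per-fold r² on 2 bins
    is meaningless), test predictions are clipped to [0, 1] (the target
    is a probability, and high-degree polynomials extrapolate wildly when
    a held-out bin sits at the edge of the range), and the whole CV is
    averaged over several random fold assignments.
    """
    ybar = np.average(y, weights=w)
    denom_all = np.sum(w * (y - ybar) ** 2)
    if denom_all <= 0:
        return 0.0
    scores = []
    for _ in range(n_repeats):
        order = rng.permutation(len(x))
        resid2 = 0.0
        for f in range(folds):
            test = order[f::folds]
            train = np.setdiff1d(order, test)
            if len(train) <= degree or len(test) == 0:
                return -np.inf
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                coef = np.polyfit(x[train], y[train], degree, w=np.sqrt(w[train]))
            pred = np.clip(np.polyval(coef, x[test]), 0.0, 1.0)
            resid2 += np.sum(w[test] * (y[test] - pred) ** 2)
        scores.append(1.0 - resid2 / denom_all)
    return float(np.mean(scores))


def fit_optimal_pupil(
    binned: BinnedStateProb,
    state: str = "optimal",
    max_degree: int = 6,
    folds: int = 5,
    elbow_fraction: float = 0.10,
    seed: int = 0,
    grid_size: int = 512,
) -> OptimalPupilFit:
    """Pick a polynomial degree by the elbow of cross-validated r² and
    return the optimal pupil diameter.

    Degrees 1..``max_degree`` are scored by 5-fold CV over usable bins
    (fits weighted by bin trial count). The elbow is the smallest degree
    whose incremental CV r² to the next degree falls below
    ``elbow_fraction`` of the total r² gain across the scan. A final
    weighted fit to all usable bins gives the fitted curve; the optimal
    diameter is its argmax restricted to the observed pupil range.
    """
    use = binned.usable & (binned.counts > 0)
    x = binned.bin_centers[use]
    y = binned.probs.loc[use, state].to_numpy(dtype=float)
    w = binned.counts[use].astype(float)
    if len(x) < 5:
        raise ValidationError(f"need at least 5 usable bins, got {len(x)}")
    rng = np.random.default_rng(seed)
    degrees = list(range(1, max_degree + 1))
    r2 = {d: _cv_r2(x, y, w, d, folds, np.random.default_rng(rng.integers(2**31))) for d in degrees}
    # Elbow on the monotone envelope of the r² curve: the smallest degree
    # after which the incremental CV gain falls below elbow_fraction of
    # the total gain across the scan.
    env = np.maximum.accumulate([r2[d] for d in degrees])
    gain = env[-1] - env[0]
    if gain <= 0:
        degree = int(degrees[int(np.argmax(env))])
    else:
        degree = degrees[-1]
        for i, d in enumerate(degrees[:-1]):
            if env[i + 1] - env[i] < elbow_fraction * gain:
                degree = d
                break
    degree = min(degree, len(x) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coef = np.polyfit(x, y, degree, w=np.sqrt(w))
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, grid_size)
    opt = float(grid[np.argmax(np.polyval(coef, grid))])
    return OptimalPupilFit(
        degree=degree,
        coefficients=coef,
        optimal_diameter=opt,
        cv_r2_by_degree=r2,
        data_range=(lo, hi),
    )


def align_to_optimal(features: pd.DataFrame, fit: OptimalPupilFit, stereotype_labels=None):
    """Per-trial signed and absolute distance from the optimal pupil.

    Returns a DataFrame with ``distance`` and ``abs_distance`` columns;
    when stereotype labels are given, also the mean |distance| per
    stereotype as a dict in ``.attrs['mean_abs_by_state']``.
    """
    d = features["pupil"].to_numpy(dtype=float) - fit.optimal_diameter
    out = pd.DataFrame({"distance": d, "abs_distance": np.abs(d)})
    if stereotype_labels is not None:
        lab = np.asarray(stereotype_labels, dtype=object)
        out.attrs["mean_abs_by_state"] = {
            s: float(np.nanmean(out["abs_distance"][lab == s]))
            for s in sorted(set(lab))
        }
    return out


# ---------------------------------------------------------------------------
# Quadratic regressions


@dataclass
class StateRegression:
    """Standardized least-squares fit of state probability on measures."""

    target: str
    coefficients: pd.Series  # named: x, x_sd10, x^2, x:y interactions, const
    cv_r2: float
    feature_means: pd.Series
    feature_sds: pd.Series


def _design_matrix(features: pd.DataFrame, measures, include_sd=True):
    cols = {}
    for m in measures:
        cols[m] = features[m].to_numpy(dtype=float)
        if include_sd:
            cols[f"{m}_sd10"] = features[f"{m}_sd10"].to_numpy(dtype=float)
    base = pd.DataFrame(cols)
    means, sds = base.mean(), base.std(ddof=0)
    z = (base - means) / sds.replace(0, np.nan)
    for m in measures:
        z[f"{m}^2"] = z[m] ** 2
    for i, a in enumerate(measures):
        for b_ in measures[i + 1 :]:
            z[f"{a}:{b_}"] = z[a] * z[b_]
    return z, means, sds


def quadratic_state_regression(
    features: pd.DataFrame,
    state_prob: np.ndarray,
    measures=("pupil", "face", "locomotion"),
    include_sd: bool = True,
    folds: int = 5,
    seed: int = 0,
    target_name: str = "optimal",
) -> StateRegression:
    """Regress a state's posterior probability on standardized measure
    values, their 10-trial SDs, squared values, and pairwise interactions.

    The target is the (soft) per-trial posterior probability of the
    stereotype. Returns the coefficients of the full-data fit and the
    5-fold cross-validated r².
    """
    measures = list(measures)
    y = np.asarray(state_prob, dtype=float)
    X, means, sds = _design_matrix(features, measures, include_sd=include_sd)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    Xo, yo = X.to_numpy()[ok], y[ok]
    if len(yo) <= X.shape[1] + 1:
        raise ValidationError("not enough complete trials for the regression")
    M = np.column_stack([Xo, np.ones(len(Xo))])
    coef, *_ = np.linalg.lstsq(M, yo, rcond=None)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(yo))
    scores = []
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        cf, *_ = np.linalg.lstsq(M[train], yo[train], rcond=None)
        resid = yo[test] - M[test] @ cf
        denom = np.sum((yo[test] - yo[train].mean()) ** 2)
        scores.append(1.0 - np.sum(resid**2) / denom if denom > 0 else 0.0)
    names = list(X.columns) + ["const"]
    return StateRegression(
        target=target_name,
        coefficients=pd.Series(coef, index=names),
        cv_r2=float(np.mean(scores)),
        feature_means=means,
        feature_sds=sds,
    )


# ---------------------------------------------------------------------------
# State-conditioned correlation and transition-aligned variability


def state_conditioned_correlation(
    features: pd.DataFrame,
    stereotype_labels,
    x: str = "pupil",
    y: str = "movement_index",
    min_trials: int = 10,
) -> dict:
    """Pearson correlation between two per-trial measures within each
    stereotype (NaN with fewer than ``min_trials`` complete trials)."""
    lab = np.asarray(stereotype_labels, dtype=object)
    xv = features[x].to_numpy(dtype=float)
    yv = features[y].to_numpy(dtype=float)
    out = {}
    for s in sorted(set(lab)):
        sel = (lab == s) & np.isfinite(xv) & np.isfinite(yv)
        if sel.sum() < min_trials:
            out[s] = float("nan")
            continue
        out[s] = float(pearsonr(xv[sel], yv[sel]).statistic)
    return out


def transition_aligned_variability(
    label_sequences,
    feature_frames,
    stereotypes: StereotypeMap,
    columns=("pupil_sd10", "face_sd10", "locomotion_sd10"),
    target: str = "optimal",
    window: int = 10,
) -> dict:
    """Mean change of 10-trial SDs around optimal-state entries and exits.

    For each entry into (exit from) a ``target`` epoch, the sd10 columns
    are extracted on the 2*window+1 trials centered on the transition
    trial, baselined by subtracting the value at the window start, then
    averaged across transitions (and sessions). Returns
    ``{"entry": DataFrame, "exit": DataFrame, "n_entries": int,
    "n_exits": int}`` with rows indexed by lag -window..window; empty
    (all-NaN) frames with a warning when no optimal epochs exist.
    """
    lags = np.arange(-window, window + 1)
    snips = {"entry": [], "exit": []}
    for seq, feats in zip(label_sequences, feature_frames):
        labels = seq.labels if isinstance(seq, StateLabelSequence) else np.asarray(seq)
        names = np.array(
            ["indeterminate" if l == INDETERMINATE else stereotypes.mapping[int(l)] for l in labels],
            dtype=object,
        )
        is_t = names == target
        starts = np.flatnonzero(is_t & ~np.roll(is_t, 1))
        ends = np.flatnonzero(is_t & ~np.roll(is_t, -1)) + 1
        if len(is_t) and is_t[0] and 0 in starts:
            starts = starts[starts != 0]  # session opens mid-epoch: not an entry
        if len(is_t) and is_t[-1]:
            ends = ends[ends != len(is_t)]
        F = feats[list(columns)].to_numpy(dtype=float)
        for kind, idxs in (("entry", starts), ("exit", ends)):
            for i in idxs:
                pos = i + lags
                ok = (pos >= 0) & (pos < len(F))
                snip = np.full((len(lags), len(columns)), np.nan)
                snip[ok] = F[pos[ok]]
                first = np.flatnonzero(ok)
                if len(first) == 0 or not np.all(np.isfinite(snip[first[0]])):
                    continue
                snips[kind].append(snip - snip[first[0]])
    out = {}
    for kind in ("entry", "exit"):
        if snips[kind]:
            out[kind] = pd.DataFrame(
                np.nanmean(np.stack(snips[kind]), axis=0), index=lags, columns=list(columns)
            )
        else:
            warnings.warn(f"no optimal-state {kind} transitions found", stacklevel=2)
            out[kind] = pd.DataFrame(np.nan, index=lags, columns=list(columns))
    out["n_entries"] = len(snips["entry"])
    out["n_exits"] = len(snips["exit"])
    return out
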