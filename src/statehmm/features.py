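"""Per-trial physiological features from raw traces.

Raw pupil-diameter, face-motion-energy and locomotion-speed traces are
smoothed with second-order Savitzky-Golay filters (500 ms window for
pupil, 200 ms for face and locomotion), upsampled to 1 kHz, and (pupil,
face) normalized to the session maximum. The analysis value of each
measure on a trial is the sample immediately before stimulus onset; its
short-horizon variability is the standard deviation (and coefficient of
variation) over the preceding ten trials. Face and locomotion are
combined into a single movement index by z-scoring each across all of a
subject's included trials and summing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .glmhmm import ValidationError

SG_WINDOW_MS = {"pupil": 500.0, "face": 200.0, "locomotion": 200.0}
SG_ORDER = 2
TARGET_RATE_HZ = 1000.0
MEASURES = ("pupil", "face", "locomotion")


@dataclass
class ConditionedTrace:
    """Uniform 1 kHz trace after smoothing (and optional normalization)."""

    time_s: np.ndarray
    values: np.ndarray
    measure: str
    session_max: float | None = None

    def __post_init__(self) -> None:
        dt = np.diff(self.time_s)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError("conditioned trace must have uniform spacing")


def _nan_runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs in ``mask`` (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def interpolate_gaps(time_s, values, max_gap_ms: float = 200.0):
    """Linearly fill NaN gaps strictly shorter than ``max_gap_ms``.

    Gap duration is the time between the last valid sample before and the
    first valid sample after the gap. Gaps of 200 ms or longer, and gaps
    touching either end of the trace, remain masked.
    """
    time_s = np.asarray(time_s, dtype=float)
    out = np.asarray(values, dtype=float).copy()
    for start, stop in _nan_runs(np.isnan(out)):
        if start == 0 or stop == len(out):
            continue
        span_ms = (time_s[stop] - time_s[start - 1]) * 1000.0
        if span_ms < max_gap_ms:
            out[start:stop] = np.interp(
                time_s[start:stop],
                [time_s[start - 1], time_s[stop]],
                [out[start - 1], out[stop]],
            )
    return out


def _segmentwise_savgol(values: np.ndarray, window: int) -> np.ndarray:
    """Savitzky-Golay filter applied to each valid (non-NaN) segment."""
    out = values.copy()
    for start, stop in _nan_runs(~np.isnan(values)):
        seg = values[start:stop]
        if len(seg) >= window:
            out[start:stop] = savgol_filter(seg, window, SG_ORDER)
    return out


def condition(time_s, values, measure: str, target_rate_hz: float = TARGET_RATE_HZ) -> ConditionedTrace:
    """Smooth at the native rate and upsample to a uniform 1 kHz grid.

    The Savitzky-Golay window is 500 ms for pupil and 200 ms for face and
    locomotion (second order, so constants, ramps and parabolas pass
    unchanged); upsampling is by linear interpolation. NaN gaps remain
    NaN — run :func:`interpolate_gaps` first to fill short dropouts.
    """
    if measure not in SG_WINDOW_MS:
        raise ValidationError(f"unknown measure {measure!r}")
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(time_s) != len(values):
        raise ValidationError("time and value arrays must have equal length")
    native_dt = float(np.median(np.diff(time_s)))
    window = int(round(SG_WINDOW_MS[measure] / 1000.0 / native_dt))
    window = max(window | 1, SG_ORDER + 1 + ((SG_ORDER + 1) % 2 == 0))  # odd, > order
    if len(values) < window:
        raise ValidationError(
            f"trace shorter than the {SG_WINDOW_MS[measure]:.0f} ms filter window"
        )
    smooth = _segmentwise_savgol(values, window)
    dt = 1.0 / target_rate_hz
    grid = time_s[0] + dt * np.arange(int(np.floor((time_s[-1] - time_s[0]) / dt)) + 1)
    # np.interp propagates NaN across the straddled interval, keeping long
    # gaps masked on the upsampled grid.
    up = np.interp(grid, time_s, smooth)
    return ConditionedTrace(time_s=grid, values=up, measure=measure)


def normalize_to_max(trace: ConditionedTrace) -> ConditionedTrace:
    """Divide by the session maximum, mapping the max to 1."""
    m = float(np.nanmax(trace.values))
    if m <= 0:
        raise ValidationError("cannot normalize a trace with nonpositive maximum")
    return ConditionedTrace(
        time_s=trace.time_s, values=trace.values / m, measure=trace.measure, session_max=m
    )


def normalize_pupil(trace: ConditionedTrace) -> ConditionedTrace:
    """Session-max pupil normalization (values in [0, 1], max exactly 1)."""
    return normalize_to_max(trace)


def prestim_values(trace: ConditionedTrace, onsets) -> np.ndarray:
    """Sample of the trace immediately before each stimulus onset.

    For each onset, the value at the last grid time strictly before it;
    onsets at or before the trace start yield NaN.
    """
    onsets = np.asarray(onsets, dtype=float)
    idx = np.searchsorted(trace.time_s, onsets, side="left") - 1
    out = np.full(len(onsets), np.nan)
    ok = idx >= 0
    out[ok] = trace.values[idx[ok]]
    return out


def rolling_variability(values, window: int = 10, min_periods: int = 3):
    """Past-trial SD and CV: for trial t, statistics over trials
    [t-window, t-1] within the session (sample SD, ddof=1); trials with
    fewer than ``min_periods`` valid predecessors are missing. CV is
    undefined (NaN) when the window mean is 0."""
    s = pd.Series(np.asarray(values, dtype=float)).shift(1)
    roll = s.rolling(window, min_periods=min_periods)
    sd = roll.std(ddof=1)
    mean = roll.mean()
    cv = sd / mean.where(mean != 0)
    return sd.to_numpy(), cv.to_numpy()


def movement_index(face_values, locomotion_values):
    """Z-score each movement measure across trials and sum.

    By construction the index is equally correlated with both inputs when
    they have equal variance. Raises on zero-variance input (z-score
    undefined).
    """
    out = []
    for name, v in (("face", face_values), ("locomotion", locomotion_values)):
        v = np.asarray(v, dtype=float)
        mu, sd = np.nanmean(v), np.nanstd(v)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"zero-variance {name} input: z-score undefined")
        out.append((v - mu) / sd)
    return out[0] + out[1]


def motion_energy(frames, roi=None, normalize: bool = True) -> np.ndarray:
    """Face motion energy from a video frame stack (F, H, W).

    Per frame, the mean absolute frame-to-frame intensity change within
    the ROI (a boolean mask or index tuple; whole frame by default),
    normalized to the session maximum. The first frame has no
    predecessor and is NaN.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValidationError("frames must be a (F, H, W) stack")
    diff = np.abs(np.diff(frames, axis=0))
    if roi is not None:
        roi_mask = np.asarray(roi)
        if roi_mask.dtype == bool:
            diff = diff[:, roi_mask]
        else:
            diff = diff[(slice(None),) + tuple(roi)]
    e = diff.reshape(len(diff), -1).mean(axis=1)
    e = np.concatenate([[np.nan], e])
    if normalize:
        m = np.nanmax(e)
        if m > 0:
            e = e / m
    return e


# ---------------------------------------------------------------------------
# Session / subject pipelines


def session_trial_features(
    session,
    target_rate_hz: float = TARGET_RATE_HZ,
    max_gap_ms: float = 200.0,
    window: int = 10,
) -> pd.DataFrame:
    """Per-trial pre-stimulus values and rolling variability for one session.

    Columns: ``pupil, face, locomotion`` (pre-stimulus values; pupil and
    face session-max normalized), ``<measure>_sd10`` and
    ``<measure>_cv10``. Rolling statistics never use the current or
    future trials.
    """
    onsets = session.trials["stim_onset_s"].to_numpy(dtype=float)
    out = pd.DataFrame(index=session.trials.index)
    for measure in MEASURES:
        if measure not in session.traces:
            continue
        t, v = session.traces[measure]
        v = np.asarray(v, dtype=float)
        if measure == "pupil":
            v = interpolate_gaps(t, v, max_gap_ms=max_gap_ms)
        cond = condition(t, v, measure, target_rate_hz=target_rate_hz)
        if measure in ("pupil", "face"):
            cond = normalize_to_max(cond)
        vals = prestim_values(cond, onsets)
        sd, cv = rolling_variability(vals, window=window)
        out[measure] = vals
        out[f"{measure}_sd10"] = sd
        out[f"{measure}_cv10"] = cv
    return out


def subject_trial_features(sessions, **kwargs) -> pd.DataFrame:
    """Concatenate per-session features and add the subject-level movement
    index (value and 10-trial SD, each a sum of z-scores across all of the
    subject's trials)."""
    frames = []
    for s in sessions:
        f = session_trial_features(s, **kwargs)
        f.insert(0, "session_id", s.session_id)
        f.insert(1, "trial", np.arange(len(f)))
        frames.append(f)
    feats = pd.concat(frames, ignore_index=True)
    if {"face", "locomotion"}.issubset(feats.columns):
        feats["movement_index"] = movement_index(feats["face"], feats["locomotion"])
        feats["movement_index_sd10"] = movement_index(
            feats["face_sd10"], feats["locomotion_sd10"]
        )
    return feats
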