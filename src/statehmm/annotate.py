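"""Discrete state labels, stereotype classification, and dwell statistics.

Posterior state probabilities are discretized with a confidence
threshold (default 0.8): a trial belongs to the argmax state when that
state's posterior reaches the threshold and is otherwise indeterminate.
Each fitted state is classified into one of six stereotypes by its
response profile at the easiest stimuli: optimal, disengaged, left/right
bias, and avoid-left/avoid-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glmhmm import GLMHMMParams, ValidationError, emission_probs

INDETERMINATE = -1

STEREOTYPES = (
    "optimal",
    "disengaged",
    "bias_left",
    "bias_right",
    "avoid_left",
    "avoid_right",
)

# Idealized response profiles at (left-target, right-target) easy stimuli,
# rows over categories (L, R, Nr).
_IDEAL_PROFILES = {
    "optimal": (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
    "disengaged": (np.array([0, 0, 1.0]), np.array([0, 0, 1.0])),
    "bias_left": (np.array([1.0, 0, 0]), np.array([1.0, 0, 0])),
    "bias_right": (np.array([0, 1.0, 0]), np.array([0, 1.0, 0])),
    "avoid_right": (np.array([1.0, 0, 0]), np.array([0, 0, 1.0])),
    "avoid_left": (np.array([0, 0, 1.0]), np.array([0, 1.0, 0])),
}


@dataclass
class StateLabelSequence:
    """Per-trial discrete labels for one session plus its epoch list.

    ``labels[t]`` is a state id or INDETERMINATE (-1); ``epochs`` are
    (label, start_trial, length) runs tiling the session.
    """

    labels: np.ndarray
    threshold: float
    epochs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.epochs = _run_lengths(self.labels)


def _run_lengths(labels: np.ndarray) -> list:
    epochs = []
    if len(labels) == 0:
        return epochs
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            epochs.append((int(labels[start]), start, t - start))
            start = t
    return epochs


def discretize(gamma: np.ndarray, threshold: float = 0.8) -> StateLabelSequence:
    """Label each trial with its argmax state when confident, else
    indeterminate. The threshold is inclusive (gamma == threshold counts
    as discrete) and must exceed 0.5 so labels are unique."""
    if not 0.5 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0.5, 1]")
    gamma = np.asarray(gamma, dtype=float)
    top = gamma.max(axis=1)
    labels = np.where(top >= threshold, gamma.argmax(axis=1), INDETERMINATE)
    return StateLabelSequence(labels=labels, threshold=threshold)


# ---------------------------------------------------------------------------
# Stereotypes


@dataclass
class StereotypeMap:
    """state id -> stereotype name, with the response summary behind it."""

    mapping: dict
    profiles: dict  # state id -> (3,) x2 response probabilities at u = -1, +1

    def states_of(self, stereotype: str) -> list:
        return [k for k, v in self.mapping.items() if v == stereotype]

    def stereotype_labels(self, labels: np.ndarray) -> np.ndarray:
        """Map a per-trial state-id label array to stereotype names
        ('indeterminate' for INDETERMINATE trials)."""
        out = np.empty(len(labels), dtype=object)
        for i, l in enumerate(labels):
            out[i] = "indeterminate" if l == INDETERMINATE else self.mapping[int(l)]
        return out


def classify_stereotypes(params: GLMHMMParams, stimulus_grid=None) -> StereotypeMap:
    """Classify each state into one of the six stereotypes.

    Uses the response profile at the easiest left- and right-target
    stimuli (the extremes of the grid, by default u = -1 and +1):
    disengaged when No-response dominates both sides; optimal when the
    correct lick dominates both sides; bias when one lick direction
    dominates both sides; avoid-right (avoid-left) when the correct lick
    dominates the left (right) target but No-response dominates the
    other. Any remaining profile falls back to the nearest idealized
    stereotype in total-variation distance, so the map is total.
    """
    grid = np.asarray(stimulus_grid if stimulus_grid is not None else [-1.0, 1.0], float)
    if not (np.any(grid < 0) and np.any(grid > 0)):
        raise ValidationError("stimulus grid must contain a left (<0) and right (>0) value")
    u_left, u_right = float(grid.min()), float(grid.max())
    mapping, profiles = {}, {}
    for k in range(params.n_states):
        pL = emission_probs(params, k, u_left)  # response to left-target stimulus
        pR = emission_probs(params, k, u_right)
        profiles[k] = (pL, pR)
        if pL[2] >= 0.5 and pR[2] >= 0.5:
            mapping[k] = "disengaged"
        elif pL[0] >= 0.5 and pR[1] >= 0.5:
            mapping[k] = "optimal"
        elif pL[0] >= 0.5 and pR[0] >= 0.5:
            mapping[k] = "bias_left"
        elif pL[1] >= 0.5 and pR[1] >= 0.5:
            mapping[k] = "bias_right"
        elif pL[0] >= 0.5 and pR[2] >= 0.5:
            mapping[k] = "avoid_right"
        elif pL[2] >= 0.5 and pR[1] >= 0.5:
            mapping[k] = "avoid_left"
        else:
            tv = {
                name: 0.5 * (np.abs(pL - iL).sum() + np.abs(pR - iR).sum())
                for name, (iL, iR) in _IDEAL_PROFILES.items()
            }
            mapping[k] = min(tv, key=tv.get)
    return StereotypeMap(mapping=mapping, profiles=profiles)


# ---------------------------------------------------------------------------
# Dwell statistics


@dataclass
class DwellStats:
    """Occupancy, dwell-time and transition-duration summaries."""

    occupancy: dict  # stereotype -> fraction of trials
    indeterminate_fraction: float
    dwell_times: dict  # stereotype -> list of epoch lengths (trials)
    transition_durations: list  # lengths of indeterminate runs between states
    median_transition: float  # nan when no transitions

    def __post_init__(self) -> None:
        total = sum(self.occupancy.values()) + self.indeterminate_fraction
        if abs(total - 1.0) > 1e-10:
            raise ValidationError("occupancy fractions must sum to 1")


def dwell_stats(label_sequences, stereotypes: StereotypeMap) -> DwellStats:
    """Aggregate epoch statistics across sessions.

    ``label_sequences`` is a list of :class:`StateLabelSequence` (or raw
    label arrays), one per session; epochs never merge across session
    boundaries. A transition duration is the length of an indeterminate
    run flanked by two discrete epochs; indeterminate runs at session
    edges count toward occupancy only.
    """
    if not label_sequences:
        raise ValidationError("need at least one labelled session")
    counts = {s: 0 for s in STEREOTYPES}
    n_ind = 0
    n_total = 0
    dwell = {s: [] for s in STEREOTYPES}
    trans = []
    for seq in label_sequences:
        epochs = seq.epochs if isinstance(seq, StateLabelSequence) else _run_lengths(np.asarray(seq))
        labels = [e[0] for e in epochs]
        for i, (lab, _start, length) in enumerate(epochs):
            n_total += length
            if lab == INDETERMINATE:
                n_ind += length
                if 0 < i < len(epochs) - 1:
                    trans.append(length)
            else:
                st = stereotypes.mapping[lab]
                counts[st] += length
                dwell[st].append(length)
    occupancy = {s: c / n_total for s, c in counts.items()}
    return DwellStats(
        occupancy=occupancy,
        indeterminate_fraction=n_ind / n_total,
        dwell_times=dwell,
        transition_durations=trans,
        median_transition=float(np.median(trans)) if trans else float("nan"),
    )
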