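"""Synthetic experiment generator with known ground truth.

Emulates the structure of head-fixed two-alternative (plus no-response)
discrimination sessions: a few hundred trials per session, stimulus values
on the task grids, a sticky hidden state chain, multinomial choices drawn
from each state's psychometric GLM, and continuous physiological traces
(normalized pupil diameter, face motion energy, locomotion speed) whose
pre-stimulus level, variability and mutual coupling depend on the hidden
state. Every downstream stage of the package is testable against the
generative parameters returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .glmhmm import CATEGORIES, GLMHMMParams, ValidationError, emission_logprobs

MEASURES = ("pupil", "face", "locomotion")

# Default per-state physiology for a 3-state (disengaged-low / optimal /
# disengaged-high style) configuration; see PhysioCoupling.
_DEF_PUPIL_MEAN = (0.3, 0.6, 0.9)
_DEF_MOVE_SHARED_LOADING = np.sqrt(0.9)  # face/locomotion loading on the
# shared per-trial movement factor; the residual 10% is measure-private
# jitter so the two movement channels are strongly but not perfectly
# correlated, as in real recordings.


@dataclass
class PhysioCoupling:
    """State-conditional physiology: per-state mean and SD of each measure's
    pre-stimulus value, the within-trial AR(1) persistence of the trace
    wiggle, and the per-state correlation between pupil and the latent
    movement factor (the inverted-U coupling: decoupled in the optimal
    state, coupled when disengaged)."""

    pupil_mean: np.ndarray
    pupil_sd: np.ndarray
    face_mean: np.ndarray
    face_sd: np.ndarray
    locomotion_mean: np.ndarray
    locomotion_sd: np.ndarray
    pupil_movement_corr: np.ndarray
    persistence: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "pupil_mean",
            "pupil_sd",
            "face_mean",
            "face_sd",
            "locomotion_mean",
            "locomotion_sd",
            "pupil_movement_corr",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        K = len(self.pupil_mean)
        for name in ("pupil_sd", "face_mean", "face_sd", "locomotion_mean", "locomotion_sd", "pupil_movement_corr"):
            if len(getattr(self, name)) != K:
                raise ValidationError(f"{name} must have length K={K}")
        for name in ("pupil_sd", "face_sd", "locomotion_sd"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} must be nonnegative")
        if np.any((self.pupil_mean < 0) | (self.pupil_mean > 1)):
            raise ValidationError("pupil means must lie in [0, 1]")
        if np.any((self.face_mean < 0) | (self.face_mean > 1)):
            raise ValidationError("face means must lie in [0, 1]")
        if np.any(self.locomotion_mean < 0):
            raise ValidationError("locomotion means must be nonnegative")
        if np.any(np.abs(self.pupil_movement_corr) > 1):
            raise ValidationError("pupil-movement correlations must lie in [-1, 1]")
        if not 0 <= self.persistence < 1:
            raise ValidationError("persistence must lie in [0, 1)")

    @property
    def n_states(self) -> int:
        return len(self.pupil_mean)


def default_coupling(optimum_pupil: float = 0.6) -> PhysioCoupling:
    """Three-state coupling with the optimal state (index 1) at intermediate
    pupil/movement and decoupled; the non-optimal states sit at the arousal
    extremes and are strongly pupil-movement coupled (inverted-U)."""
    lo = max(0.1, optimum_pupil - 0.13)
    hi = min(0.9, optimum_pupil + 0.13)
    # Means overlap substantially (gaps ~1.5-2 within-state SDs): pupil
    # distributions of the states overlap heavily in real recordings, and
    # the optimal state is the least variable.
    return PhysioCoupling(
        pupil_mean=(lo, optimum_pupil, hi),
        pupil_sd=(0.09, 0.06, 0.09),
        face_mean=(0.32, 0.45, 0.58),
        face_sd=(0.09, 0.06, 0.09),
        locomotion_mean=(0.05, 0.1, 0.16),
        locomotion_sd=(0.05, 0.03, 0.06),
        pupil_movement_corr=(0.8, 0.1, 0.8),
        persistence=0.8,
    )


def default_glmhmm(K: int = 3) -> GLMHMMParams:
    """Sticky ground-truth models used throughout the test suite.

    K=3: disengaged (low arousal), optimal (intermediate), left-bias
    (high arousal) — three behaviorally distinct psychometric profiles.
    """
    if K == 1:
        W = np.array([[[-3.0], [3.0], [0.0]]])
        b = np.array([[1.0, 1.0, 0.0]])
        return GLMHMMParams(W, b, np.ones((1, 1)), np.ones(1))
    if K == 3:
        # state 0: disengaged (Nr dominates at every stimulus);
        # state 1: optimal (steep stimulus-guided psychometric);
        # state 2: left bias (licks left regardless of stimulus).
        W = np.array(
            [
                [[-1.2], [1.2], [0.0]],
                [[-4.0], [4.0], [0.0]],
                [[-1.0], [1.0], [0.0]],
            ]
        )
        b = np.array(
            [
                [-2.0, -2.0, 0.0],
                [1.5, 1.5, 0.0],
                [2.5, -0.5, 0.0],
            ]
        )
        A = np.full((3, 3), 0.01) + np.diag([0.97, 0.97, 0.97])
        A /= A.sum(axis=1, keepdims=True)
        pi = np.array([0.25, 0.5, 0.25])
        return GLMHMMParams(W, b, A, pi)
    raise ValidationError("default ground truths are provided for K in {1, 3}")


def recovery_glmhmm() -> GLMHMMParams:
    """Well-separated, fully identifiable 3-state truth for parameter-
    recovery experiments.

    All three states are responsive (optimal, left-bias, right-bias), so
    every stimulus weight is expressed in the data: slopes are moderate
    (steep psychometrics saturate at the easy stimuli and carry little
    slope information, while rarely-responding states barely express
    their weights at all). Transition diagonal 0.98.
    """
    W = np.array(
        [
            [[-2.0], [2.0], [0.0]],
            [[-1.5], [1.5], [0.0]],
            [[-1.5], [1.5], [0.0]],
        ]
    )
    b = np.array(
        [
            [1.3, 1.3, 0.0],
            [2.2, -0.3, 0.0],
            [-0.3, 2.2, 0.0],
        ]
    )
    A = np.full((3, 3), 0.01) + np.diag([0.97, 0.97, 0.97])
    A /= A.sum(axis=1, keepdims=True)
    return GLMHMMParams(W, b, A, np.full(3, 1.0 / 3.0))


VISUAL_GRID = (-1.0, -0.6, -0.2, 0.2, 0.6, 1.0)
AUDITORY_GRID = (-1.0, -0.6, -0.2, 0.2, 0.6, 1.0)


@dataclass
class GenerativeConfig:
    """Full description of a synthetic experiment."""

    n_sessions: int = 10
    trials_per_session: int = 400
    modality: Literal["auditory", "visual"] = "visual"
    stimulus_grid: tuple = VISUAL_GRID
    glmhmm: GLMHMMParams = field(default_factory=default_glmhmm)
    physio_coupling: PhysioCoupling = field(default_factory=default_coupling)
    iti_mean_s: float = 5.0
    iti_jitter_s: float = 2.0
    stim_duration_s: float = 1.2
    sample_rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValidationError("n_sessions and trials_per_session must be >= 1")
        grid = np.asarray(self.stimulus_grid, dtype=float)
        if grid.size == 0 or np.any(np.abs(grid) > 1):
            raise ValidationError("stimulus_grid must be nonempty with values in [-1, 1]")
        if self.iti_mean_s <= 0 or self.iti_jitter_s < 0 or self.stim_duration_s <= 0:
            raise ValidationError("timing parameters must be positive (jitter nonnegative)")
        if self.sample_rate_hz < 30:
            raise ValidationError("traces must be sampled at >= 30 Hz")
        if self.glmhmm.n_states != self.physio_coupling.n_states:
            raise ValidationError(
                "glmhmm and physio_coupling disagree on the number of states "
                f"({self.glmhmm.n_states} vs {self.physio_coupling.n_states})"
            )


@dataclass
class SyntheticGroundTruth:
    """Generative parameters plus the true hidden state sequences."""

    state_sequences: list  # one int array per session
    glmhmm: GLMHMMParams
    physio_coupling: PhysioCoupling
    seed: int

    def __post_init__(self) -> None:
        K = self.glmhmm.n_states
        for seq in self.state_sequences:
            s = np.asarray(seq)
            if s.size and (s.min() < 0 or s.max() >= K):
                raise ValidationError("state ids must lie in [0, K)")


# ---------------------------------------------------------------------------
# Stimulus values


def stimulus_value(modality: str, descriptor) -> float:
    """Map a stimulus descriptor to its signed task value in [-1, 1].

    auditory: descriptor = (p_right, p_left), the proportions of tones in
    the right-target and left-target octaves; value = p_right - p_left.
    visual: descriptor = (angle_deg in [0, 90], side), where ``side`` in
    {"L", "R"} assigns the orientation pole nearer the angle; magnitude =
    |angle - 45| / 45, signed negative for left.
    """
    if modality == "auditory":
        p_right, p_left = float(descriptor[0]), float(descriptor[1])
        if not (0 <= p_right <= 1 and 0 <= p_left <= 1 and p_right + p_left <= 1 + 1e-12):
            raise ValidationError("octave proportions must be in [0,1] and sum to <= 1")
        return p_right - p_left
    if modality == "visual":
        angle, side = float(descriptor[0]), str(descriptor[1])
        if not 0 <= angle <= 90:
            raise ValidationError("Gabor angle must lie in [0, 90] degrees")
        if side not in ("L", "R"):
            raise ValidationError("side must be 'L' or 'R'")
        mag = abs(angle - 45.0) / 45.0
        return -mag if side == "L" else mag
    raise ValidationError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Trial simulation


def _sample_chain(rng, A, pi, T):
    states = np.empty(T, dtype=int)
    K = len(pi)
    states[0] = rng.choice(K, p=pi)
    for t in range(1, T):
        states[t] = rng.choice(K, p=A[states[t - 1]])
    return states


def simulate_trials(cfg: GenerativeConfig):
    """Draw hidden state chains, stimuli, choices and trial onset times.

    Returns ``(trial_tables, truth)`` where ``trial_tables`` is one
    DataFrame per session with columns ``stimulus_value, choice, outcome,
    stim_onset_s, reward_port`` and ``truth`` is the
    :class:`SyntheticGroundTruth`. Chains never cross session boundaries;
    onsets accumulate a uniform ITI on [mean - jitter, mean + jitter] plus
    the stimulus duration. Seeded runs are bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    params = cfg.glmhmm
    grid = np.asarray(cfg.stimulus_grid, dtype=float)
    tables, seqs = [], []
    for _ in range(cfg.n_sessions):
        T = cfg.trials_per_session
        states = _sample_chain(rng, params.transitions, params.init_probs, T)
        stim = rng.choice(grid, size=T)
        logp = emission_logprobs(params, stim[:, None])  # (T, K, 3)
        probs = np.exp(logp[np.arange(T), states])
        u = rng.random(T)
        choices = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        itis = cfg.iti_mean_s + cfg.iti_jitter_s * (2 * rng.random(T) - 1)
        onsets = np.cumsum(itis) + np.arange(T) * cfg.stim_duration_s
        correct = np.where(stim < 0, 0, np.where(stim > 0, 1, -1))
        choice_lbl = np.array(CATEGORIES)[choices]
        outcome = np.where(
            choices == 2, "no_response", np.where(choices == correct, "hit", "error")
        )
        reward_port = np.where(outcome == "hit", choice_lbl, "")
        tables.append(
            pd.DataFrame(
                {
                    "stimulus_value": stim,
                    "choice": choice_lbl,
                    "outcome": outcome,
                    "stim_onset_s": onsets,
                    "reward_port": reward_port,
                }
            )
        )
        seqs.append(states)
    truth = SyntheticGroundTruth(
        state_sequences=seqs,
        glmhmm=params,
        physio_coupling=cfg.physio_coupling,
        seed=cfg.seed,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Physiology simulation


def _trial_targets(rng, coupling: PhysioCoupling, states: np.ndarray):
    """Per-trial latent targets for (pupil, face, locomotion).

    A bivariate standard normal (p, m) with state-dependent correlation
    drives pupil (via p) and a shared movement factor (via m); face and
    locomotion load on m with coefficient sqrt(0.9) plus independent
    jitter, so their index inherits the configured pupil-movement
    correlation (up to a ~3% attenuation from the jitter).
    """
    T = len(states)
    rho = coupling.pupil_movement_corr[states]
    p = rng.standard_normal(T)
    m = rho * p + np.sqrt(1 - rho**2) * rng.standard_normal(T)
    lam = _DEF_MOVE_SHARED_LOADING
    res = np.sqrt(1 - lam**2)
    face_z = lam * m + res * rng.standard_normal(T)
    loco_z = lam * m + res * rng.standard_normal(T)
    pupil = coupling.pupil_mean[states] + coupling.pupil_sd[states] * p
    face = coupling.face_mean[states] + coupling.face_sd[states] * face_z
    loco = coupling.locomotion_mean[states] + coupling.locomotion_sd[states] * loco_z
    return pupil, face, loco


def _build_trace(rng, times, anchor_times, anchor_values, sd_scale, persistence):
    """Trace through exact anchor values with an AR(1) wiggle between them.

    The wiggle is an AR(1) process pinned to zero at the anchor samples
    (its linear interpolant over anchors is subtracted), so the sample
    immediately before each stimulus carries exactly the drawn target.
    """
    base = np.interp(times, anchor_times, anchor_values)
    if sd_scale > 0 and len(times) > 1:
        phi = persistence
        innov_sd = sd_scale * np.sqrt(max(1 - phi**2, 1e-12))
        noise = rng.standard_normal(len(times)) * innov_sd
        w = np.empty(len(times))
        w[0] = noise[0] / np.sqrt(max(1 - phi**2, 1e-12))
        for i in range(1, len(times)):
            w[i] = phi * w[i - 1] + noise[i]
        idx = np.searchsorted(times, anchor_times)
        idx = np.clip(idx, 0, len(times) - 1)
        w = w - np.interp(times, times[idx], w[idx])
        return base + w
    return base


def simulate_physio(truth: SyntheticGroundTruth, cfg: GenerativeConfig, trial_tables=None):
    """Generate pupil / face / locomotion traces for each session.

    Returns a list (one per session) of dicts
    ``{measure: (time_s, values)}``. The sample at the last tick strictly
    before each stimulus onset equals the per-trial latent target drawn
    from the state-conditional distribution, so pre-stimulus samples have
    exactly the configured state-conditional moments. Traces start 60 s
    before the first onset; pupil and face are clipped to [0, 1] and
    locomotion to >= 0 (defaults keep targets well inside the bounds).
    """
    if trial_tables is None:
        trial_tables, _ = simulate_trials(cfg)
    if len(trial_tables) != len(truth.state_sequences):
        raise ValidationError("trial tables and ground truth disagree on session count")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E37]))
    coupling = truth.physio_coupling
    dt = 1.0 / cfg.sample_rate_hz
    out = []
    for table, states in zip(trial_tables, truth.state_sequences):
        onsets = table["stim_onset_s"].to_numpy()
        t0 = onsets[0] - 60.0
        t1 = onsets[-1] + cfg.stim_duration_s
        times = t0 + dt * np.arange(int(np.ceil((t1 - t0) / dt)) + 1)
        # anchor at the last sample strictly before each onset
        anchor_idx = np.searchsorted(times, onsets, side="left") - 1
        anchor_times = times[anchor_idx]
        pupil_t, face_t, loco_t = _trial_targets(rng, coupling, np.asarray(states))
        traces = {}
        for name, targets, sds in (
            ("pupil", pupil_t, coupling.pupil_sd),
            ("face", face_t, coupling.face_sd),
            ("locomotion", loco_t, coupling.locomotion_sd),
        ):
            wiggle_sd = 0.5 * float(np.mean(sds))
            vals = _build_trace(
                rng, times, anchor_times, targets, wiggle_sd, coupling.persistence
            )
            if name in ("pupil", "face"):
                # A brief full dilation / movement burst during the
                # pre-task baseline: sessions reach their maximum early
                # (handling, task start), so the session max of these
                # max-normalized measures is genuinely 1.
                burst_t = times[0] + 15.0 + 10.0 * rng.random()
                burst = np.exp(-0.5 * ((times - burst_t) / 3.0) ** 2)
                vals = np.maximum(vals, np.where(times < onsets[0] - 5.0, burst, 0.0))
                vals = np.clip(vals, 0.0, 1.0)
            else:
                vals = np.maximum(vals, 0.0)
            traces[name] = (times.copy(), vals)
        out.append(traces)
    return out


def simulate_experiment(cfg: GenerativeConfig):
    """Convenience wrapper: trials + ground truth + physiology."""
    tables, truth = simulate_trials(cfg)
    physio = simulate_physio(truth, cfg, trial_tables=tables)
    return tables, physio, truth
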