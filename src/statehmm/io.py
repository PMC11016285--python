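"""Session data model, tabular read/write, and session-inclusion filters.

The canonical on-disk format is a plain-text "tabular dialect": one
directory per session containing a ``trials.csv`` table (one row per
stimulus presentation) and one two-column ``(time_s, value)`` CSV per
physiological trace, plus a small ``meta.json``. NWB files holding the
same content can be read when ``pynwb`` is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glmhmm import ValidationError

TRIAL_COLUMNS = ("stimulus_value", "choice", "outcome", "stim_onset_s")
CHOICES = ("L", "R", "Nr")
OUTCOMES = ("hit", "error", "no_response")
TRACE_NAMES = ("pupil", "face", "locomotion")


@dataclass
class Session:
    """One behavioral session: trials plus physiological traces.

    ``trials`` columns: stimulus_value (float in [-1,1]), choice
    (L/R/Nr), outcome (hit/error/no_response), stim_onset_s (s),
    optionally reward_port (L/R) and training_stage (int).
    ``traces``: measure name -> (time_s, values) arrays.
    """

    subject_id: str
    session_id: str
    modality: str
    trials: pd.DataFrame
    traces: dict = field(default_factory=dict)
    stim_duration_s: float = 1.2
    training_stage: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValidationError(f"trials table missing required column(s): {missing}")
        t = self.trials
        if not set(t["choice"]).issubset(CHOICES):
            raise ValidationError(f"invalid choice values: {set(t['choice']) - set(CHOICES)}")
        if not set(t["outcome"]).issubset(OUTCOMES):
            raise ValidationError(f"invalid outcome values: {set(t['outcome']) - set(OUTCOMES)}")
        nr = t["choice"] == "Nr"
        noresp = t["outcome"] == "no_response"
        if not (nr == noresp).all():
            raise ValidationError("outcome 'no_response' must coincide with choice 'Nr'")
        onsets = t["stim_onset_s"].to_numpy(dtype=float)
        if len(onsets) and np.any(np.diff(onsets) <= 0):
            raise ValidationError("stim_onset_s must be strictly increasing within a session")
        if np.any(np.abs(t["stimulus_value"].to_numpy(dtype=float)) > 1 + 1e-12):
            raise ValidationError("stimulus_value must lie in [-1, 1]")
        for name, (time_s, values) in self.traces.items():
            time_s = np.asarray(time_s, dtype=float)
            if np.any(np.diff(time_s) <= 0):
                raise ValidationError(f"trace {name!r} timebase must be strictly increasing")
            if len(time_s) != len(values):
                raise ValidationError(f"trace {name!r} timebase/value length mismatch")
            if len(onsets):
                if time_s[0] > onsets[0] - 60.0 + 1e-6 or time_s[-1] < onsets[-1] + self.stim_duration_s - 1e-6:
                    raise ValidationError(
                        f"trace {name!r} must cover [first onset - 60 s, last onset + stim duration]"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def n_rewards(self) -> int:
        return int((self.trials["outcome"] == "hit").sum())

    def reward_port_shares(self) -> dict:
        """Fraction of rewards delivered at each port (over hit trials)."""
        hits = self.trials[self.trials["outcome"] == "hit"]
        n = len(hits)
        if n == 0:
            return {"L": 0.0, "R": 0.0}
        port = hits["reward_port"] if "reward_port" in hits.columns else hits["choice"]
        return {p: float((port == p).sum()) / n for p in ("L", "R")}


@dataclass
class SubjectDataset:
    """Included sessions for one subject plus the exclusion log."""

    subject_id: str
    sessions: list
    exclusions: dict = field(default_factory=dict)
    includable: bool = False

    def __post_init__(self) -> None:
        for s in self.sessions:
            if s.subject_id != self.subject_id:
                raise ValidationError("all sessions must share the subject id")


# ---------------------------------------------------------------------------
# Tabular dialect


def write_sessions(sessions, path, ground_truth=None) -> None:
    """Write sessions in the tabular dialect under ``path``.

    Layout: ``<path>/<session_id>/trials.csv``, one ``<measure>.csv`` per
    trace, and ``meta.json``. If ``ground_truth`` (a
    :class:`~statehmm.synthetic.SyntheticGroundTruth`) is given, a
    ``ground_truth.json`` sidecar with the generative parameters and true
    state sequences is written at the root.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for s in sessions:
        d = root / s.session_id
        d.mkdir(exist_ok=True)
        s.trials.to_csv(d / "trials.csv", index=False)
        for name, (time_s, values) in s.traces.items():
            pd.DataFrame({"time_s": time_s, "value": values}).to_csv(
                d / f"{name}.csv", index=False
            )
        meta = {
            "subject_id": s.subject_id,
            "session_id": s.session_id,
            "modality": s.modality,
            "stim_duration_s": s.stim_duration_s,
            "training_stage": s.training_stage,
            "traces": sorted(s.traces),
        }
        with open(d / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)
    if ground_truth is not None:
        gt = {
            "seed": ground_truth.seed,
            "glmhmm": ground_truth.glmhmm.to_dict(),
            "state_sequences": [np.asarray(s).tolist() for s in ground_truth.state_sequences],
            "physio_coupling": {
                k: (np.asarray(v).tolist() if np.ndim(v) else v)
                for k, v in vars(ground_truth.physio_coupling).items()
            },
        }
        with open(root / "ground_truth.json", "w") as fh:
            json.dump(gt, fh, indent=1)


def _read_tabular_session(d: Path) -> Session:
    trials_path = d / "trials.csv"
    if not trials_path.exists():
        raise ValidationError(f"{d} has no trials.csv")
    trials = pd.read_csv(trials_path, keep_default_na=False, na_values=[""])
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"{trials_path} missing required column(s): {missing}")
    if "reward_port" in trials.columns:
        trials["reward_port"] = trials["reward_port"].fillna("").astype(str)
    meta = {}
    if (d / "meta.json").exists():
        with open(d / "meta.json") as fh:
            meta = json.load(fh)
    traces = {}
    for f in sorted(d.glob("*.csv")):
        if f.stem == "trials":
            continue
        tab = pd.read_csv(f)
        for col in ("time_s", "value"):
            if col not in tab.columns:
                raise ValidationError(f"{f} missing required column(s): ['{col}']")
        traces[f.stem] = (tab["time_s"].to_numpy(float), tab["value"].to_numpy(float))
    return Session(
        subject_id=str(meta.get("subject_id", "subject")),
        session_id=str(meta.get("session_id", d.name)),
        modality=str(meta.get("modality", "visual")),
        trials=trials,
        traces=traces,
        stim_duration_s=float(meta.get("stim_duration_s", 1.2)),
        training_stage=meta.get("training_stage"),
    )


def read_sessions(path, format: str = "tabular") -> list:
    """Read all sessions under ``path`` (one subdirectory per session)."""
    root = Path(path)
    if not root.exists():
        raise ValidationError(f"path does not exist: {root}")
    if format == "tabular":
        dirs = sorted(d for d in root.iterdir() if d.is_dir())
        if not dirs and (root / "trials.csv").exists():
            dirs = [root]
        if not dirs:
            raise ValidationError(f"no session directories under {root}")
        return [_read_tabular_session(d) for d in dirs]
    if format == "nwb":
        files = sorted(root.glob("*.nwb")) if root.is_dir() else [root]
        return [read_nwb_session(f) for f in files]
    raise ValidationError(f"unknown format {format!r}; use 'tabular' or 'nwb'")


def sessions_from_synthetic(tables, physio, cfg, subject_id="synthetic") -> list:
    """Wrap synthetic generator output into validated Sessions."""
    out = []
    for i, (trials, traces) in enumerate(zip(tables, physio)):
        out.append(
            Session(
                subject_id=subject_id,
                session_id=f"{subject_id}_s{i:03d}",
                modality=cfg.modality,
                trials=trials.copy(),
                traces={k: (t.copy(), v.copy()) for k, (t, v) in traces.items()},
                stim_duration_s=cfg.stim_duration_s,
            )
        )
    return out


# ---------------------------------------------------------------------------
# NWB (optional)


def read_nwb_session(path, field_map=None) -> Session:
    """Read one NWB file into a Session (requires the optional ``pynwb``).

    ``field_map`` maps our column names to the file's trials-table column
    names and acquisition series names; defaults assume like-named fields.
    """
    try:
        from pynwb import NWBHDF5IO  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading NWB files requires pynwb (install the 'nwb' extra)"
        ) from exc
    fm = {
        "stimulus_value": "stimulus_value",
        "choice": "choice",
        "outcome": "outcome",
        "stim_onset_s": "start_time",
        "pupil": "pupil",
        "face": "face",
        "locomotion": "locomotion",
    }
    fm.update(field_map or {})
    with NWBHDF5IO(str(path), "r") as io_:  # pragma: no cover - optional dependency
        nwb = io_.read()
        tt = nwb.trials.to_dataframe()
        trials = pd.DataFrame(
            {
                "stimulus_value": tt[fm["stimulus_value"]].to_numpy(float),
                "choice": tt[fm["choice"]].astype(str).to_numpy(),
                "outcome": tt[fm["outcome"]].astype(str).to_numpy(),
                "stim_onset_s": tt[fm["stim_onset_s"]].to_numpy(float),
            }
        )
        traces = {}
        for name in TRACE_NAMES:
            ts = nwb.acquisition.get(fm[name])
            if ts is not None:
                t = (
                    np.asarray(ts.timestamps)
                    if ts.timestamps is not None
                    else ts.starting_time + np.arange(len(ts.data)) / ts.rate
                )
                traces[name] = (t, np.asarray(ts.data, dtype=float))
        return Session(
            subject_id=str(nwb.subject.subject_id if nwb.subject else "subject"),
            session_id=str(nwb.identifier),
            modality="auditory",
            trials=trials,
            traces=traces,
        )


# ---------------------------------------------------------------------------
# Inclusion filters


def filter_sessions(
    sessions,
    min_rewards: int = 100,
    min_port_share: float = 0.20,
    min_sessions: int = 10,
    allowed_stages=(5, 6),
) -> SubjectDataset:
    """Apply the session-inclusion criteria and flag subject includability.

    A session is kept when it delivered at least ``min_rewards`` rewards
    (hit trials) with no less than ``min_port_share`` of rewards at each
    port, and (when a training stage is recorded) its stage is allowed.
    The subject is includable only when at least ``min_sessions`` sessions
    survive. Idempotent: filtering the kept set changes nothing.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValidationError("filter_sessions requires at least one session")
    subject = sessions[0].subject_id
    if any(s.subject_id != subject for s in sessions):
        raise ValidationError("all sessions must come from one subject")
    kept, excl = [], {}
    for s in sessions:
        if s.training_stage is not None and s.training_stage not in allowed_stages:
            excl[s.session_id] = "training_stage"
        elif s.n_rewards() < min_rewards:
            excl[s.session_id] = "min_rewards"
        elif min(s.reward_port_shares().values()) < min_port_share:
            excl[s.session_id] = "port_balance"
        else:
            kept.append(s)
    return SubjectDataset(
        subject_id=subject,
        sessions=kept,
        exclusions=excl,
        includable=len(kept) >= min_sessions,
    )


def sessions_to_arrays(sessions):
    """Convert Sessions to the (inputs, choices) pairs the model consumes."""
    out = []
    for s in sessions:
        U = s.trials["stimulus_value"].to_numpy(float)[:, None]
        y = np.array([CHOICES.index(c) for c in s.trials["choice"]])
        out.append((U, y))
    return out
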