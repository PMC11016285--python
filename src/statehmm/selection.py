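"""Cross-validated choice of the number of states and choice prediction.

The number of hidden states is chosen by 5-fold cross-validation across
sessions: for each candidate K the model is fit to the training sessions
(best of several random EM restarts) and scored by the held-out
log-likelihood normalized per trial. The chosen K is the smallest K on
the plateau of that curve. Choice-prediction accuracy withholds
contiguous 20% blocks of trials within each session, infers the state of
each withheld trial from the preceding trials and the transition matrix,
and predicts the most likely choice of that state's GLM.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .glmhmm import (
    GLMHMMParams,
    PriorConfig,
    ValidationError,
    em_fit,
    emission_logprobs,
    log_posterior,
)


def _as_session_arrays(dataset):
    """Accept Sessions, (inputs, choices) pairs, or a SubjectDataset."""
    if hasattr(dataset, "sessions"):
        dataset = dataset.sessions
    out = []
    for item in dataset:
        if isinstance(item, tuple):
            U = np.atleast_2d(np.asarray(item[0], dtype=float))
            if U.shape[0] == 1 and np.ndim(item[0]) == 1:
                U = U.T
            out.append((U, np.asarray(item[1])))
        else:  # Session
            from .io import sessions_to_arrays

            out.append(sessions_to_arrays([item])[0])
    return out


def fit_best_of_restarts(
    sessions,
    K: int,
    prior: PriorConfig,
    restarts: int,
    seed,
    **em_kwargs,
):
    """Run EM from several random initializations; keep the best objective.

    K=1 has a unimodal objective, so a single start suffices there.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = 1 if K == 1 else max(1, restarts)
    best = None
    best_idx = 0
    for i in range(n):
        fit = em_fit(sessions, K, prior=prior, seed=rng, **em_kwargs)
        if best is None or fit.log_posterior > best.log_posterior:
            best, best_idx = fit, i
    return best, best_idx


@dataclass
class SelectionResult:
    """Cross-validation summary for the scan over K."""

    k_scanned: list
    test_ll_per_trial: dict  # K -> mean over folds
    fold_ll: dict  # K -> per-fold array
    chosen_k: int
    winning_restarts: dict  # (K, fold) -> restart index
    final_params: GLMHMMParams | None = None
    plateau_tol: float = 0.002

    def ll_curve_vs_one_state(self) -> dict:
        """Test log-likelihood change relative to the one-state model."""
        base = self.test_ll_per_trial[min(self.k_scanned)]
        return {k: v - base for k, v in self.test_ll_per_trial.items()}


def select_num_states(
    dataset,
    K_max: int = 7,
    folds: int = 5,
    restarts: int = 10,
    prior: PriorConfig | None = None,
    seed: int = 0,
    plateau_tol: float = 0.002,
    fit_final: bool = True,
    final_restarts: int | None = None,
    **em_kwargs,
) -> SelectionResult:
    """Choose K by cross-validated test log-likelihood with a plateau rule.

    Sessions are shuffled once (seeded) and split round-robin into
    ``folds`` folds. For each fold and each K in 1..K_max the best of
    ``restarts`` EM fits on the training sessions is scored on the held-out
    sessions (log-likelihood per test trial). The chosen K is the smallest
    K whose mean test log-likelihood lies within ``plateau_tol`` nats/trial
    of the maximum — the start of the plateau. The final model is then a
    single best-of-restarts MLE fit to all sessions.
    """
    sessions = _as_session_arrays(dataset)
    prior = prior or PriorConfig()
    if len(sessions) < folds:
        raise ValidationError(
            f"need at least {folds} sessions for {folds}-fold CV, got {len(sessions)}"
        )
    # Fold assignment is keyed on session content (not list position), so
    # the CV score is invariant to session ordering.
    keys = [
        hashlib.sha1(np.ascontiguousarray(U).tobytes() + np.ascontiguousarray(y).tobytes()).hexdigest()
        for U, y in sessions
    ]
    canonical = np.argsort(keys)
    rng = np.random.default_rng(seed)
    order = canonical[rng.permutation(len(sessions))]
    fold_of = {int(s): f % folds for f, s in enumerate(order)}

    ks = list(range(1, K_max + 1))
    fold_ll = {k: np.zeros(folds) for k in ks}
    winners = {}
    for f in range(folds):
        train = [s for i, s in enumerate(sessions) if fold_of[i] != f]
        test = [s for i, s in enumerate(sessions) if fold_of[i] == f]
        n_test = sum(len(y) for _, y in test)
        for k in ks:
            fit, idx = fit_best_of_restarts(
                train, k, prior, restarts, np.random.default_rng((seed, f, k)), **em_kwargs
            )
            winners[(k, f)] = idx
            fold_ll[k][f] = log_posterior(fit.params, test, PriorConfig("MLE")) / n_test
    mean_ll = {k: float(fold_ll[k].mean()) for k in ks}
    top = max(mean_ll.values())
    chosen = min(k for k in ks if mean_ll[k] >= top - plateau_tol)

    final = None
    if fit_final:
        fit, _ = fit_best_of_restarts(
            sessions,
            chosen,
            PriorConfig("MLE"),
            final_restarts if final_restarts is not None else restarts,
            np.random.default_rng((seed, folds, 0)),
            **em_kwargs,
        )
        final = fit.params
    return SelectionResult(
        k_scanned=ks,
        test_ll_per_trial=mean_ll,
        fold_ll=fold_ll,
        chosen_k=chosen,
        winning_restarts=winners,
        final_params=final,
        plateau_tol=plateau_tol,
    )


# ---------------------------------------------------------------------------
# Choice prediction


@dataclass
class PredictionResult:
    """Cross-validated per-trial choice predictions and accuracy."""

    predicted: list  # one int array per session (category codes)
    observed: list
    accuracy: float
    n_trials: int = 0

    def __post_init__(self) -> None:
        pred = np.concatenate(self.predicted)
        obs = np.concatenate(self.observed)
        self.n_trials = len(obs)
        assert np.isclose(self.accuracy, float(np.mean(pred == obs)))


def _fold_mask(T: int, folds: int, fold: int, block_trials: int) -> np.ndarray:
    """True where trials are withheld: every ``folds``-th contiguous block
    of ``block_trials`` trials, rotating with ``fold``."""
    if block_trials < 1 or block_trials > T:
        raise ValidationError("withheld block longer than session (or empty)")
    chunk = np.arange(T) // block_trials
    return (chunk % folds) == fold


def _contiguous_segments(U, y, keep: np.ndarray):
    """(U, y) pieces for each maximal run of kept trials."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], keep.astype(int), [0]))))
    for lo, hi in zip(idx[::2], idx[1::2]):
        out.append((U[lo:hi], y[lo:hi]))
    return out


def predict_choices(
    dataset,
    K: int,
    folds: int = 5,
    block_trials: int = 12,
    prior: PriorConfig | None = None,
    restarts: int = 3,
    seed: int = 0,
    **em_kwargs,
) -> PredictionResult:
    """Cross-validated choice prediction with withheld trial blocks.

    Each session is tiled with contiguous blocks of ``block_trials``
    trials; fold f withholds every ``folds``-th block (so each fold tests
    ~1/folds of trials, 20% by default) and a model is trained on the
    remaining trials, each contiguous observed segment an independent
    chain. Withheld choices are then predicted by online filtering: the
    state belief is updated from observed (training) trials and
    propagated through the transition matrix across withheld trials
    (whose choices stay unobserved); the prediction for a withheld trial
    is the argmax choice category of the argmax belief state's GLM at
    that trial's stimulus. Ties take the lowest index.
    """
    sessions = _as_session_arrays(dataset)
    prior = prior or PriorConfig()
    if K < 1:
        raise ValidationError("K must be >= 1")
    predicted = [np.full(len(y), -1, dtype=int) for _, y in sessions]
    observed = [np.asarray(y) for _, y in sessions]

    for f in range(folds):
        train, masks = [], []
        for U, y in sessions:
            test_mask = _fold_mask(len(y), folds, f, block_trials)
            masks.append(test_mask)
            train.extend(_contiguous_segments(U, y, ~test_mask))
        fit, _ = fit_best_of_restarts(
            train, K, prior, restarts, np.random.default_rng((seed, f)), **em_kwargs
        )
        params = fit.params
        A = params.transitions
        for si, (U, y) in enumerate(sessions):
            test_mask = masks[si]
            B = np.exp(emission_logprobs(params, U)[np.arange(len(y)), :, y])
            P = np.exp(emission_logprobs(params, U))  # (T, K, 3)
            belief = params.init_probs.copy()  # prior belief over trial 0
            for t in range(len(y)):
                if test_mask[t]:
                    state = int(np.argmax(belief))
                    predicted[si][t] = int(np.argmax(P[t, state]))
                    belief = belief @ A  # choice unobserved: predict only
                else:
                    b = belief * B[t]
                    belief = (b / b.sum()) @ A

    pred = np.concatenate(predicted)
    obs = np.concatenate(observed)
    return PredictionResult(
        predicted=predicted,
        observed=observed,
        accuracy=float(np.mean(pred == obs)),
    )


def accuracy_curve(dataset, k_values, **kwargs) -> dict:
    """Choice-prediction accuracy for each K in ``k_values``."""
    return {k: predict_choices(dataset, k, **kwargs).accuracy for k in k_values}
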