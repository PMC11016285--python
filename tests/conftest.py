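"""Shared fixtures: one mid-sized synthetic experiment with a fitted model,
built once per test session and reused by the annotation, arousal and
acceptance tests."""

import numpy as np
import pytest

from statehmm import annotate, features, glmhmm, io as sio, selection, synthetic


@pytest.fixture(scope="session")
def experiment():
    """Standard 3-state experiment (disengaged / optimal / left-bias),
    10 sessions x 400 trials, pupil optimum 0.55."""
    cfg = synthetic.GenerativeConfig(
        n_sessions=10,
        trials_per_session=400,
        physio_coupling=synthetic.default_coupling(0.55),
        seed=42,
    )
    tables, physio, truth = synthetic.simulate_experiment(cfg)
    return cfg, tables, physio, truth


@pytest.fixture(scope="session")
def sessions(experiment):
    cfg, tables, physio, _ = experiment
    return sio.sessions_from_synthetic(tables, physio, cfg)


@pytest.fixture(scope="session")
def trial_features(sessions):
    return features.subject_trial_features(sessions)


@pytest.fixture(scope="session")
def fitted(experiment, sessions):
    """Best-of-restarts 3-state MLE fit plus labels and stereotypes."""
    cfg = experiment[0]
    arrs = sio.sessions_to_arrays(sessions)
    fit, _ = selection.fit_best_of_restarts(
        arrs, 3, glmhmm.PriorConfig(), restarts=5, seed=np.random.default_rng(1)
    )
    stereo = annotate.classify_stereotypes(fit.params, cfg.stimulus_grid)
    seqs, labels = [], []
    for arr in arrs:
        post = glmhmm.forward_backward(fit.params, *arr)
        seq = annotate.discretize(post.gamma)
        seqs.append(seq)
        labels.append(stereo.stereotype_labels(seq.labels))
    return {
        "params": fit.params,
        "stereotypes": stereo,
        "sequences": seqs,
        "stereotype_labels": np.concatenate(labels),
    }


@pytest.fixture(scope="session")
def session_features(sessions):
    return [features.session_trial_features(s) for s in sessions]
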