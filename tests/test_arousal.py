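"""Inverted-U analyses: binned probabilities, optimal pupil, alignment,
quadratic regressions, correlations, transition-aligned variability."""

import numpy as np
import pandas as pd
import pytest

from statehmm import arousal
from statehmm.arousal import (
    BinnedStateProb,
    align_to_optimal,
    binned_state_prob,
    fit_optimal_pupil,
    quadratic_state_regression,
    state_conditioned_correlation,
    transition_aligned_variability,
)
from statehmm.glmhmm import ValidationError


def make_binned(x, p, counts=None, measure="pupil"):
    x = np.asarray(x, dtype=float)
    counts = np.full(len(x), 200) if counts is None else np.asarray(counts)
    probs = pd.DataFrame({"optimal": p, "disengaged": 1.0 - np.asarray(p)})
    edges = np.concatenate([[x[0] - 0.01], (x[1:] + x[:-1]) / 2, [x[-1] + 0.01]])
    return BinnedStateProb(
        measure=measure, bin_edges=edges, bin_centers=x, counts=counts, probs=probs
    )


class TestBinnedStateProb:
    def test_all_optimal_gives_probability_one(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"pupil": rng.random(500)})
        labels = np.array(["optimal"] * 500, dtype=object)
        b = binned_state_prob(feats, labels, "pupil", n_bins=5)
        assert np.allclose(b.probs.loc[b.counts > 0, "optimal"], 1.0)

    def test_independent_labels_match_global_occupancy(self):
        rng = np.random.default_rng(1)
        n = 20_000
        feats = pd.DataFrame({"pupil": rng.random(n)})
        labels = np.where(rng.random(n) < 0.3, "optimal", "disengaged").astype(object)
        b = binned_state_prob(feats, labels, "pupil", n_bins=10)
        for pk, nk in zip(b.probs["optimal"], b.counts):
            se = np.sqrt(0.3 * 0.7 / nk)
            assert abs(pk - 0.3) < 4 * se

    def test_row_normalization(self, trial_features, fitted):
        b = binned_state_prob(trial_features, fitted["stereotype_labels"], "pupil")
        occ = b.counts > 0
        total = b.probs.to_numpy()[occ].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError):
            binned_state_prob(pd.DataFrame({"x": [1.0]}), np.array(["optimal"]), "pupil")


class TestFitOptimalPupil:
    def test_noiseless_parabola_selects_degree_two(self):
        x = np.linspace(0.2, 0.9, 10)
        y = np.clip(0.8 - 3.0 * (x - 0.6) ** 2, 0, 1)
        fit = fit_optimal_pupil(make_binned(x, y))
        assert fit.degree == 2
        assert abs(fit.optimal_diameter - 0.6) < (0.9 - 0.2) / 500

    def test_monotone_curve_clamps_to_right_edge(self):
        x = np.linspace(0.2, 0.9, 10)
        fit = fit_optimal_pupil(make_binned(x, np.linspace(0.05, 0.9, 10)))
        assert np.isclose(fit.optimal_diameter, 0.9, atol=1e-6)

    def test_binomial_noise_recovery(self):
        """Probabilities drawn binomially (200 trials/bin) around an
        inverted-U with peak 0.55: recovered optimum within 0.05."""
        rng = np.random.default_rng(5)
        x = np.linspace(0.25, 0.85, 12)
        p_true = np.clip(0.75 - 4.0 * (x - 0.55) ** 2, 0.02, 1)
        y = rng.binomial(200, p_true) / 200
        fit = fit_optimal_pupil(make_binned(x, y))
        assert abs(fit.optimal_diameter - 0.55) < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            fit_optimal_pupil(make_binned([0.2, 0.4, 0.6, 0.8], [0, 0.5, 0.5, 0]))

    def test_optimum_always_inside_data_range(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0.2, 0.9, 10))
        y = rng.random(10)
        fit = fit_optimal_pupil(make_binned(x, y))
        assert x.min() <= fit.optimal_diameter <= x.max()


class TestAlignToOptimal:
    def test_zero_distance_at_optimum(self):
        x = np.linspace(0.2, 0.9, 10)
        fit = fit_optimal_pupil(make_binned(x, 0.8 - 3 * (x - 0.6) ** 2))
        feats = pd.DataFrame({"pupil": [fit.optimal_diameter]})
        out = align_to_optimal(feats, fit)
        assert np.isclose(out["distance"].iloc[0], 0.0, atol=1e-9)

    def test_symmetric_distribution(self):
        x = np.linspace(0.2, 0.9, 10)
        fit = fit_optimal_pupil(make_binned(x, 0.8 - 3 * (x - 0.55) ** 2))
        rng = np.random.default_rng(3)
        pupil = fit.optimal_diameter + rng.uniform(-0.2, 0.2, 4000)
        out = align_to_optimal(pd.DataFrame({"pupil": pupil}), fit)
        assert abs(out["distance"].mean()) < 0.01
        assert out["abs_distance"].mean() > 0.05

    def test_mean_abs_distance_ordering_on_pipeline(self, trial_features, fitted):
        """Trials labelled optimal sit closer to the optimal pupil than
        disengaged or sub-optimal trials (inverted-U signature)."""
        labels = fitted["stereotype_labels"]
        b = binned_state_prob(trial_features, labels, "pupil")
        fit = fit_optimal_pupil(b)
        out = align_to_optimal(trial_features, fit, stereotype_labels=labels)
        m = out.attrs["mean_abs_by_state"]
        assert m["optimal"] < m["disengaged"]
        assert m["optimal"] < m["bias_left"]


class TestQuadraticRegression:
    def test_recovers_negative_quadratic_coefficient(self):
        rng = np.random.default_rng(0)
        n = 6000
        feats = pd.DataFrame(
            {
                "pupil": rng.standard_normal(n),
                "face": rng.standard_normal(n),
                "locomotion": rng.standard_normal(n),
            }
        )
        target = 1.0 - feats["pupil"] ** 2 + 0.05 * rng.standard_normal(n)
        reg = quadratic_state_regression(feats, target, include_sd=False)
        c = reg.coefficients
        assert c["pupil^2"] < 0
        assert abs(c["pupil^2"] - (-1.0)) < 0.1
        assert reg.cv_r2 > 0.8

    def test_null_target_has_no_predictive_power(self):
        rng = np.random.default_rng(1)
        n = 5000
        feats = pd.DataFrame(
            {m: rng.standard_normal(n) for m in ("pupil", "face", "locomotion")}
        )
        reg = quadratic_state_regression(
            feats, rng.random(n), include_sd=False, seed=2
        )
        assert reg.cv_r2 <= 0.02

    def test_pure_interaction_target(self):
        rng = np.random.default_rng(2)
        n = 6000
        feats = pd.DataFrame(
            {
                "pupil": rng.standard_normal(n),
                "movement_index": rng.standard_normal(n),
            }
        )
        target = feats["pupil"] * feats["movement_index"] + 0.05 * rng.standard_normal(n)
        reg = quadratic_state_regression(
            feats, target, measures=("pupil", "movement_index"), include_sd=False
        )
        c = reg.coefficients
        assert abs(c["pupil:movement_index"] - 1.0) < 0.05
        for name in ("pupil", "movement_index", "pupil^2", "movement_index^2"):
            assert abs(c[name]) < 0.05


def test_stationary_mask_thresholds_locomotion():
    feats = pd.DataFrame({"locomotion": [0.0, 0.005, 0.01, 0.5, np.nan]})
    mask = arousal.stationary_mask(feats)
    assert mask.tolist() == [True, True, False, False, False]


class TestStateConditionedCorrelation:
    def test_perfect_linear_relation(self):
        feats = pd.DataFrame(
            {"pupil": np.linspace(0, 1, 50), "movement_index": 2 * np.linspace(0, 1, 50) + 1}
        )
        r = state_conditioned_correlation(feats, np.array(["optimal"] * 50, dtype=object))
        assert np.isclose(r["optimal"], 1.0)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        feats = pd.DataFrame(
            {"pupil": rng.standard_normal(n), "movement_index": rng.standard_normal(n)}
        )
        r = state_conditioned_correlation(feats, np.array(["optimal"] * n, dtype=object))
        assert abs(r["optimal"]) < 3 / np.sqrt(n)

    def test_too_few_trials_missing(self):
        feats = pd.DataFrame({"pupil": np.arange(5.0), "movement_index": np.arange(5.0)})
        r = state_conditioned_correlation(feats, np.array(["optimal"] * 5, dtype=object))
        assert np.isnan(r["optimal"])


class TestTransitionAlignedVariability:
    def test_constant_sd10_gives_zero_change(self, fitted):
        frames = []
        for seq in fitted["sequences"]:
            n = len(seq.labels)
            frames.append(
                pd.DataFrame(
                    {
                        "pupil_sd10": np.ones(n),
                        "face_sd10": np.ones(n),
                        "locomotion_sd10": np.ones(n),
                    }
                )
            )
        out = transition_aligned_variability(
            fitted["sequences"], frames, fitted["stereotypes"]
        )
        assert np.allclose(out["entry"].to_numpy(), 0.0, equal_nan=True)
        assert np.allclose(out["exit"].to_numpy(), 0.0, equal_nan=True)

    def test_no_optimal_epochs_warns_and_returns_empty(self):
        from statehmm.annotate import classify_stereotypes
        from statehmm.glmhmm import GLMHMMParams

        disengaged = GLMHMMParams(  # P(Nr) ~ 1 at every stimulus
            np.zeros((1, 3, 1)), np.array([[-9.0, -9.0, 0.0]]), np.ones((1, 1)), np.ones(1)
        )
        stereo = classify_stereotypes(disengaged, [-1, 1])
        labels = [np.zeros(20, int)]
        frames = [pd.DataFrame({c: np.ones(20) for c in
                                ("pupil_sd10", "face_sd10", "locomotion_sd10")})]
        with pytest.warns(UserWarning):
            out = transition_aligned_variability(labels, frames, stereo)
        assert out["n_entries"] == 0
        assert out["entry"].isna().all().all()

    def test_reduced_optimal_variability_shows_at_transitions(
        self, fitted, session_features
    ):
        """Synthetic optimal-state SDs are lower: variability drops after
        entering the optimal state and rises after leaving it."""
        out = transition_aligned_variability(
            fitted["sequences"], session_features, fitted["stereotypes"]
        )
        assert out["n_entries"] > 5 and out["n_exits"] > 5
        assert out["entry"].loc[1:, "pupil_sd10"].mean() < 0
        assert out["exit"].loc[1:, "pupil_sd10"].mean() > 0
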