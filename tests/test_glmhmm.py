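"""Core model tests: emissions, exact inference, EM, and the MAP objective."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statehmm import glmhmm
from statehmm.glmhmm import (
    GLMHMMParams,
    PriorConfig,
    ValidationError,
    em_fit,
    emission_logprobs,
    emission_probs,
    forward_backward,
    log_posterior,
)


def make_params(K=2, seed=0, sticky=0.9):
    return glmhmm.random_init(K, np.random.default_rng(seed), sticky=sticky)


def brute_force_loglik(params, U, y):
    """Path-enumeration oracle for the marginal likelihood."""
    T, K = len(y), params.n_states
    B = np.exp(emission_logprobs(params, U))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = params.init_probs[path[0]] * B[0, path[0], y[0]]
        for t in range(1, T):
            p *= params.transitions[path[t - 1], path[t]] * B[t, path[t], y[t]]
        total += p
    return np.log(total)


def brute_force_gamma(params, U, y):
    """Posterior state marginals by path enumeration."""
    T, K = len(y), params.n_states
    B = np.exp(emission_logprobs(params, U))
    gamma = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = params.init_probs[path[0]] * B[0, path[0], y[0]]
        for t in range(1, T):
            p *= params.transitions[path[t - 1], path[t]] * B[t, path[t], y[t]]
        for t, k in enumerate(path):
            gamma[t, k] += p
    return gamma / gamma.sum(axis=1, keepdims=True)


class TestEmissions:
    def test_zero_parameters_give_uniform_choice_probabilities(self):
        p = GLMHMMParams(np.zeros((1, 3, 1)), np.zeros((1, 3)), np.ones((1, 1)), np.ones(1))
        assert np.allclose(emission_probs(p, 0, 0.7), 1 / 3)

    def test_softmax_shift_invariance(self):
        w = np.array([[[-1.0], [2.0], [0.0]]])
        b = np.array([[0.5, -0.3, 0.0]])
        p1 = GLMHMMParams(w, b, np.ones((1, 1)), np.ones(1))
        probs1 = emission_probs(p1, 0, 0.4)
        # shifting every logit by a constant (breaking the gauge) must not
        # change the probabilities; compute directly
        logits = (w[0, :, 0] * 0.4 + b[0]) + 5.0
        probs2 = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(probs1, probs2, atol=1e-12)

    def test_hand_computed_softmax(self):
        # softmax of logits (-3, 3, 0)
        p = GLMHMMParams(
            np.array([[[-3.0], [3.0], [0.0]]]), np.zeros((1, 3)), np.ones((1, 1)), np.ones(1)
        )
        assert np.allclose(emission_probs(p, 0, 1.0), [0.0024, 0.9503, 0.0473], atol=5e-5)

    def test_probabilities_positive_and_normalized(self):
        p = make_params(3, seed=5)
        for k in range(3):
            probs = emission_probs(p, k, np.linspace(-1, 1, 7))
            assert np.all(probs > 0)
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_state_index_out_of_range(self):
        with pytest.raises(ValidationError):
            emission_probs(make_params(2), 2, 0.0)


class TestForwardBackward:
    def test_single_state_loglik_is_summed_emission(self):
        p = make_params(1, seed=3)
        rng = np.random.default_rng(0)
        U = rng.uniform(-1, 1, 50)[:, None]
        y = rng.integers(0, 3, 50)
        post = forward_backward(p, U, y)
        assert np.allclose(post.gamma, 1.0)
        expected = emission_logprobs(p, U)[np.arange(50), 0, y].sum()
        assert np.isclose(post.log_likelihood, expected, rtol=1e-12)

    def test_absorbing_chain_stays_in_initial_state(self):
        p = make_params(2, seed=1)
        p = GLMHMMParams(p.weights, p.biases, np.eye(2), np.array([1.0, 0.0]))
        rng = np.random.default_rng(2)
        U = rng.uniform(-1, 1, 20)[:, None]
        y = rng.integers(0, 3, 20)
        post = forward_backward(p, U, y)
        assert np.allclose(post.gamma[:, 0], 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        T=st.integers(1, 8),
        K=st.integers(1, 3),
    )
    def test_matches_path_enumeration(self, seed, T, K):
        rng = np.random.default_rng(seed)
        p = glmhmm.random_init(K, rng, sticky=0.6)
        U = rng.uniform(-1, 1, T)[:, None]
        y = rng.integers(0, 3, T)
        post = forward_backward(p, U, y)
        ll = brute_force_loglik(p, U, y)
        assert np.isclose(post.log_likelihood, ll, rtol=1e-10)
        assert np.allclose(post.gamma, brute_force_gamma(p, U, y), atol=1e-10)

    def test_long_sticky_chain_does_not_underflow(self):
        rng = np.random.default_rng(7)
        p = glmhmm.random_init(7, rng, sticky=0.95)
        U = rng.uniform(-1, 1, 2000)[:, None]
        y = rng.integers(0, 3, 2000)
        post = forward_backward(p, U, y)
        assert np.isfinite(post.log_likelihood)
        assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_nan_input_rejected(self):
        p = make_params(2)
        with pytest.raises(ValidationError):
            forward_backward(p, np.array([[np.nan]]), np.array([0]))


@pytest.fixture(scope="module")
def small_data():
    from statehmm import synthetic

    cfg = synthetic.GenerativeConfig(
        n_sessions=4, trials_per_session=150, seed=11,
        physio_coupling=synthetic.default_coupling(),
    )
    tables, _ = synthetic.simulate_trials(cfg)
    return [
        (
            tb["stimulus_value"].to_numpy()[:, None],
            np.array([("L", "R", "Nr").index(c) for c in tb["choice"]]),
        )
        for tb in tables
    ]


class TestEM:
    @pytest.mark.parametrize("mode", ["MLE", "MAP"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_objective_monotone_nondecreasing(self, small_data, mode, seed):
        fit = em_fit(small_data, 2, prior=PriorConfig(mode), seed=seed, max_iter=40)
        diffs = np.diff(fit.trace)
        assert np.all(diffs >= -1e-8)

    def test_single_state_fit_matches_sklearn_multinomial_mle(self, small_data):
        """K=1 EM reduces to a pooled multinomial logistic regression; the
        independent convex-optimization oracle is scikit-learn."""
        from sklearn.linear_model import LogisticRegression

        fit = em_fit(small_data, 1, seed=0, tol=1e-9, max_iter=50)
        U = np.concatenate([u for u, _ in small_data])
        y = np.concatenate([c for _, c in small_data])
        sk = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10).fit(U, y)
        grid = np.linspace(-1, 1, 21)[:, None]
        ours = np.exp(emission_logprobs(fit.params, grid)[:, 0, :])
        theirs = sk.predict_proba(grid)[:, np.argsort(sk.classes_)]
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_map_shrinks_toward_prior(self, small_data):
        mle = em_fit(small_data, 1, prior=PriorConfig("MLE"), seed=0).params
        mapf = em_fit(small_data, 1, prior=PriorConfig("MAP", gaussian_variance=0.1), seed=0).params
        assert np.sum(mapf.weights**2) < np.sum(mle.weights**2)

    def test_validation_errors(self, small_data):
        with pytest.raises(ValidationError):
            em_fit(small_data, 0)
        with pytest.raises(ValidationError):
            em_fit([], 2)


class TestLogPosterior:
    def test_mle_equals_summed_forward_loglik(self):
        p = make_params(2, seed=4)
        rng = np.random.default_rng(5)
        sessions = [
            (rng.uniform(-1, 1, 30)[:, None], rng.integers(0, 3, 30)) for _ in range(3)
        ]
        lp = log_posterior(p, sessions, PriorConfig("MLE"))
        ll = sum(forward_backward(p, U, y).log_likelihood for U, y in sessions)
        assert np.isclose(lp, ll, rtol=1e-12)

    def test_map_minus_mle_is_prior_logdensity(self):
        from scipy.stats import dirichlet, norm

        p = make_params(3, seed=6)
        rng = np.random.default_rng(7)
        sessions = [(rng.uniform(-1, 1, 20)[:, None], rng.integers(0, 3, 20))]
        prior = PriorConfig("MAP")
        diff = log_posterior(p, sessions, prior) - log_posterior(p, sessions, PriorConfig("MLE"))
        expect = 0.0
        for k in range(3):
            for c in range(2):
                expect += norm.logpdf(p.weights[k, c, 0], 0, np.sqrt(2))
                expect += norm.logpdf(p.biases[k, c], 0, np.sqrt(2))
            expect += dirichlet.logpdf(p.transitions[k], np.full(3, 2.0))
        assert np.isclose(diff, expect, rtol=1e-10)

    def test_map_prior_at_zero_weights_closed_form(self):
        from scipy.stats import dirichlet, norm

        K = 2
        p = GLMHMMParams(
            np.zeros((K, 3, 1)), np.zeros((K, 3)), np.full((K, K), 0.5), np.full(K, 0.5)
        )
        from statehmm.glmhmm import _log_prior

        lp = _log_prior(p, PriorConfig("MAP"))
        gauss = 2 * K * 2 * norm.logpdf(0.0, 0, np.sqrt(2))  # (w + b) x 2 cats x K
        dir_ = K * dirichlet.logpdf([0.5, 0.5], [2.0, 2.0])
        assert np.isclose(lp, gauss + dir_, rtol=1e-12)


class TestGaugeAndSymmetry:
    def test_label_permutation_leaves_likelihood_invariant(self):
        p = make_params(3, seed=8)
        rng = np.random.default_rng(9)
        U = rng.uniform(-1, 1, 40)[:, None]
        y = rng.integers(0, 3, 40)
        base = forward_backward(p, U, y).log_likelihood
        for perm in itertools.permutations(range(3)):
            assert np.isclose(
                forward_backward(p.permuted(list(perm)), U, y).log_likelihood,
                base,
                rtol=1e-10,
            )

    def test_gauge_fixing_rejected_when_violated(self):
        W = np.ones((1, 3, 1))
        with pytest.raises(ValidationError):
            GLMHMMParams(W, np.zeros((1, 3)), np.ones((1, 1)), np.ones(1))

    def test_params_json_roundtrip(self, tmp_path):
        p = make_params(3, seed=10)
        path = tmp_path / "params.json"
        p.to_json(path)
        q = GLMHMMParams.from_json(path)
        for attr in ("weights", "biases", "transitions", "init_probs"):
            assert np.array_equal(getattr(p, attr), getattr(q, attr))
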