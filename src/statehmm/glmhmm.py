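"""Multinomial-emission GLM-HMM: emissions, exact inference, and EM fitting.

The model segments trial-by-trial choice behavior into K discrete hidden
states. Each state k carries its own multinomial logistic regression
(a "psychometric GLM") mapping the scalar stimulus value u_t to a
probability over the three choice categories Left, Right and No-response:

    P(y_t = c | z_t = k, u_t) = softmax_c( w[k][c] . u_t + b[k][c] )

States evolve as a first-order Markov chain with a K x K row-stochastic
transition matrix A and an initial distribution pi; chains restart at every
session boundary and never span sessions.

The softmax over three categories is over-parameterized, so the
No-response category is fixed as the reference (w = b = 0 in every state).
Any other gauge yields identical choice probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

CATEGORIES = ("L", "R", "Nr")
N_CATEGORIES = 3
REFERENCE_CATEGORY = 2  # Nr: weights and bias pinned to zero (gauge)

__all__ = [
    "CATEGORIES",
    "GLMHMMParams",
    "PriorConfig",
    "StatePosterior",
    "emission_probs",
    "emission_logprobs",
    "forward_backward",
    "forward_filter",
    "em_fit",
    "log_posterior",
]


class ValidationError(ValueError):
    """Raised when inputs violate a model or data contract."""


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class GLMHMMParams:
    """Parameters of a K-state multinomial GLM-HMM.

    Attributes
    ----------
    weights : ndarray, shape (K, 3, D)
        Stimulus weights per state and category. Category order is
        ``("L", "R", "Nr")``; the Nr row is identically zero (gauge).
    biases : ndarray, shape (K, 3)
        Per-state per-category intercepts; Nr column is zero.
    transitions : ndarray, shape (K, K)
        Row-stochastic state transition matrix A.
    init_probs : ndarray, shape (K,)
        Initial state distribution pi (one chain start per session).
    """

    weights: np.ndarray
    biases: np.ndarray
    transitions: np.ndarray
    init_probs: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.init_probs = np.asarray(self.init_probs, dtype=float)
        if self.weights.ndim == 2:  # (K, C) scalar-input convenience
            self.weights = self.weights[:, :, None]
        self.validate()

    @property
    def n_states(self) -> int:
        return self.weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[2]

    def validate(self) -> None:
        K = self.n_states
        if self.weights.shape[:2] != (K, N_CATEGORIES):
            raise ValidationError(f"weights must be (K, 3, D); got {self.weights.shape}")
        if self.biases.shape != (K, N_CATEGORIES):
            raise ValidationError(f"biases must be (K, 3); got {self.biases.shape}")
        if self.transitions.shape != (K, K):
            raise ValidationError(f"transitions must be ({K}, {K}); got {self.transitions.shape}")
        if self.init_probs.shape != (K,):
            raise ValidationError(f"init_probs must be ({K},); got {self.init_probs.shape}")
        if np.any(self.transitions < 0) or not np.allclose(
            self.transitions.sum(axis=1), 1.0, atol=1e-10
        ):
            raise ValidationError("transition matrix rows must be nonnegative and sum to 1")
        if np.any(self.init_probs < 0) or not np.isclose(self.init_probs.sum(), 1.0, atol=1e-10):
            raise ValidationError("init_probs must be a probability distribution")
        if not (
            np.allclose(self.weights[:, REFERENCE_CATEGORY], 0.0)
            and np.allclose(self.biases[:, REFERENCE_CATEGORY], 0.0)
        ):
            raise ValidationError("reference category Nr must have zero weights and bias")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "transitions": self.transitions.tolist(),
            "init_probs": self.init_probs.tolist(),
            "categories": list(CATEGORIES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLMHMMParams":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            biases=np.asarray(d["biases"], dtype=float),
            transitions=np.asarray(d["transitions"], dtype=float),
            init_probs=np.asarray(d["init_probs"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GLMHMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def permuted(self, perm: Sequence[int]) -> "GLMHMMParams":
        """Return the model with states relabelled by ``perm`` (new = old[perm])."""
        p = np.asarray(perm)
        return GLMHMMParams(
            weights=self.weights[p],
            biases=self.biases[p],
            transitions=self.transitions[np.ix_(p, p)],
            init_probs=self.init_probs[p],
        )


@dataclass
class PriorConfig:
    """MAP prior: zero-mean Gaussian on GLM parameters, Dirichlet on A rows."""

    mode: Literal["MLE", "MAP"] = "MLE"
    gaussian_variance: float = 2.0
    dirichlet_alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("MLE", "MAP"):
            raise ValidationError(f"mode must be 'MLE' or 'MAP', got {self.mode!r}")
        if self.gaussian_variance <= 0 or self.dirichlet_alpha <= 0:
            raise ValidationError("prior hyperparameters must be positive")

    @property
    def is_map(self) -> bool:
        return self.mode == "MAP"


@dataclass
class StatePosterior:
    """Smoothed posteriors for one session: gamma (T, K), summed transition
    posteriors xi (K, K), and the session log marginal likelihood."""

    gamma: np.ndarray
    xi: np.ndarray
    log_likelihood: float

    def __post_init__(self) -> None:
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-10):
            raise ValidationError("posterior rows must sum to 1")


# ---------------------------------------------------------------------------
# Emissions


def _as_inputs(u, n_inputs: int) -> np.ndarray:
    U = np.asarray(u, dtype=float)
    if U.ndim == 0:
        U = U.reshape(1, 1)
    elif U.ndim == 1:
        U = U[:, None] if n_inputs == 1 else U[None, :]
    if not np.all(np.isfinite(U)):
        raise ValidationError("stimulus inputs must be finite")
    if U.shape[1] != n_inputs:
        raise ValidationError(f"expected {n_inputs}-dimensional inputs, got {U.shape[1]}")
    return U


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def emission_logprobs(params: GLMHMMParams, U: np.ndarray) -> np.ndarray:
    """Log emission probabilities, shape (T, K, 3), for inputs U (T, D)."""
    logits = np.einsum("td,kcd->tkc", U, params.weights) + params.biases[None]
    return _log_softmax(logits)


def emission_probs(params: GLMHMMParams, k: int, u) -> np.ndarray:
    """Choice probabilities over (L, R, Nr) for state ``k`` at stimulus ``u``.

    ``u`` may be a scalar (returns shape (3,)) or an array of T stimuli
    (returns (T, 3)).
    """
    if not 0 <= k < params.n_states:
        raise ValidationError(f"state index {k} out of range for K={params.n_states}")
    scalar = np.ndim(u) == 0
    U = _as_inputs(u, params.n_inputs)
    out = np.exp(emission_logprobs(params, U)[:, k, :])
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Inference

_TINY = 1e-300


def _session_arrays(params: GLMHMMParams, inputs, choices):
    U = _as_inputs(inputs, params.n_inputs)
    y = np.asarray(choices)
    if y.dtype.kind in "US":
        y = np.array([CATEGORIES.index(c) for c in y])
    y = y.astype(int)
    if len(y) != len(U):
        raise ValidationError("inputs and choices must have equal length")
    if len(y) == 0:
        raise ValidationError("session must contain at least one trial")
    if np.any((y < 0) | (y >= N_CATEGORIES)):
        raise ValidationError("choice codes must be in {0, 1, 2}")
    return U, y


def _fb_core_py(pi, A, B):
    """Scaled forward-backward recursions on precomputed emission
    likelihoods B (T, K). Returns (gamma, xi, log_likelihood); the
    log-likelihood is -inf when the data are impossible under the model."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        return alpha, np.zeros((K, K)), -np.inf
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:
            return alpha, np.zeros((K, K)), -np.inf
        alpha[t] = a / c[t]

    beta_next = np.ones(K)
    xi = np.zeros((K, K))
    gamma = np.empty((T, K))
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta_next
        beta = (A @ bb) / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi[i, j] += alpha[t, i] * A[i, j] * bb[j] / c[t + 1]
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
        beta_next = beta
    return gamma, xi, float(np.log(c).sum())


def _filter_core_py(pi, A, B):
    T, K = B.shape
    alpha = np.empty((T, K))
    a = pi * B[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        alpha[t] = a / a.sum()
    return alpha


try:  # JIT-compiled recursions; the pure-numpy path is the fallback
    from numba import njit

    _fb_core = njit(cache=True)(_fb_core_py)
    _filter_core = njit(cache=True)(_filter_core_py)
except ImportError:  # pragma: no cover
    _fb_core = _fb_core_py
    _filter_core = _filter_core_py


def forward_backward(params: GLMHMMParams, inputs, choices) -> StatePosterior:
    """Exact smoothing for one session via the scaled forward-backward
    recursions (emissions evaluated in the log domain; per-step
    normalization keeps T=2000, K=7 chains from underflowing).
    """
    U, y = _session_arrays(params, inputs, choices)
    T = len(y)
    B = np.exp(emission_logprobs(params, U)[np.arange(T), :, y])  # (T, K)
    gamma, xi, ll = _fb_core(params.init_probs, params.transitions, B)
    if not np.isfinite(ll):
        raise ValidationError("data have zero likelihood under the model")
    return StatePosterior(gamma=gamma, xi=xi, log_likelihood=float(ll))


def forward_filter(params: GLMHMMParams, inputs, choices) -> np.ndarray:
    """Filtered state probabilities p(z_t | y_1..t), shape (T, K)."""
    U, y = _session_arrays(params, inputs, choices)
    B = np.exp(emission_logprobs(params, U)[np.arange(len(y)), :, y])
    return _filter_core(params.init_probs, params.transitions, B)


# ---------------------------------------------------------------------------
# Objective (log-likelihood / log-posterior)


def _log_prior(params: GLMHMMParams, prior: PriorConfig) -> float:
    """Log density of the MAP prior at ``params`` (0 in MLE mode)."""
    if not prior.is_map:
        return 0.0
    v = prior.gaussian_variance
    free = params.n_states * (N_CATEGORIES - 1) * (params.n_inputs + 1)
    ss = float(np.sum(params.weights[:, :REFERENCE_CATEGORY] ** 2)) + float(
        np.sum(params.biases[:, :REFERENCE_CATEGORY] ** 2)
    )
    lp = -0.5 * free * np.log(2 * np.pi * v) - ss / (2 * v)
    a = prior.dirichlet_alpha
    K = params.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(params.transitions)
    # Dirichlet(alpha, ..., alpha) log pdf per row, including normalizer
    lp += K * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * float(logA.sum())
    return float(lp)


def log_posterior(params: GLMHMMParams, sessions, prior: PriorConfig | None = None) -> float:
    """Summed session log-likelihoods, plus the prior log-density in MAP mode.

    ``sessions`` is a sequence of (inputs, choices) pairs.
    """
    prior = prior or PriorConfig()
    ll = sum(forward_backward(params, U, y).log_likelihood for U, y in sessions)
    return float(ll + _log_prior(params, prior))


# ---------------------------------------------------------------------------
# EM


def _pack(weights_k: np.ndarray, biases_k: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [weights_k[:REFERENCE_CATEGORY].ravel(), biases_k[:REFERENCE_CATEGORY]]
    )


def _unpack(theta: np.ndarray, D: int):
    nw = (N_CATEGORIES - 1) * D
    W = np.zeros((N_CATEGORIES, D))
    b = np.zeros(N_CATEGORIES)
    W[:REFERENCE_CATEGORY] = theta[:nw].reshape(N_CATEGORIES - 1, D)
    b[:REFERENCE_CATEGORY] = theta[nw:]
    return W, b


def _weighted_multinomial_nll(theta, U, Yonehot, g, var):
    """Gamma-weighted multinomial NLL (+ Gaussian penalty) and its gradient."""
    D = U.shape[1]
    W, b = _unpack(theta, D)
    logits = U @ W.T + b  # (T, C)
    logp = _log_softmax(logits)
    nll = -float(np.sum(g[:, None] * Yonehot * logp))
    P = np.exp(logp)
    R = g[:, None] * (P - Yonehot)  # (T, C)
    gW = R.T @ U  # (C, D)
    gb = R.sum(axis=0)
    grad = _pack(gW, gb)
    if var is not None:
        nll += float(theta @ theta) / (2 * var)
        grad = grad + theta / var
    return nll, grad


def _fit_state_glm(U, Yonehot, g, theta0, var):
    """Maximize the expected complete-data GLM term for one state."""
    res = minimize(
        _weighted_multinomial_nll,
        theta0,
        args=(U, Yonehot, g, var),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    f0, _ = _weighted_multinomial_nll(theta0, U, Yonehot, g, var)
    if res.fun <= f0:
        return res.x
    return theta0  # never move downhill: EM stays monotone


def random_init(
    K: int,
    rng: np.random.Generator,
    n_inputs: int = 1,
    sticky: float = 0.9,
) -> GLMHMMParams:
    """Random starting point: sticky transitions, uniform pi, N(0,1) GLMs."""
    A = sticky * np.eye(K) + (1 - sticky) * rng.dirichlet(np.ones(K), size=K)
    A /= A.sum(axis=1, keepdims=True)
    W = np.zeros((K, N_CATEGORIES, n_inputs))
    b = np.zeros((K, N_CATEGORIES))
    W[:, :REFERENCE_CATEGORY] = rng.standard_normal((K, N_CATEGORIES - 1, n_inputs))
    b[:, :REFERENCE_CATEGORY] = rng.standard_normal((K, N_CATEGORIES - 1))
    return GLMHMMParams(W, b, A, np.full(K, 1.0 / K))


@dataclass
class FitResult:
    """EM output: fitted parameters plus the per-iteration objective trace."""

    params: GLMHMMParams
    trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def log_posterior(self) -> float:
        return self.trace[-1]


def em_fit(
    sessions,
    K: int,
    prior: PriorConfig | None = None,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    init: GLMHMMParams | None = None,
    estimate_init_probs: bool = True,
) -> FitResult:
    """Fit a K-state GLM-HMM by EM, maximizing the log-likelihood (MLE) or
    log-posterior (MAP).

    Each session is an independent chain: forward-backward restarts from pi
    at every session and expected transitions never span session boundaries.
    The M-step updates A and pi in closed form from expected counts (plus
    Dirichlet pseudo-counts under MAP) and each state's GLM by L-BFGS on the
    gamma-weighted multinomial log-likelihood (plus the Gaussian penalty
    under MAP). The objective is non-decreasing; iteration stops when the
    improvement drops below ``tol`` or at ``max_iter``.
    """
    prior = prior or PriorConfig()
    if K < 1:
        raise ValidationError("K must be >= 1")
    if len(sessions) == 0:
        raise ValidationError("need at least one session")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_inputs = np.atleast_2d(np.asarray(sessions[0][0], dtype=float)).shape[-1]
    params = init if init is not None else random_init(K, rng, n_inputs=n_inputs)
    data = [_session_arrays(params, U, y) for U, y in sessions]
    U_all = np.concatenate([U for U, _ in data])
    y_all = np.concatenate([y for _, y in data])
    Y1h = np.eye(N_CATEGORIES)[y_all]
    var = prior.gaussian_variance if prior.is_map else None
    pseudo = (prior.dirichlet_alpha - 1.0) if prior.is_map else 0.0

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        posts = [forward_backward(params, U, y) for U, y in data]
        obj = sum(p.log_likelihood for p in posts) + _log_prior(params, prior)
        if trace and obj < trace[-1] - 1e-8:
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: {trace[-1]:.10g} -> {obj:.10g}"
            )
        done = bool(trace) and (obj - trace[-1] < tol)
        trace.append(float(obj))
        if done:
            converged = True
            break

        # M-step: transitions and initial distribution
        xi = np.sum([p.xi for p in posts], axis=0)
        if K > 1:
            A = xi + pseudo
            rowsum = A.sum(axis=1, keepdims=True)
            A = np.where(rowsum > 0, A / np.where(rowsum == 0, 1, rowsum), 1.0 / K)
        else:
            A = np.ones((1, 1))
        if estimate_init_probs:
            pi0 = np.sum([p.gamma[0] for p in posts], axis=0)
            pi0 = pi0 / pi0.sum()
        else:
            pi0 = np.full(K, 1.0 / K)

        # M-step: per-state GLMs on pooled trials
        G = np.concatenate([p.gamma for p in posts], axis=0)  # (T_total, K)
        W = np.zeros_like(params.weights)
        b = np.zeros_like(params.biases)
        for k in range(K):
            theta0 = _pack(params.weights[k], params.biases[k])
            theta = _fit_state_glm(U_all, Y1h, G[:, k], theta0, var)
            W[k], b[k] = _unpack(theta, params.n_inputs)
        params = GLMHMMParams(W, b, A, pi0)

    return FitResult(params=params, trace=trace, converged=converged, n_iter=it)
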