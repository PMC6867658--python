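"""Reward-gated hidden Markov model of explore/exploit choice dynamics.

The model has seven latent states -- one explore state plus one rule state
per stimulus feature -- and two transition *plates*, selected by whether the
previous trial was rewarded. Parameters are tied: every rule state shares the
same stay probability (falling back to explore otherwise), the explore state
transitions to each of the six rules with equal probability, and direct
rule-to-rule transitions are forbidden. Each plate therefore has two free
parameters, four in total (:class:`setshift.agent.AgentParams`).

Emissions: a rule state deterministically produces the option carrying its
feature (probability zero for any other choice); the explore state chooses
uniformly among the three options. Sessions are assumed to start in explore.

This module provides the inference machinery: likelihoods via scaled
forward-backward, Baum-Welch EM with tied-parameter M-steps and random
restarts, Viterbi decoding, and stationary-distribution ("attractor depth")
analysis of the fitted plates.

Note the fitted model's explore-to-rule transition is uniform over all six
rules; the generative simulator in :mod:`setshift.agent` instead constrains
the adopted rule to a feature of the last choice. Both conventions are
deliberate and kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .agent import EXPLORE, AgentParams, rule_state
from .env import FEATURES
from .stats import session_arrays

#: Latent-state labels in canonical order; index 0 is explore.
STATES = (EXPLORE,) + tuple(rule_state(f) for f in FEATURES)
N_STATES = 7

_PARAM_FLOOR = 1e-6  # keeps all transition rows strictly positive during EM


class StationaryNotFound(Exception):
    """Raised when a transition plate has no unique stationary distribution."""


@dataclass(frozen=True)
class TransitionPlates:
    """Row-stochastic 7x7 transition matrices, one per reward outcome."""

    A_rwd: np.ndarray
    A_norwd: np.ndarray

    def plate(self, reward: int) -> np.ndarray:
        return self.A_rwd if reward else self.A_norwd


def _plate(p_rule_stay: float, p_explore_stay: float) -> np.ndarray:
    A = np.zeros((N_STATES, N_STATES))
    A[0, 0] = p_explore_stay
    A[0, 1:] = (1.0 - p_explore_stay) / 6.0
    for i in range(1, N_STATES):
        A[i, i] = p_rule_stay
        A[i, 0] = 1.0 - p_rule_stay
    return A


def build_transition_plates(params: AgentParams) -> TransitionPlates:
    """Tied transition matrices for both reward plates.

    Raises ValueError (via AgentParams validation) for out-of-range
    probabilities.
    """
    return TransitionPlates(
        A_rwd=_plate(params.p_rule_stay_rwd, params.p_explore_stay_rwd),
        A_norwd=_plate(params.p_rule_stay_norwd, params.p_explore_stay_norwd),
    )


def emission_matrix(session: pd.DataFrame) -> np.ndarray:
    """T x 7 emission probabilities of the observed choices.

    Explore emits any option with probability 1/3; rule state f emits
    probability 1 if the chosen option carries feature f, else 0.
    """
    a = session_arrays(session)
    T = len(a["reward"])
    B = np.zeros((T, N_STATES))
    B[:, 0] = 1.0 / 3.0
    for i in range(3):
        B[:, 1 + i] = a["chosen_color"] == i
        B[:, 4 + i] = a["chosen_shape"] == i
    return B


def _forward_backward(B: np.ndarray, rewards: np.ndarray, plates: TransitionPlates):
    """Scaled forward-backward. Returns (loglik, gamma, alphahat, betahat, c).

    The initial distribution is a point mass on explore. An impossible
    observation sequence yields loglik = -inf with NaN posteriors.
    """
    T = B.shape[0]
    alphahat = np.zeros((T, N_STATES))
    c = np.zeros(T)
    a0 = np.zeros(N_STATES)
    a0[0] = B[0, 0]
    c[0] = a0.sum()
    if c[0] <= 0:
        return -np.inf, np.full((T, N_STATES), np.nan), None, None, None
    alphahat[0] = a0 / c[0]
    A = [plates.A_norwd, plates.A_rwd]
    for t in range(1, T):
        pred = alphahat[t - 1] @ A[rewards[t - 1]]
        at = pred * B[t]
        c[t] = at.sum()
        if c[t] <= 0:
            return -np.inf, np.full((T, N_STATES), np.nan), None, None, None
        alphahat[t] = at / c[t]
    betahat = np.zeros((T, N_STATES))
    betahat[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        betahat[t] = (A[rewards[t]] @ (B[t + 1] * betahat[t + 1])) / c[t + 1]
    gamma = alphahat * betahat
    gamma /= gamma.sum(axis=1, keepdims=True)
    return float(np.log(c).sum()), gamma, alphahat, betahat, c


def forward_backward(session: pd.DataFrame, params: AgentParams):
    """(log-likelihood, per-trial state posteriors) for one session.

    The log-likelihood is log P(choices | rewards, params) under the tied
    7-state model starting in explore.
    """
    B = emission_matrix(session)
    rewards = session["reward"].to_numpy().astype(int)
    loglik, gamma, *_ = _forward_backward(B, rewards, build_transition_plates(params))
    return loglik, gamma


@dataclass
class HMMFit:
    params: AgentParams
    loglik: float
    posteriors: np.ndarray
    viterbi_path: np.ndarray
    n_restarts: int
    seed: object
    converged: bool = True
    degenerate: bool = False
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_session_list(sessions):
    if isinstance(sessions, pd.DataFrame):
        return [sessions]
    return list(sessions)


def _em_single(Bs, rewards_list, init: AgentParams, tol: float, max_iter: int):
    """Baum-Welch on one or more sessions (pooled M-step). Returns (params, ll, history)."""
    params = init
    history = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        plates = build_transition_plates(params)
        ll_total = 0.0
        # pooled expected counts: [plate][rule/explore] numerators & denominators
        num = np.zeros((2, 2))
        den = np.zeros((2, 2))
        diag = {1: np.diag(plates.A_rwd), 0: np.diag(plates.A_norwd)}
        for B, rewards in zip(Bs, rewards_list):
            ll, gamma, alphahat, betahat, c = _forward_backward(B, rewards, plates)
            if not np.isfinite(ll):
                return params, -np.inf, np.array(history)
            ll_total += ll
            if B.shape[0] < 2:
                continue
            for k in (0, 1):
                mask = rewards[:-1] == k
                if not mask.any():
                    continue
                D = (
                    alphahat[:-1][mask]
                    * diag[k][None, :]
                    * (B[1:][mask] * betahat[1:][mask])
                    / c[1:][mask][:, None]
                )
                g = gamma[:-1][mask]
                num[k, 0] += D[:, 0].sum()
                den[k, 0] += g[:, 0].sum()
                num[k, 1] += D[:, 1:].sum()
                den[k, 1] += g[:, 1:].sum()
        history.append(ll_total)
        if ll_total - prev_ll < tol * max(abs(ll_total), 1.0) and len(history) > 1:
            prev_ll = ll_total
            break
        prev_ll = ll_total

        def _ratio(k, j, current):
            if den[k, j] <= 0:
                return current
            return float(np.clip(num[k, j] / den[k, j], _PARAM_FLOOR, 1 - _PARAM_FLOOR))

        params = AgentParams(
            p_rule_stay_rwd=_ratio(1, 1, params.p_rule_stay_rwd),
            p_explore_stay_rwd=_ratio(1, 0, params.p_explore_stay_rwd),
            p_rule_stay_norwd=_ratio(0, 1, params.p_rule_stay_norwd),
            p_explore_stay_norwd=_ratio(0, 0, params.p_explore_stay_norwd),
        )
    return params, prev_ll, np.array(history)


def fit_em(
    sessions,
    n_restarts: int = 100,
    seed=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> HMMFit:
    """Fit the tied ioHMM by Baum-Welch EM with random restarts.

    ``sessions`` may be a single session table or a list (pooled fit). Each
    restart initializes the four stay probabilities uniformly in (0.05, 0.95)
    and iterates until the relative log-likelihood improvement falls below
    ``tol``; the restart with the highest observed-data log-likelihood wins.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    session_list = _as_session_list(sessions)
    Bs = [emission_matrix(s) for s in session_list]
    rewards_list = [s["reward"].to_numpy().astype(int) for s in session_list]
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_restarts):
        init = AgentParams(*rng.uniform(0.05, 0.95, size=4))
        params, ll, history = _em_single(Bs, rewards_list, init, tol, max_iter)
        if best is None or ll > best[1]:
            best = (params, ll, history)
    params, ll, history = best
    degenerate = not np.isfinite(ll)

    _, gamma, *_ = _forward_backward(
        Bs[0], rewards_list[0], build_transition_plates(params)
    )
    path = viterbi_decode(session_list[0], params)
    return HMMFit(
        params=params,
        loglik=ll,
        posteriors=gamma,
        viterbi_path=path,
        n_restarts=n_restarts,
        seed=seed,
        converged=len(history) < max_iter,
        degenerate=degenerate,
        loglik_history=history,
    )


def viterbi_decode(session: pd.DataFrame, params: AgentParams) -> np.ndarray:
    """Most probable a-posteriori latent-state sequence (array of state labels).

    Starts in explore (the initial distribution is a point mass there) and
    never steps between two different rule states. Ties break toward explore,
    i.e. toward the lowest state index.
    """
    B = emission_matrix(session)
    rewards = session["reward"].to_numpy().astype(int)
    plates = build_transition_plates(params)
    T = B.shape[0]
    with np.errstate(divide="ignore"):
        logB = np.log(B)
        logA = [np.log(plates.A_norwd), np.log(plates.A_rwd)]
    delta = np.full((T, N_STATES), -np.inf)
    psi = np.zeros((T, N_STATES), dtype=int)
    delta[0, 0] = logB[0, 0]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + logA[rewards[t - 1]]
        psi[t] = np.argmax(scores, axis=0)
        delta[t] = scores[psi[t], np.arange(N_STATES)] + logB[t]
    path = np.zeros(T, dtype=int)
    path[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return np.array([STATES[i] for i in path])


def decode_states(
    session: pd.DataFrame, params: AgentParams, method: str = "viterbi"
) -> np.ndarray:
    """Per-trial 'most probable cause' labels, by Viterbi path (default) or
    by the argmax of the smoothed posteriors."""
    if method == "viterbi":
        return viterbi_decode(session, params)
    if method == "posterior":
        _, gamma = forward_backward(session, params)
        return np.array([STATES[i] for i in np.argmax(gamma, axis=1)])
    raise ValueError(f"unknown decoding method {method!r}")


@dataclass
class StationaryResult:
    """Stationary distributions of both plates and their explore entries."""

    pi_rwd: np.ndarray
    pi_norwd: np.ndarray
    explore_depth_rwd: float
    explore_depth_norwd: float


def stationary_explore_closed_form(p_rule_stay: float, p_explore_stay: float) -> float:
    """Explore occupancy of the collapsed 2-state (explore vs generic rule) chain.

    Because rule parameters are tied, each plate reduces to two effective
    states with stationary explore mass (1 - a) / ((1 - a) + (1 - b)) where a
    is the rule-stay and b the explore-stay probability.
    """
    a, b = p_rule_stay, p_explore_stay
    denom = (1.0 - a) + (1.0 - b)
    if denom <= 0:
        raise StationaryNotFound("both states absorbing; no unique stationary distribution")
    return (1.0 - a) / denom


def _stationary_vector(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    w, vl = scipy.linalg.eig(A, left=True, right=False)
    idx = np.flatnonzero(np.abs(w - 1.0) < tol)
    if len(idx) != 1:
        raise StationaryNotFound(
            f"eigenvalue-1 multiplicity {len(idx)}; no unique stationary distribution"
        )
    v = np.real(vl[:, idx[0]])
    v = v / v.sum()
    if np.any(v < -1e-10):
        raise StationaryNotFound("eigenvalue-1 left eigenvector is not a distribution")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_distribution(plates: TransitionPlates) -> StationaryResult:
    """Left eigenvalue-1 eigenvectors of both plates and the explore 'depth'.

    The explore entry of each stationary distribution is the relative depth
    of the exploration attractor under that plate's dynamics. Raises
    :class:`StationaryNotFound` when a plate has no unique nonnegative
    eigenvalue-1 left eigenvector.
    """
    pi_rwd = _stationary_vector(plates.A_rwd)
    pi_norwd = _stationary_vector(plates.A_norwd)
    return StationaryResult(
        pi_rwd=pi_rwd,
        pi_norwd=pi_norwd,
        explore_depth_rwd=float(pi_rwd[0]),
        explore_depth_norwd=float(pi_norwd[0]),
    )
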