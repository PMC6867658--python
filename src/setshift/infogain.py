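"""One-trial-memory Bayesian model of directed exploration.

Scores candidate choices in the set-shifting task by how much information
they are expected to yield about which stimulus feature is currently the
rewarded rule. The decision-maker tracks a belief -- a probability vector
over the N_f = 6 features -- that each feature is the best one, initialized
uniformly, updated by one trial's evidence, and then asked: which next choice
(repeating 0, 1, or 2 features of the last choice) most reduces the entropy
of that belief?

Evidence model: after a rewarded choice each of the two chosen features has
likelihood 1/2 of being the rule and the others 0; after an unrewarded choice
the chosen features have likelihood 0 and the remaining N_f - 2 features are
equally likely. Tiny half-normal noise (|N(0, 1e-4)|) can be added to exact
zeros so that entropies stay computable; every function also runs in an exact
noise-free mode for closed-form checks.

Entropies are in bits.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

N_FEATURES = 6
_NOISE_SD = 1e-4


def entropy_bits(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def init_prior(n_features: int = N_FEATURES) -> np.ndarray:
    """Uniform prior that each feature is the best one."""
    if n_features < 3:
        raise ValueError("need at least 3 features")
    return np.full(n_features, 1.0 / n_features)


def likelihood(
    choice_features: tuple[int, int],
    reward: bool,
    rng: np.random.Generator | None = None,
    n_features: int = N_FEATURES,
) -> np.ndarray:
    """Per-feature likelihood that it is the best, after one observed outcome.

    ``choice_features`` are the two distinct feature indices of the chosen
    option. If ``rng`` is given, absolute-value Gaussian noise replaces exact
    zeros; otherwise the vector is exact.
    """
    f1, f2 = choice_features
    if f1 == f2:
        raise ValueError("chosen features must be distinct")
    lik = np.zeros(n_features)
    if reward:
        lik[[f1, f2]] = 0.5
    else:
        lik[:] = 1.0 / (n_features - 2)
        lik[[f1, f2]] = 0.0
    if rng is not None:
        zeros = lik == 0.0
        lik[zeros] = np.abs(rng.normal(0.0, _NOISE_SD, size=int(zeros.sum())))
    return lik


def posterior(prior: np.ndarray, lik: np.ndarray) -> np.ndarray:
    """Elementwise product of prior and likelihood, renormalized."""
    post = np.asarray(prior, dtype=float) * np.asarray(lik, dtype=float)
    total = post.sum()
    if total <= 0:
        raise ValueError("prior and likelihood have disjoint support")
    return post / total


def one_trial_prior(
    choice_features: tuple[int, int],
    reward: bool,
    rng: np.random.Generator | None = None,
    n_features: int = N_FEATURES,
) -> np.ndarray:
    """Belief after one observed choice/outcome, starting from a uniform prior."""
    return posterior(init_prior(n_features), likelihood(choice_features, reward, rng, n_features))


def expected_information_gain(
    prior: np.ndarray,
    candidate_features: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """(expected entropy drop in bits, reward probability) for a candidate choice.

    The reward probability is the prior mass on the candidate's two features
    (features are mutually exclusive as "best", so the masses add). The
    expected future entropy averages the rewarded and unrewarded posteriors,
    weighted by that probability; the gain is prior entropy minus it.
    """
    prior = np.asarray(prior, dtype=float)
    n = len(prior)
    f1, f2 = candidate_features
    p_reward = float(prior[f1] + prior[f2])
    h_now = entropy_bits(prior)
    h_next = 0.0
    for rewarded, weight in ((True, p_reward), (False, 1.0 - p_reward)):
        if weight <= 0:
            continue
        lik = likelihood(candidate_features, rewarded, rng, n)
        try:
            post = posterior(prior, lik)
        except ValueError:
            continue  # impossible future given the prior; weight is ~0
        h_next += weight * entropy_bits(post)
    return h_now - h_next, p_reward


def candidate_sets(prev_choice: tuple[int, int], n_features: int = N_FEATURES):
    """Concrete candidate choices by change type, relative to the last choice.

    Features 0..2 are colors, 3..5 shapes (matching ``env.FEATURES``); a valid
    choice pairs one color with one shape. Returns a dict mapping 0/1/2
    (number of changed dimensions) to lists of feature pairs.
    """
    c0, s0 = sorted(prev_choice)
    if not (c0 < 3 <= s0):
        raise ValueError("previous choice must pair one color with one shape")
    other_colors = [c for c in range(3) if c != c0]
    other_shapes = [s for s in range(3, n_features) if s != s0]
    return {
        0: [(c0, s0)],
        1: [(c0, s) for s in other_shapes] + [(c, s0) for c in other_colors],
        2: list(itertools.product(other_colors, other_shapes)),
    }


def rank_choice_types(
    prior: np.ndarray,
    prev_choice: tuple[int, int] = (0, 3),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean information gain and reward probability per change type (0/1/2).

    Averages over the concrete candidates of each type; the returned frame is
    indexed by change type with columns ``gain`` and ``p_reward``, plus rank
    columns (1 = best).
    """
    rows = {}
    for change, cands in candidate_sets(prev_choice).items():
        gains, prs = zip(
            *(expected_information_gain(prior, cand, rng) for cand in cands)
        )
        rows[change] = {"gain": float(np.mean(gains)), "p_reward": float(np.mean(prs))}
    table = pd.DataFrame(rows).T
    table["gain_rank"] = table["gain"].rank(ascending=False).astype(int)
    table["p_reward_rank"] = table["p_reward"].rank(ascending=False).astype(int)
    return table


def s2_style_table(
    prev_choice: tuple[int, int] = (0, 3),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Gain and reward probability per change type per previous-outcome condition.

    For each previous outcome (reward delivery / omission) the belief is the
    one-trial update of the uniform prior, and every candidate change type is
    scored against it.
    """
    frames = []
    for outcome, rewarded in (("reward", True), ("omission", False)):
        prior = one_trial_prior(prev_choice, rewarded, rng)
        table = rank_choice_types(prior, prev_choice, rng).reset_index(names="change")
        table.insert(0, "previous_outcome", outcome)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)
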