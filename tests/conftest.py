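import numpy as np
import pandas as pd
import pytest

from setshift import agent
from setshift.agent import AgentParams
from setshift.env import COLORS, FEATURES, PERMUTATIONS, SHAPES

# Baseline per-session parameter estimates for the more exploratory subject
# (reward plate: rule-stay 0.978, explore-stay 0.73; omission plate: 0.02, 0.28).
MONKEY_B_BASELINE = AgentParams(
    p_rule_stay_rwd=0.978,
    p_explore_stay_rwd=0.73,
    p_rule_stay_norwd=0.02,
    p_explore_stay_norwd=0.28,
)


@pytest.fixture(scope="session")
def monkey_b_params():
    return MONKEY_B_BASELINE


@pytest.fixture(scope="session")
def optimal_params():
    return agent.REWARD_OPTIMAL_PARAMS


@pytest.fixture(scope="session")
def session_b():
    """One 600-trial session at the baseline parameter set."""
    return agent.simulate_session(MONKEY_B_BASELINE, 600, seed=7)


@pytest.fixture(scope="session")
def session_optimal():
    """One 500-trial session at the reward-optimal parameter set."""
    return agent.simulate_session(agent.REWARD_OPTIMAL_PARAMS, 500, seed=11)


def make_session(
    chosen,
    rewards,
    blocks=None,
    rules=None,
    session_id="test",
    monkey="B",
    condition="pre",
):
    """Build a session table from an explicit choice sequence.

    ``chosen`` is a list of (color, shape) name pairs; each trial's option set
    is a bijection containing the chosen stimulus. Rewards and block indices
    are taken as given (consistency with the rule column is not enforced, so
    tests can construct exact scenarios).
    """
    n = len(chosen)
    rewards = list(rewards)
    blocks = list(blocks) if blocks is not None else [0] * n
    rules = list(rules) if rules is not None else [FEATURES[0]] * n
    data = {
        "session_id": [session_id] * n,
        "monkey": [monkey] * n,
        "condition": [condition] * n,
        "trial_index": list(range(1, n + 1)),
        "block_index": blocks,
        "rule": rules,
    }
    opt_cols = {f"opt{j}_color": [] for j in (1, 2, 3)}
    opt_shps = {f"opt{j}_shape": [] for j in (1, 2, 3)}
    choice_idx = []
    for color, shape in chosen:
        ci, si = COLORS.index(color), SHAPES.index(shape)
        perm = next(p for p in PERMUTATIONS if p[ci] == si)
        for j in range(3):
            opt_cols[f"opt{j + 1}_color"].append(COLORS[j])
            opt_shps[f"opt{j + 1}_shape"].append(SHAPES[perm[j]])
        choice_idx.append(ci + 1)
    data.update(opt_cols)
    data.update(opt_shps)
    data["choice_index"] = choice_idx
    data["reward"] = rewards
    return pd.DataFrame(data)


def enumerate_log_joint(session, params):
    """Full log joint over all 7^T latent paths, as a (7, ..., 7) tensor.

    Direct, recursion-free spelling of the model definition: initial point
    mass on explore, reward-gated transition factors, and emission factors,
    added over broadcast axes (one axis per trial). Summing (logsumexp) over
    all axes gives the exact observed-data log-likelihood; marginalizing all
    but one axis gives exact posteriors.
    """
    from setshift import hmm

    B = hmm.emission_matrix(session)
    rewards = session["reward"].to_numpy().astype(int)
    plates = hmm.build_transition_plates(params)
    A = [plates.A_norwd, plates.A_rwd]
    T = B.shape[0]
    with np.errstate(divide="ignore"):
        logB = np.log(B)
        logA = [np.log(A[0]), np.log(A[1])]
        logpi = np.full(7, -np.inf)
        logpi[0] = 0.0

    def axis_shape(*axes):
        shape = [1] * T
        for ax in axes:
            shape[ax] = 7
        return shape

    logJ = np.zeros((7,) * T)
    logJ += (logpi + logB[0]).reshape(axis_shape(0))
    for t in range(1, T):
        logJ = logJ + logA[rewards[t - 1]].reshape(axis_shape(t - 1, t))
        logJ = logJ + logB[t].reshape(axis_shape(t))
    return logJ


def joint_log_prob(session, params, path_indices):
    """Log joint probability of a latent path and the observed choices.

    Independent scoring route used to validate decoding and likelihoods:
    initial point mass on explore, reward-gated transitions, and the
    rule-consistency emission model, multiplied along the path.
    """
    from setshift import hmm

    B = hmm.emission_matrix(session)
    rewards = session["reward"].to_numpy().astype(int)
    plates = hmm.build_transition_plates(params)
    A = [plates.A_norwd, plates.A_rwd]
    if path_indices[0] != 0:
        return -np.inf
    logp = np.log(B[0, 0]) if B[0, 0] > 0 else -np.inf
    for t in range(1, len(path_indices)):
        a = A[rewards[t - 1]][path_indices[t - 1], path_indices[t]]
        b = B[t, path_indices[t]]
        if a <= 0 or b <= 0:
            return -np.inf
        logp += np.log(a) + np.log(b)
    return logp
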