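"""Generative explore/exploit agent for the set-shifting task.

The agent is an input-output hidden Markov process with seven latent states:
one *explore* state and six *rule* states (one per stimulus feature). On each
trial it is either following a rule -- deterministically choosing the option
that carries the rule feature -- or exploring, choosing uniformly among the
three options. Between trials the state evolves according to four stay
probabilities, gated by the previous trial's reward:

- ``p_rule_stay_rwd`` / ``p_rule_stay_norwd``: probability of keeping the
  current rule state after a rewarded / unrewarded trial; otherwise the agent
  falls back to explore. Direct rule-to-different-rule transitions never occur.
- ``p_explore_stay_rwd`` / ``p_explore_stay_norwd``: probability of remaining
  in explore; otherwise the agent adopts a rule state matching one of the two
  features of its last choice, chosen at random.

Sessions simulated here carry the generating latent state per trial, which
downstream fitting and decoding code treats as ground truth.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import env
from .env import COLORS, FEATURES, PERMUTATIONS, SHAPES, OptionSet, Stimulus

EXPLORE = "explore"

#: Orderings used to shuffle option positions in the fast simulation core.
_ORDERINGS = tuple(itertools.permutations(range(3)))


@dataclass(frozen=True)
class AgentParams:
    """The four stay probabilities defining the reward-gated agent."""

    p_rule_stay_rwd: float
    p_explore_stay_rwd: float
    p_rule_stay_norwd: float
    p_explore_stay_norwd: float

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")

    def stay_probs(self, reward: bool) -> tuple[float, float]:
        """(rule-stay, explore-stay) for the plate selected by ``reward``."""
        if reward:
            return self.p_rule_stay_rwd, self.p_explore_stay_rwd
        return self.p_rule_stay_norwd, self.p_explore_stay_norwd

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "AgentParams":
        return cls(**{k: float(d[k]) for k in (
            "p_rule_stay_rwd", "p_explore_stay_rwd",
            "p_rule_stay_norwd", "p_explore_stay_norwd")})


#: Reward-optimal parameter set for this environment, from a grid study over
#: uniformly sampled parameter quadruples (see ``study.grid_study``).
REWARD_OPTIMAL_PARAMS = AgentParams(
    p_rule_stay_rwd=0.9971,
    p_explore_stay_rwd=0.0325,
    p_rule_stay_norwd=0.0436,
    p_explore_stay_norwd=0.5277,
)


def rule_state(feature: str) -> str:
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    return f"rule:{feature}"


def state_feature(state: str) -> str | None:
    """The rule feature of a latent-state label, or None for explore."""
    if state == EXPLORE:
        return None
    kind, _, feature = state.partition(":")
    if kind != "rule" or feature not in FEATURES:
        raise ValueError(f"malformed latent state {state!r}")
    return feature


def sample_next_state(
    z: str,
    reward: bool,
    params: AgentParams,
    last_choice: Stimulus | None,
    rng: np.random.Generator,
) -> str:
    """One step of the latent Markov chain, gated by the last reward."""
    p_rule_stay, p_explore_stay = params.stay_probs(reward)
    feature = state_feature(z)
    if feature is not None:
        return z if rng.random() < p_rule_stay else EXPLORE
    if rng.random() < p_explore_stay:
        return EXPLORE
    if last_choice is None:
        raise ValueError("cannot leave explore before any choice was made")
    return rule_state(last_choice.features[int(rng.integers(2))])


def emit_choice(z: str, opts: OptionSet, rng: np.random.Generator) -> int:
    """Choice index (0-based) emitted in state ``z`` on option set ``opts``."""
    feature = state_feature(z)
    if feature is None:
        return int(rng.integers(env.N_OPTIONS))
    return opts.index_matching(feature)


def _simulate_core(
    params: AgentParams,
    n_trials: int,
    rng: np.random.Generator,
    allow_rule_repeat: bool = False,
    explore_to_rule: str = "last_choice",
) -> dict[str, np.ndarray]:
    """Fast array-valued simulation of one session.

    Latent states and rules are coded as feature indices into
    ``env.FEATURES`` (-1 = explore). The first trial always starts in explore;
    the state transition into trial t depends on the state and reward of trial
    t-1 only.

    ``explore_to_rule`` selects the convention for which rule is adopted on
    leaving explore: ``"last_choice"`` (default) constrains it to one of the
    two features of the last choice, chosen at random; ``"uniform"`` draws it
    uniformly over all six rules, exactly as the fitted model assumes (useful
    for parameter-recovery studies where generator and model must coincide).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if explore_to_rule not in ("last_choice", "uniform"):
        raise ValueError("explore_to_rule must be 'last_choice' or 'uniform'")
    uniform_adopt = explore_to_rule == "uniform"
    pr_r, pe_r = params.p_rule_stay_rwd, params.p_explore_stay_rwd
    pr_n, pe_n = params.p_rule_stay_norwd, params.p_explore_stay_norwd

    u_perm = rng.integers(0, 6, size=n_trials)
    u_order = rng.integers(0, 6, size=n_trials)
    u_trans = rng.random(n_trials)
    u_emit = rng.integers(0, 3, size=n_trials)
    u_feat = (
        rng.integers(0, 6, size=n_trials)
        if uniform_adopt
        else rng.integers(0, 2, size=n_trials)
    )

    block = np.empty(n_trials, dtype=np.int32)
    rule_arr = np.empty(n_trials, dtype=np.int8)
    opt_colors = np.empty((n_trials, 3), dtype=np.int8)
    opt_shapes = np.empty((n_trials, 3), dtype=np.int8)
    choice = np.empty(n_trials, dtype=np.int8)
    reward_arr = np.empty(n_trials, dtype=np.int8)
    latent = np.empty(n_trials, dtype=np.int8)

    n_rule_choices = 5 if not allow_rule_repeat else 6
    rule = int(rng.integers(6))
    correct = 0
    block_idx = 0
    z = -1  # explore
    last_color = last_shape = -1
    prev_reward = 0

    for t in range(n_trials):
        if t > 0:
            u = u_trans[t]
            if z >= 0:
                stay = pr_r if prev_reward else pr_n
                if u >= stay:
                    z = -1
            else:
                stay = pe_r if prev_reward else pe_n
                if u >= stay:
                    if uniform_adopt:
                        z = u_feat[t]
                    else:
                        z = last_shape + 3 if u_feat[t] else last_color
        perm = PERMUTATIONS[u_perm[t]]
        order = _ORDERINGS[u_order[t]]
        if z < 0:
            c = u_emit[t]
        elif z < 3:
            c = order.index(z)
        else:
            target = z - 3
            c = 0
            while perm[order[c]] != target:
                c += 1
        ch_color = order[c]
        ch_shape = perm[ch_color]
        rwd = 1 if (ch_color == rule or ch_shape + 3 == rule) else 0

        block[t] = block_idx
        rule_arr[t] = rule
        for j in range(3):
            opt_colors[t, j] = order[j]
            opt_shapes[t, j] = perm[order[j]]
        choice[t] = c
        reward_arr[t] = rwd
        latent[t] = z

        if rwd:
            correct += 1
            if correct == env.CORRECT_PER_BLOCK:
                r = int(rng.integers(n_rule_choices))
                if not allow_rule_repeat and r >= rule:
                    r += 1
                rule = r
                correct = 0
                block_idx += 1
        last_color, last_shape = ch_color, ch_shape
        prev_reward = rwd

    return {
        "block_index": block,
        "rule": rule_arr,
        "opt_colors": opt_colors,
        "opt_shapes": opt_shapes,
        "choice": choice,
        "reward": reward_arr,
        "latent": latent,
    }


def _arrays_to_frame(
    arrays: dict[str, np.ndarray],
    session_id: str,
    monkey: str,
    condition: str,
) -> pd.DataFrame:
    n = len(arrays["choice"])
    latent_labels = [
        EXPLORE if z < 0 else rule_state(FEATURES[z]) for z in arrays["latent"]
    ]
    data = {
        "session_id": np.repeat(session_id, n),
        "monkey": np.repeat(monkey, n),
        "condition": np.repeat(condition, n),
        "trial_index": np.arange(1, n + 1),
        "block_index": arrays["block_index"],
        "rule": [FEATURES[r] for r in arrays["rule"]],
    }
    for j in range(3):
        data[f"opt{j + 1}_color"] = [COLORS[c] for c in arrays["opt_colors"][:, j]]
        data[f"opt{j + 1}_shape"] = [SHAPES[s] for s in arrays["opt_shapes"][:, j]]
    data["choice_index"] = arrays["choice"].astype(int) + 1
    data["reward"] = arrays["reward"].astype(int)
    data["latent_state"] = latent_labels
    return pd.DataFrame(data)


def simulate_session(
    params: AgentParams,
    n_trials: int,
    seed,
    *,
    session_id: str = "sim-0",
    monkey: str = "B",
    condition: str = "pre",
    allow_rule_repeat: bool = False,
    explore_to_rule: str = "last_choice",
) -> pd.DataFrame:
    """Simulate one session; returns a session table with a latent_state column.

    ``seed`` may be an int or a ``numpy.random.Generator``. Two calls with the
    same integer seed produce identical sessions. See :func:`_simulate_core`
    for ``explore_to_rule``.
    """
    rng = np.random.default_rng(seed)
    arrays = _simulate_core(params, n_trials, rng, allow_rule_repeat, explore_to_rule)
    return _arrays_to_frame(arrays, session_id, monkey, condition)


def simulate_dataset(
    param_draws,
    sessions_per_draw: int,
    trials_per_session: int,
    seed,
    *,
    return_sessions: bool = False,
):
    """Simulate many sessions per parameter draw and summarize each draw.

    Returns a DataFrame with one row per draw: the four parameters, the mean
    reward probability, and the lapse rate (errors deviating from the previous
    choice within the 10 trials before each rule change, per pre-change-point
    trial). Optionally also returns the full session tables.
    """
    from .stats import lapse_rate_from_arrays

    if sessions_per_draw < 1 or trials_per_session < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    sessions = []
    for d, params in enumerate(param_draws):
        n_rwd = n_tot = 0
        n_lapse = n_window = 0
        for s in range(sessions_per_draw):
            arrays = _simulate_core(params, trials_per_session, rng)
            n_rwd += int(arrays["reward"].sum())
            n_tot += trials_per_session
            lap, win = lapse_rate_from_arrays(arrays)
            n_lapse += lap
            n_window += win
            if return_sessions:
                sessions.append(
                    _arrays_to_frame(arrays, f"draw{d}-s{s}", "B", "pre")
                )
        rows.append(
            {
                **params.as_dict(),
                "reward_rate": n_rwd / n_tot,
                "lapse_rate": n_lapse / n_window if n_window else np.nan,
                "n_prechange_trials": n_window,
            }
        )
    summaries = pd.DataFrame(rows)
    if return_sessions:
        return summaries, sessions
    return summaries
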