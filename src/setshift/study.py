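"""Study-level inference over per-session statistics.

Covers the condition contrasts and regression analyses used to separate a
treatment effect from practice, the attractor-depth regression, projections
onto axes of endogenous covariation, the simulated parameter-grid performance
study, and change-point-aligned permutation tests on decoded state labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from . import agent, stats
from .agent import AgentParams

logger = logging.getLogger(__name__)

PARAM_NAMES = (
    "p_rule_stay_rwd",
    "p_explore_stay_rwd",
    "p_rule_stay_norwd",
    "p_explore_stay_norwd",
)


# ---------------------------------------------------------------------------
# session-summary regressions

def _check_full_rank(X: np.ndarray):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "check for constant or collinear predictors"
        )


def fit_step_ramp_glm(summaries: pd.DataFrame, statistic: str):
    """OLS of a session statistic on a treatment step, a practice ramp, and monkey.

    ``summaries`` needs columns ``tx`` (0 before / 1 after treatment),
    ``session_number`` and ``monkey_dummy`` besides the statistic. Returns the
    fitted statsmodels results; beta1 (tx) is the treatment offset and beta2
    (session_number) the practice slope.
    """
    for group in (0, 1):
        if (summaries["tx"] == group).sum() < 2:
            raise ValueError("need at least 2 sessions per condition")
    X = sm.add_constant(
        summaries[["tx", "session_number", "monkey_dummy"]].astype(float)
    )
    _check_full_rank(X.to_numpy())
    return sm.OLS(summaries[statistic].astype(float), X).fit()


def fit_depth_glm(depth_rows: pd.DataFrame):
    """OLS of explore-state depth on reward, treatment, their interaction,
    monkey, and session number.

    ``depth_rows`` holds one row per session x plate with columns ``depth``,
    ``rwd`` (1 = reward plate), ``cocaine`` (condition flag), ``monkey_dummy``
    and ``session_number``.
    """
    depth_rows = depth_rows.copy()
    depth_rows["rwd_x_cocaine"] = depth_rows["rwd"] * depth_rows["cocaine"]
    X = sm.add_constant(
        depth_rows[
            ["rwd", "cocaine", "rwd_x_cocaine", "monkey_dummy", "session_number"]
        ].astype(float)
    )
    _check_full_rank(X.to_numpy())
    return sm.OLS(depth_rows["depth"].astype(float), X).fit()


def covariation_axis_projection(
    x, y, baseline_mask
) -> np.ndarray:
    """Project (x, y) session pairs onto their baseline axis of covariation.

    An ordinary-least-squares line is fitted to the baseline sessions only;
    every session's pair is then projected onto the unit vector along that
    line. Returns the signed scalar coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(baseline_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 baseline sessions")
    if np.std(x[mask]) == 0:
        raise ValueError("baseline x has zero variance")
    slope, _ = np.polyfit(x[mask], y[mask], 1)
    direction = np.array([1.0, slope])
    direction /= np.linalg.norm(direction)
    return x * direction[0] + y * direction[1]


# ---------------------------------------------------------------------------
# parameter-grid performance study

@dataclass
class GridResult:
    draws: pd.DataFrame
    optimum: dict[str, float]
    lapse_correlations: dict[str, float]
    max_reward: float
    band_threshold: float
    n_in_band: int


def grid_study(
    n_draws: int = 3000,
    sessions_per_draw: int = 2,
    trials_per_session: int = 500,
    seed=None,
) -> GridResult:
    """Simulated performance of uniformly sampled agent parameter sets.

    Parameter quadruples are drawn uniformly in [0, 1]^4, each simulated in
    the task, and summarized by mean reward probability and lapse rate. The
    reward-optimal parameter set is the geometric mean over draws whose
    reward probability lies within 1% of the grid maximum; the result also
    reports the Pearson correlation of each parameter with lapse rate.
    """
    if min(n_draws, sessions_per_draw, trials_per_session) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.0, 1.0, size=(n_draws, 4))
    param_draws = [AgentParams(*row) for row in raw]
    draws = agent.simulate_dataset(
        param_draws, sessions_per_draw, trials_per_session, rng
    )

    max_reward = float(draws["reward_rate"].max())
    threshold = max_reward * 0.99
    in_band = draws["reward_rate"] >= threshold
    if in_band.sum() < 2:
        warnings.warn("fewer than 2 draws within 1% of maximum reward; widening band")
        threshold = max_reward * 0.98
        in_band = draws["reward_rate"] >= threshold
    optimum = {
        name: float(scipy.stats.gmean(draws.loc[in_band, name]))
        for name in PARAM_NAMES
    }

    ok = draws["lapse_rate"].notna()
    lapse_correlations = {
        name: float(
            scipy.stats.pearsonr(draws.loc[ok, name], draws.loc[ok, "lapse_rate"])[0]
        )
        for name in PARAM_NAMES
    }
    return GridResult(
        draws=draws,
        optimum=optimum,
        lapse_correlations=lapse_correlations,
        max_reward=max_reward,
        band_threshold=float(threshold),
        n_in_band=int(in_band.sum()),
    )


# ---------------------------------------------------------------------------
# change-point-aligned permutation test on state labels

def changepoint_shuffle_test(
    session: pd.DataFrame,
    state_labels,
    n_shuffles: int = 100,
    window: int = 10,
    seed=None,
) -> pd.DataFrame:
    """Explore-label frequency around change points vs a label-shuffle null.

    Bins are trials relative to each change point (offset 0 = first trial
    after the rule changed, negative offsets precede it). The null shuffles
    the label sequence within the session, conserving label counts. A bin is
    flagged high (low) when the observed explore frequency exceeds (falls
    below) the 97.5% (2.5%) tail of the shuffle distribution.
    """
    labels = np.asarray(state_labels)
    explore = (labels == "explore").astype(float)
    block = session["block_index"].to_numpy()
    boundaries = np.flatnonzero(np.diff(block) > 0) + 1
    if len(boundaries) == 0:
        raise ValueError("session contains no change points")
    n = len(explore)
    offsets = np.arange(-window, window)

    def bin_means(indicator):
        means = np.full(len(offsets), np.nan)
        for i, off in enumerate(offsets):
            idx = boundaries + off
            idx = idx[(idx >= 0) & (idx < n)]
            if len(idx):
                means[i] = indicator[idx].mean()
        return means

    observed = bin_means(explore)
    rng = np.random.default_rng(seed)
    null = np.array(
        [bin_means(rng.permutation(explore)) for _ in range(n_shuffles)]
    )
    lo = np.nanquantile(null, 0.025, axis=0)
    hi = np.nanquantile(null, 0.975, axis=0)
    return pd.DataFrame(
        {
            "offset": offsets,
            "observed": observed,
            "null_mean": np.nanmean(null, axis=0),
            "null_lo": lo,
            "null_hi": hi,
            "flag_high": observed > hi,
            "flag_low": observed < lo,
        }
    )


# ---------------------------------------------------------------------------
# condition contrasts

@dataclass
class ConditionContrast:
    t: float
    df: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p: float


def compare_conditions(
    summaries: pd.DataFrame,
    statistic: str,
    by: str = "condition",
    groups: tuple = ("pre", "post"),
) -> ConditionContrast:
    """Welch two-sample t-test of a statistic between two session groups.

    The reported difference is groups[1] minus groups[0], with a
    Satterthwaite-approximated 95% confidence interval.
    """
    a = summaries.loc[summaries[by] == groups[0], statistic].dropna().to_numpy()
    b = summaries.loc[summaries[by] == groups[1], statistic].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 sessions per group")
    res = scipy.stats.ttest_ind(b, a, equal_var=False)
    ci = res.confidence_interval(0.95)
    return ConditionContrast(
        t=float(res.statistic),
        df=float(res.df),
        mean_diff=float(b.mean() - a.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# per-block perseveration: global vs last-block explanations

def _block_predictors(session: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Per-block perseverative counts with candidate predictors."""
    block = session["block_index"].to_numpy()
    cats = labels["category"].to_numpy()
    in_post = labels["in_post_window"].to_numpy()
    error = session["reward"].to_numpy() == 0
    deviating = labels["dimension_change"].to_numpy() >= 1

    global_lapse, _ = stats.error_rates(labels)
    rows = []
    for b in np.unique(block):
        if b == 0:
            continue
        this = block == b
        prev = block == b - 1
        post_here = this & in_post
        n_post = int(post_here.sum())
        if n_post == 0:
            continue
        prev_lapse_rate = float((error & prev & deviating).sum()) / max(prev.sum(), 1)
        prev_session = session[prev]
        if len(prev_session) >= 8:
            curve = stats.outcome_effect_curve(prev_session, max_tau=5)
            if np.all(np.isfinite(curve)):
                prev_learning = stats.fit_outcome_decay(curve).alpha
            else:
                prev_learning = np.nan
        else:
            prev_learning = np.nan
        rows.append(
            {
                "block": int(b),
                "n_persev": int((cats == "perseverative")[post_here].sum()),
                "n_post": n_post,
                "last_block_lapse_rate": prev_lapse_rate,
                "last_block_learning_rate": prev_learning,
                "global_lapse_rate": global_lapse,
            }
        )
    return pd.DataFrame(rows)


BLOCK_MODEL_PREDICTORS = (
    "last_block_lapse_rate",
    "last_block_learning_rate",
    "global_lapse_rate",
)


def compare_block_models(data: pd.DataFrame) -> pd.DataFrame:
    """Binomial model comparison on a per-block predictor table.

    ``data`` holds one row per block with ``n_persev`` (perseverative errors),
    ``n_post`` (post-change-window trials) and one column per candidate
    predictor. Each model regresses the perseverative counts on a single
    predictor (logit link); rows with any missing predictor are dropped so
    all models see the same blocks. Returns log-likelihood, AIC, BIC and the
    corresponding weights per model; degenerate predictors are skipped.
    """
    data = data.dropna(subset=list(BLOCK_MODEL_PREDICTORS))
    if len(data) < 2:
        raise ValueError("need at least 2 usable blocks")
    endog = np.column_stack([data["n_persev"], data["n_post"] - data["n_persev"]])
    rows = []
    for name in BLOCK_MODEL_PREDICTORS:
        x = data[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.info("model %s skipped: predictor has zero variance", name)
            continue
        X = sm.add_constant(x)
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        k = X.shape[1]
        rows.append(
            {
                "model": name,
                "loglik": float(fit.llf),
                "aic": float(2 * k - 2 * fit.llf),
                "bic": float(k * np.log(len(data)) - 2 * fit.llf),
                "n_blocks": len(data),
            }
        )
    result = pd.DataFrame(rows)
    for crit in ("aic", "bic"):
        delta = result[crit] - result[crit].min()
        w = np.exp(-delta / 2)
        result[f"{crit}_weight"] = w / w.sum()
    return result


def block_lapse_model_comparison(sessions) -> pd.DataFrame:
    """Compare three explanations of per-block perseverative errors.

    Predictors (one binomial model each): the lapse rate of the previous
    block, the learning rate (outcome-decay alpha) of the previous block, and
    the session's global lapse rate. A win for the global model indicates a
    session-wide propensity rather than block-local failures to learn.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    frames = []
    for session in sessions:
        labels = stats.label_errors(session)
        frames.append(_block_predictors(session, labels))
    return compare_block_models(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# building summaries from raw sessions

def summarize_sessions(
    sessions,
    include_depth: bool = False,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """One row of statistics per session (the study pipeline's input table).

    Adds ``tx`` (0 for condition 'pre', 1 for 'post'), ``monkey_dummy``
    (1 for monkey B) and a within-monkey ``session_number``. With
    ``include_depth`` the tied ioHMM is fitted per session and the stationary
    explore depths of both plates are appended.
    """
    from . import hmm

    rows = []
    for session in sessions:
        row = stats.session_summary(session)
        if include_depth:
            fit = hmm.fit_em(session, **(fit_kwargs or {}))
            depths = hmm.stationary_distribution(
                hmm.build_transition_plates(fit.params)
            )
            row["explore_depth_rwd"] = depths.explore_depth_rwd
            row["explore_depth_norwd"] = depths.explore_depth_norwd
        rows.append(row)
    out = pd.DataFrame(rows)
    out["tx"] = (out["condition"] == "post").astype(int)
    out["monkey_dummy"] = (out["monkey"] == "B").astype(int)
    out["session_number"] = out.groupby("monkey").cumcount() + 1
    return out
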