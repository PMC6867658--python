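"""Behavioral statistics for set-shifting sessions.

All functions operate on session tables (see :mod:`setshift.io`) and work
identically on simulated and real-format data. The vocabulary follows the
set-shifting literature:

- *change point*: the uncued switch of the rewarded rule after 15 correct
  trials; trial "0" is the last trial before the switch.
- *lapse*: an error in the stable window (the 10 trials ending at trial 0)
  that deviates from the previous choice's color or shape.
- *perseverative error*: an error in the 5 trials after a change point that
  repeats the previous choice's color or shape.
- *novel choice*: a choice sharing neither color nor shape with the previous
  choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import env
from .env import COLORS, SHAPES

logger = logging.getLogger(__name__)

PRE_WINDOW = 10
POST_WINDOW = 5


# ---------------------------------------------------------------------------
# session-table accessors

def _index_of(series: pd.Series, vocab) -> np.ndarray:
    lut = {v: i for i, v in enumerate(vocab)}
    return series.map(lut).to_numpy(dtype=np.int8)


def session_arrays(session: pd.DataFrame) -> dict[str, np.ndarray]:
    """Decode a session table into integer-coded numpy arrays."""
    choice = session["choice_index"].to_numpy() - 1
    opt_colors = np.column_stack(
        [_index_of(session[f"opt{j}_color"], COLORS) for j in (1, 2, 3)]
    )
    opt_shapes = np.column_stack(
        [_index_of(session[f"opt{j}_shape"], SHAPES) for j in (1, 2, 3)]
    )
    rows = np.arange(len(session))
    out = {
        "block": session["block_index"].to_numpy(),
        "reward": session["reward"].to_numpy().astype(np.int8),
        "opt_colors": opt_colors,
        "opt_shapes": opt_shapes,
        "choice": choice,
        "chosen_color": opt_colors[rows, choice],
        "chosen_shape": opt_shapes[rows, choice],
    }
    if "latent_state" in session.columns:
        out["latent"] = session["latent_state"].to_numpy()
    return out


def dimension_change(chosen_color: np.ndarray, chosen_shape: np.ndarray) -> np.ndarray:
    """Per-trial number of dimensions changed vs the previous choice (-1 = undefined)."""
    n = len(chosen_color)
    d = np.full(n, -1, dtype=np.int8)
    if n > 1:
        shared = (chosen_color[1:] == chosen_color[:-1]).astype(np.int8) + (
            chosen_shape[1:] == chosen_shape[:-1]
        ).astype(np.int8)
        d[1:] = 2 - shared
    return d


def _change_windows(block: np.ndarray, pre: int, post: int):
    """Boolean masks for the pre/post change-point windows.

    A change point sits between the last trial of one block and the first
    trial of the next; the pre window covers the ``pre`` trials ending at the
    last pre-change trial, the post window the ``post`` trials from the first
    post-change trial.
    """
    n = len(block)
    boundaries = np.flatnonzero(np.diff(block) > 0) + 1
    in_pre = np.zeros(n, dtype=bool)
    in_post = np.zeros(n, dtype=bool)
    for b in boundaries:
        in_pre[max(b - pre, 0): b] = True
        in_post[b: min(b + post, n)] = True
    return in_pre, in_post, boundaries


# ---------------------------------------------------------------------------
# error taxonomy

def label_errors(
    session: pd.DataFrame,
    pre_window: int = PRE_WINDOW,
    post_window: int = POST_WINDOW,
) -> pd.DataFrame:
    """Classify every trial as correct / lapse / lapse_like / perseverative / other_error.

    Lapses are errors inside the stable pre-change window that deviate from
    the previous choice in at least one dimension; perseverative errors are
    post-change errors repeating at least one dimension; deviating errors
    anywhere else are lapse_like. The first trial has no previous choice, so
    its dimension_change is null and an error there is other_error.
    """
    a = session_arrays(session)
    d = dimension_change(a["chosen_color"], a["chosen_shape"])
    in_pre, in_post, _ = _change_windows(a["block"], pre_window, post_window)
    error = a["reward"] == 0

    category = np.where(error, "other_error", "correct").astype(object)
    deviates = d >= 1
    repeats = (d >= 0) & (d <= 1)
    category[error & deviates] = "lapse_like"
    category[error & in_pre & deviates] = "lapse"
    category[error & in_post & repeats] = "perseverative"

    return pd.DataFrame(
        {
            "category": category,
            "dimension_change": pd.array(
                np.where(d < 0, np.nan, d), dtype="Int8"
            ) if len(d) else pd.array([], dtype="Int8"),
            "in_pre_window": in_pre,
            "in_post_window": in_post,
        },
        index=session.index,
    )


def error_rates(labels: pd.DataFrame, session: pd.DataFrame | None = None):
    """(lapse_rate, perseverative_fraction) for one session.

    lapse_rate is lapses per pre-window trial; perseverative_fraction is
    perseverative errors per error trial within the post-change epoch (NaN
    when that epoch holds no errors).
    """
    n_pre = int(labels["in_pre_window"].sum())
    lapse_rate = (
        float((labels["category"] == "lapse").sum()) / n_pre if n_pre else np.nan
    )
    post = labels[labels["in_post_window"]]
    n_post_errors = int((post["category"] != "correct").sum())
    if n_post_errors == 0:
        persev_fraction = np.nan
    else:
        persev_fraction = float(
            (post["category"] == "perseverative").sum()
        ) / n_post_errors
    return lapse_rate, persev_fraction


def lapse_rate_from_arrays(
    arrays: dict[str, np.ndarray], pre_window: int = PRE_WINDOW
) -> tuple[int, int]:
    """(lapse count, pre-window trial count) from raw simulation arrays.

    Fast path used by the grid study; mirrors :func:`label_errors` /
    :func:`error_rates` on integer-coded arrays.
    """
    rows = np.arange(len(arrays["choice"]))
    chc = arrays["opt_colors"][rows, arrays["choice"]]
    chs = arrays["opt_shapes"][rows, arrays["choice"]]
    d = dimension_change(chc, chs)
    in_pre, _, _ = _change_windows(arrays["block_index"], pre_window, 0)
    lapses = int(np.sum(in_pre & (arrays["reward"] == 0) & (d >= 1)))
    return lapses, int(in_pre.sum())


def dimension_change_ratio(labels: pd.DataFrame) -> dict[str, float]:
    """Observed / chance-expected counts of change-1 and change-2 lapses."""
    lapses = labels[labels["category"] == "lapse"]
    total = len(lapses)
    if total == 0:
        return {"change1": np.nan, "change2": np.nan}
    chance = env.chance_probabilities()
    out = {}
    for k, name in ((1, "change1"), (2, "change2")):
        observed = int((lapses["dimension_change"] == k).sum())
        out[name] = observed / (float(chance[name]) * total)
    return out


# ---------------------------------------------------------------------------
# outcome effect index and its decay

def outcome_effect_index(
    session: pd.DataFrame,
    tau: int,
    state_labels=None,
    state_kind: str | None = None,
) -> float:
    """Normalized influence of the outcome at lag ``tau`` on feature repeats.

    [p(repeat_t | reward_{t-tau}=1) - p(repeat_t | reward_{t-tau}=0)] /
    p(repeat_t), computed per feature dimension and averaged over color and
    shape. When ``state_labels`` and ``state_kind`` ('explore' or 'rule') are
    given, only outcomes received on trials of that latent kind enter.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    a = session_arrays(session)
    n = len(a["reward"])
    if n <= tau:
        return np.nan
    past_reward = a["reward"][:-tau]
    keep = np.ones(n - tau, dtype=bool)
    if state_labels is not None and state_kind is not None:
        lab = np.asarray(state_labels)[:-tau]
        is_explore = lab == "explore"
        keep &= is_explore if state_kind == "explore" else ~is_explore
    values = []
    for feat in ("chosen_color", "chosen_shape"):
        rep = (a[feat][tau:] == a[feat][:-tau])[keep]
        r = past_reward[keep]
        if rep.size == 0 or not rep.any():
            values.append(np.nan)
            continue
        if not (r == 1).any() or not (r == 0).any():
            values.append(np.nan)
            continue
        p1 = rep[r == 1].mean()
        p0 = rep[r == 0].mean()
        values.append((p1 - p0) / rep.mean())
    return float(np.nanmean(values)) if not all(np.isnan(values)) else np.nan


def outcome_effect_curve(
    session: pd.DataFrame, max_tau: int = 5, **kwargs
) -> np.ndarray:
    return np.array(
        [outcome_effect_index(session, tau, **kwargs) for tau in range(1, max_tau + 1)]
    )


@dataclass
class OutcomeDecayFit:
    offset: float
    scale: float
    alpha: float
    converged: bool = True
    degenerate: bool = False


def fit_outcome_decay(indices, taus=None) -> OutcomeDecayFit:
    """Least-squares fit of index(tau) = offset + scale * exp(-alpha * (tau - 1)).

    With this parameterization offset + scale equals the lag-1 index, so
    ``scale`` is the influence of the most recent outcome and ``alpha`` the
    learning rate (decay of that influence per trial).
    """
    y = np.asarray(indices, dtype=float)
    if taus is None:
        taus = np.arange(1, len(y) + 1)
    taus = np.asarray(taus, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("indices must be finite")
    if np.ptp(y) < 1e-12:
        return OutcomeDecayFit(float(y.mean()), 0.0, 0.0, degenerate=True)

    def model(t, offset, scale, alpha):
        return offset + scale * np.exp(-alpha * (t - 1))

    p0 = (y[-1], y[0] - y[-1], 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, taus, y, p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return OutcomeDecayFit(*p0, converged=False)
    return OutcomeDecayFit(*map(float, popt))


# ---------------------------------------------------------------------------
# novel choices

def novel_choice_probability(session: pd.DataFrame) -> dict[str, float]:
    """Probability of novel choices, split by the previous trial's outcome.

    A choice is novel when it shares neither feature with the previous choice.
    ``rwd`` / ``norwd`` are plain frequencies; the ``*_corrected`` variants
    normalize the novel-choice count by the number of novel options actually
    offered (a uniformly random chooser scores 1/3 there regardless of the
    option-set mix).
    """
    a = session_arrays(session)
    n = len(a["reward"])
    if n < 2:
        raise ValueError("need at least 2 trials")
    prev_c, prev_s = a["chosen_color"][:-1], a["chosen_shape"][:-1]
    novel_choice = (a["chosen_color"][1:] != prev_c) & (a["chosen_shape"][1:] != prev_s)
    availability = np.sum(
        (a["opt_colors"][1:] != prev_c[:, None])
        & (a["opt_shapes"][1:] != prev_s[:, None]),
        axis=1,
    )
    prev_reward = a["reward"][:-1]
    out = {}
    for name, mask in (("rwd", prev_reward == 1), ("norwd", prev_reward == 0)):
        usable = mask & (availability > 0)
        if not usable.any():
            out[name] = np.nan
            out[name + "_corrected"] = np.nan
            continue
        out[name] = float(novel_choice[usable].mean())
        out[name + "_corrected"] = float(
            novel_choice[usable].sum() / availability[usable].sum()
        )
    return out


# ---------------------------------------------------------------------------
# choice autocorrelations and switch kernels

def choice_autocorrelation(session: pd.DataFrame, max_lag: int) -> np.ndarray:
    """Mean feature-indicator autocorrelation at lags 1..max_lag.

    Each choice is coded as a 6-element indicator over features; Pearson
    autocorrelations are computed per feature and averaged, skipping features
    with zero variance in either lagged segment.
    """
    a = session_arrays(session)
    n = len(a["reward"])
    if n <= max_lag:
        raise ValueError("sequence shorter than max_lag")
    indicators = np.zeros((6, n))
    for i in range(3):
        indicators[i] = a["chosen_color"] == i
        indicators[3 + i] = a["chosen_shape"] == i
    out = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        vals = []
        for f in range(6):
            x, y = indicators[f, :-lag], indicators[f, lag:]
            if x.std() == 0 or y.std() == 0:
                continue
            vals.append(np.corrcoef(x, y)[0, 1])
        if vals:
            out[lag - 1] = np.mean(vals)
    return out


@dataclass
class KernelFit:
    last: float
    decay: float
    n_switches: int
    unstable: bool = False


def _domain_switches(values: np.ndarray, min_run: int) -> np.ndarray:
    """Indices t where values[t] != values[t-1] after a run of >= min_run."""
    switches = []
    run = 1
    for t in range(1, len(values)):
        if values[t] == values[t - 1]:
            run += 1
        else:
            if run >= min_run:
                switches.append(t)
            run = 1
    return np.array(switches, dtype=int)


def switch_triggered_kernel(
    sessions, min_run: int = 5, max_lag: int = 10
) -> tuple[np.ndarray, KernelFit]:
    """Reward history preceding switches away from established choices.

    A switch is a change of chosen color (or shape) after at least ``min_run``
    consecutive choices of the same color (shape); runs are tracked
    independently per feature dimension. The empirical kernel is the
    probability of reward at each lag before a switch, fitted with

        weight(tau) = 1 - (1 - last) * exp(-(tau - 1) / decay)

    where ``last`` is the reward probability on the trial immediately before
    the switch and ``decay`` (trials) the kernel timescale. A decision-maker
    that switches if and only if the last trial went unrewarded has last = 0
    and decay approaching 0; longer kernels (more accumulated evidence needed
    to switch) give larger decay.
    """
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    counts = np.zeros(max_lag)
    rewarded = np.zeros(max_lag)
    n_switches = 0
    for session in sessions:
        a = session_arrays(session)
        for feat in ("chosen_color", "chosen_shape"):
            for t in _domain_switches(a[feat], min_run):
                n_switches += 1
                for lag in range(1, max_lag + 1):
                    if t - lag < 0:
                        break
                    counts[lag - 1] += 1
                    rewarded[lag - 1] += a["reward"][t - lag]
    if n_switches == 0:
        raise ValueError("no qualifying switches")
    with np.errstate(invalid="ignore"):
        weights = np.where(counts > 0, rewarded / np.maximum(counts, 1), np.nan)

    taus = np.arange(1, max_lag + 1, dtype=float)
    ok = np.isfinite(weights)

    def model(t, last, decay):
        z = np.zeros_like(t)
        np.divide(t - 1, decay, out=z, where=decay > 0)
        w = 1.0 - (1.0 - last) * np.exp(-z)
        if decay <= 0:  # degenerate limit: instant recovery after lag 1
            w = np.where(t == 1, last, 1.0)
        return w

    unstable = n_switches < 10
    try:
        popt, _ = optimize.curve_fit(
            model, taus[ok], weights[ok], p0=(0.2, 1.0),
            bounds=([0.0, 0.0], [1.0, 100.0]), maxfev=10000,
        )
        fit = KernelFit(float(popt[0]), float(popt[1]), n_switches, unstable)
    except RuntimeError:
        fit = KernelFit(np.nan, np.nan, n_switches, unstable=True)
    return weights, fit


def interswitch_intervals(session: pd.DataFrame) -> np.ndarray:
    """Run lengths of repeated choices, tracked per feature dimension.

    Runs of identical chosen colors and runs of identical chosen shapes are
    collected independently; every maximal run contributes one interval.
    """
    a = session_arrays(session)
    intervals = []
    for feat in ("chosen_color", "chosen_shape"):
        v = a[feat]
        run = 1
        for t in range(1, len(v)):
            if v[t] == v[t - 1]:
                run += 1
            else:
                intervals.append(run)
                run = 1
        intervals.append(run)
    return np.array(intervals, dtype=int)


# ---------------------------------------------------------------------------
# geometric (discrete exponential) mixtures of interswitch intervals

@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    rates: np.ndarray
    half_lives: np.ndarray = field(init=False)
    means: np.ndarray = field(init=False)
    loglik: float = np.nan
    aic: float = np.nan
    bic: float = np.nan
    n: int = 0
    flagged: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        with np.errstate(divide="ignore"):
            self.half_lives = np.log(2) / self.rates
        q = np.exp(-self.rates)
        self.means = 1.0 / (1.0 - q)


def _geometric_mixture_loglik(values, counts, weights, q):
    # pmf of the discrete exponential on {1, 2, ...}: (1-q) q^(x-1)
    with np.errstate(divide="ignore"):
        logq = np.log(q)
    log_pmf = np.log(1.0 - q)[None, :] + np.where(
        (values - 1)[:, None] > 0, (values - 1)[:, None] * logq[None, :], 0.0
    )
    log_mix = special.logsumexp(log_pmf + np.log(weights)[None, :], axis=1)
    return float(np.sum(counts * log_mix)), log_pmf


def fit_exponential_mixture(
    intervals,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-9,
    init_means=None,
    init_weights=None,
) -> MixtureFit:
    """EM fit of a k-component mixture of discrete exponentials (geometrics).

    Intervals are positive integers. Components are parameterized by decay
    rates; half-life = ln 2 / rate. Free parameters are counted as k rates
    plus k - 1 mixing weights (1 for k=1, 3 for k=2, 5 for k=3, ...).
    Initialization is a deterministic quantile spread unless explicit
    component means/weights are given (used by :func:`select_order` to warm-
    start nested fits).
    """
    x = np.asarray(intervals, dtype=float)
    if x.size == 0 or np.any(x < 1) or np.any(x != np.round(x)):
        raise ValueError("intervals must be integers >= 1")
    values, counts = np.unique(x, return_counts=True)
    n = int(counts.sum())
    flagged = k > len(values)

    if init_means is None:
        # quantile-spread initialization, deterministic
        qs = np.quantile(x, (np.arange(k) + 0.5) / k)
        means = np.clip(qs, 1.0 + 1e-6, None) + np.linspace(0, 1e-3, k)
    else:
        means = np.clip(np.asarray(init_means, dtype=float), 1.0 + 1e-6, None)
    q = 1.0 - 1.0 / means
    if init_weights is None:
        weights = np.full(k, 1.0 / k)
    else:
        weights = np.asarray(init_weights, dtype=float)
        weights = weights / weights.sum()

    loglik = -np.inf
    for _ in range(max_iter):
        ll, log_pmf = _geometric_mixture_loglik(values, counts, weights, q)
        log_resp = log_pmf + np.log(weights)[None, :]
        log_resp -= special.logsumexp(log_resp, axis=1, keepdims=True)
        resp = np.exp(log_resp) * counts[:, None]
        nk = resp.sum(axis=0)
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        q = np.clip(1.0 - 1.0 / np.maximum(means, 1.0 + 1e-12), 0.0, 1.0 - 1e-12)
        if ll - loglik < tol * max(abs(ll), 1.0) and np.isfinite(ll):
            loglik = ll
            break
        loglik = ll

    rates = -np.log(np.maximum(q, 1e-300))
    n_params = 2 * k - 1
    fit = MixtureFit(k=k, weights=weights, rates=rates, n=n, flagged=flagged)
    fit.loglik = loglik
    fit.aic = 2 * n_params - 2 * loglik
    fit.bic = n_params * math.log(n) - 2 * loglik
    return fit


def select_order(intervals, k_max: int = 4):
    """Fit k = 1..k_max mixtures; return (fits, best k by AIC, best k by BIC).

    Each order is fitted both from the default initialization and warm-
    started from the previous order's solution (plus one near-duplicate,
    low-weight component), keeping the better likelihood; this keeps the
    nested log-likelihoods non-decreasing in k.
    """
    fits = []
    for k in range(1, k_max + 1):
        fit = fit_exponential_mixture(intervals, k)
        if fits:
            prev = fits[-1]
            warm = fit_exponential_mixture(
                intervals,
                k,
                init_means=np.append(prev.means, prev.means.max() * 1.5),
                init_weights=np.append(prev.weights * (1 - 1e-6), 1e-6),
            )
            if warm.loglik > fit.loglik:
                fit = warm
        fits.append(fit)
    aics = np.array([f.aic for f in fits])
    bics = np.array([f.bic for f in fits])
    return fits, int(np.argmin(aics)) + 1, int(np.argmin(bics)) + 1


def short_state_excess(fit: MixtureFit) -> float:
    """Expected-time fraction of the short-lived component of a 2-mixture.

    The expected time in a component is its mixing weight times its mean run
    length; the excess is the short component's share of the total. Values
    above 0.5 indicate more short runs than a single persistent process with
    incidental cross-dimension randomization would produce.
    """
    if fit.k != 2:
        raise ValueError("short_state_excess requires a 2-component fit")
    short = int(np.argmin(fit.means))
    expected = fit.weights * fit.means
    return float(expected[short] / expected.sum())


# ---------------------------------------------------------------------------
# information content of explore choices

def explore_mutual_information(
    session: pd.DataFrame,
    state_labels,
    n_shuffles: int = 100,
    seed=None,
) -> dict[str, dict]:
    """Mutual information between explore choices and the previous choice.

    Choice identity is the full stimulus (color x shape, 9 categories).
    Computed over explore-labeled trials, split by the previous trial's
    outcome, against a null built by shuffling the previous-choice labels
    within each split. MI is the plug-in estimate in bits.
    """
    a = session_arrays(session)
    labels = np.asarray(state_labels)
    ids = a["chosen_color"] * 3 + a["chosen_shape"]
    explore = (labels == "explore")[1:]
    prev_reward = a["reward"][:-1]
    cur, prev = ids[1:], ids[:-1]
    rng = np.random.default_rng(seed)
    out = {}
    for name, mask in (("rwd", prev_reward == 1), ("norwd", prev_reward == 0)):
        sel = explore & mask
        if sel.sum() < 2:
            logger.info("explore MI: conditioning cell %s too small, excluded", name)
            continue
        c, p = cur[sel], prev[sel]
        mi = _mutual_information_bits(c, p)
        null = np.array(
            [_mutual_information_bits(c, rng.permutation(p)) for _ in range(n_shuffles)]
        )
        out[name] = {"mi": mi, "null_mean": float(null.mean()), "null": null}
    return out


def _mutual_information_bits(x: np.ndarray, y: np.ndarray) -> float:
    joint = pd.crosstab(x, y).to_numpy().astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px * py))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# effect-size helpers

def log_odds_ratio(p1: float, p2: float) -> float:
    """logit(p1) - logit(p2); a baseline-robust measure of a probability change."""
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise ValueError("probabilities must lie strictly inside (0, 1)")
    return float(special.logit(p1) - special.logit(p2))


def repeat_after_error_probability(
    session: pd.DataFrame, labels: pd.DataFrame, horizon: int = 2
) -> dict[str, float]:
    """p(the erroneous stimulus is re-chosen within ``horizon`` trials), per error class.

    Compares lapses against all other errors; an error trial without any
    subsequent trial inside the horizon window is excluded.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    a = session_arrays(session)
    n = len(a["reward"])
    cats = labels["category"].to_numpy()
    out = {}
    for name, mask in (
        ("lapse", cats == "lapse"),
        ("other_error", (cats != "lapse") & (cats != "correct")),
    ):
        hits = []
        for t in np.flatnonzero(mask):
            if t + 1 >= n:
                continue
            upto = min(t + horizon, n - 1)
            future = slice(t + 1, upto + 1)
            hits.append(
                bool(
                    np.any(
                        (a["chosen_color"][future] == a["chosen_color"][t])
                        & (a["chosen_shape"][future] == a["chosen_shape"][t])
                    )
                )
            )
        out[name] = float(np.mean(hits)) if hits else np.nan
    return out


# ---------------------------------------------------------------------------
# per-session summary used by the study pipeline

def session_summary(session: pd.DataFrame, **label_kwargs) -> dict[str, float]:
    """Flat dictionary of the per-session statistics the study pipeline consumes."""
    labels = label_errors(session, **label_kwargs)
    lapse_rate, persev = error_rates(labels)
    novel = novel_choice_probability(session)
    return {
        "session_id": session["session_id"].iloc[0],
        "monkey": session["monkey"].iloc[0],
        "condition": session["condition"].iloc[0],
        "percent_correct": float(session["reward"].mean()) * 100.0,
        "lapse_rate": lapse_rate,
        "perseverative_fraction": persev,
        "p_novel_rwd": novel["rwd"],
        "p_novel_norwd": novel["norwd"],
    }
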