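import numpy as np
import pandas as pd
import pytest

from setshift import agent, stats
from setshift.agent import AgentParams
from setshift.stats import (
    choice_autocorrelation,
    dimension_change_ratio,
    error_rates,
    explore_mutual_information,
    fit_exponential_mixture,
    fit_outcome_decay,
    interswitch_intervals,
    label_errors,
    log_odds_ratio,
    novel_choice_probability,
    outcome_effect_curve,
    outcome_effect_index,
    repeat_after_error_probability,
    select_order,
    short_state_excess,
    switch_triggered_kernel,
)

from conftest import MONKEY_B_BASELINE, make_session

UNIFORM_CHOOSER = AgentParams(0.0, 1.0, 0.0, 1.0)  # never leaves explore


def two_block_session():
    """17 trials in block 0 (change point after trial 17) + 8 trials in block 1."""
    chosen = [("cyan", "circle")] * 14 + [
        ("cyan", "star"),       # idx 14: pre-window error sharing color only
        ("cyan", "circle"),     # idx 15
        ("magenta", "star"),    # idx 16: pre-window error deviating in both
        ("cyan", "circle"),     # idx 17: first post-change trial, deviates both
        ("cyan", "star"),       # idx 18: post-window error repeating color
        ("yellow", "triangle"), # idx 19: post-window error deviating both
        ("magenta", "circle"),  # idx 20: correct under new rule
        ("magenta", "circle"),
        ("magenta", "circle"),
        ("magenta", "circle"),
        ("magenta", "circle"),
    ]
    rewards = [1] * 14 + [0, 1, 0, 0, 0, 0, 1, 1, 1, 1, 1]
    blocks = [0] * 17 + [1] * 8
    return make_session(chosen, rewards, blocks)


class TestLabelErrors:
    def test_error_taxonomy_on_constructed_session(self):
        s = two_block_session()
        labels = label_errors(s)
        cats = labels["category"].tolist()
        # error 3 trials before the change point, sharing the previous color
        # only: deviates in shape => lapse with dimension_change 1
        assert cats[14] == "lapse"
        assert labels["dimension_change"].iloc[14] == 1
        # error just before the change point deviating in both dims
        assert cats[16] == "lapse"
        assert labels["dimension_change"].iloc[16] == 2
        # error 2 trials after the change point repeating the previous color
        assert cats[18] == "perseverative"
        assert labels["dimension_change"].iloc[18] == 1
        # post-change errors deviating in both dimensions are lapse-like
        assert cats[17] == "lapse_like"
        assert cats[19] == "lapse_like"
        assert cats[0] == "correct"

    def test_categories_mutually_exclusive_and_first_trial_null(self, session_b):
        labels = label_errors(session_b)
        assert labels["category"].isin(
            ["correct", "lapse", "lapse_like", "perseverative", "other_error"]
        ).all()
        first = make_session([("cyan", "circle")], [0])
        l0 = label_errors(first)
        assert pd.isna(l0["dimension_change"].iloc[0])
        assert l0["category"].iloc[0] == "other_error"

    def test_lapses_restricted_to_pre_window(self, session_b):
        labels = label_errors(session_b)
        assert (labels.loc[labels["category"] == "lapse", "in_pre_window"]).all()
        assert (
            labels.loc[labels["category"] == "perseverative", "in_post_window"]
        ).all()


class TestErrorRates:
    def test_constructed_session_rates(self):
        s = two_block_session()
        labels = label_errors(s)
        lapse_rate, persev = error_rates(labels)
        # one change point: 10 pre-window trials, lapses at idx 14 and 16
        assert lapse_rate == pytest.approx(2 / 10)
        # post-window errors at idx 17, 18, 19 -> 1 perseverative of 3
        assert persev == pytest.approx(1 / 3)

    def test_no_post_errors_gives_nan_fraction(self):
        chosen = [("cyan", "circle")] * 20
        rewards = [1] * 20
        blocks = [0] * 15 + [1] * 5
        labels = label_errors(make_session(chosen, rewards, blocks))
        _, persev = error_rates(labels)
        assert np.isnan(persev)

    def test_perfect_rule_stay_after_reward_suppresses_lapses(self):
        # with p(stay in rule | reward) = 1 a rewarded rule trial can never be
        # followed by a rule exit, so (a) no both-dimension lapse ever follows
        # a rewarded rule-state trial (consecutive same-rule choices share the
        # rule feature), and (b) the lapse rate collapses relative to an agent
        # that can leave rules after rewards; residual lapses only arise where
        # the pre-change window overlaps the search phase.
        locked = AgentParams(1.0, 0.3, 0.1, 0.3)
        leaky = AgentParams(0.9, 0.3, 0.1, 0.3)
        rng = np.random.default_rng(3)
        rates = {"locked": [], "leaky": []}
        for _ in range(10):
            for name, p in (("locked", locked), ("leaky", leaky)):
                s = agent.simulate_session(p, 500, seed=rng)
                labels = label_errors(s)
                rate, _ = error_rates(labels)
                rates[name].append(rate)
                if name == "locked":
                    states = s["latent_state"].to_numpy()
                    rwd = s["reward"].to_numpy()
                    lapse2 = (labels["category"].to_numpy() == "lapse") & (
                        labels["dimension_change"].to_numpy() == 2
                    )
                    for t in np.flatnonzero(lapse2):
                        assert not (states[t - 1] != "explore" and rwd[t - 1] == 1)
        assert np.nanmean(rates["locked"]) < 0.5 * np.nanmean(rates["leaky"])


class TestDimensionChangeRatio:
    def test_arithmetic(self):
        labels = pd.DataFrame(
            {
                "category": ["lapse"] * 90,
                "dimension_change": pd.array([1] * 45 + [2] * 45, dtype="Int8"),
                "in_pre_window": [True] * 90,
                "in_post_window": [False] * 90,
            }
        )
        ratios = dimension_change_ratio(labels)
        assert ratios["change1"] == pytest.approx((45 / 90) / (1 / 3))
        assert ratios["change2"] == pytest.approx((45 / 90) / (2 / 3))

    def test_uniform_random_lapses_have_unit_ratios(self):
        # the 1/3 - 2/3 chance split is derived for the stable-period context
        # where the previous choice was rewarded (the rule is one of its two
        # features), so restrict the random chooser's lapses accordingly
        rng = np.random.default_rng(5)
        c1 = c2 = 0
        for _ in range(60):
            s = agent.simulate_session(UNIFORM_CHOOSER, 500, seed=rng)
            labels = label_errors(s)
            prev_rewarded = np.concatenate([[False], s["reward"].to_numpy()[:-1] == 1])
            lapses = labels[(labels["category"] == "lapse") & prev_rewarded]
            c1 += (lapses["dimension_change"] == 1).sum()
            c2 += (lapses["dimension_change"] == 2).sum()
        total = c1 + c2
        assert c1 / (total / 3) == pytest.approx(1.0, abs=0.05)
        assert c2 / (2 * total / 3) == pytest.approx(1.0, abs=0.05)

    def test_zero_lapses_null(self):
        labels = pd.DataFrame(
            {
                "category": ["correct"],
                "dimension_change": pd.array([np.nan], dtype="Int8"),
                "in_pre_window": [False],
                "in_post_window": [False],
            }
        )
        assert np.isnan(dimension_change_ratio(labels)["change1"])


class TestOutcomeEffect:
    def test_reward_blind_chooser_has_zero_index(self):
        s = agent.simulate_session(UNIFORM_CHOOSER, 4000, seed=7)
        idx = outcome_effect_index(s, tau=1)
        assert abs(idx) < 0.1

    def test_formula_on_perfectly_outcome_driven_repeats(self):
        rng = np.random.default_rng(9)
        rewards = rng.integers(0, 2, size=300).tolist()
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen = [pool[0]]
        for t in range(1, 300):
            if rewards[t - 1] == 1:
                chosen.append(chosen[-1])  # repeat both features
            else:
                current = pool.index(chosen[-1])
                chosen.append(pool[(current + 1) % 3])  # change both features
        s = make_session(chosen, rewards)
        idx = outcome_effect_index(s, tau=1)
        p_rep = np.mean(rewards[:-1])
        assert idx == pytest.approx((1 - 0) / p_rep, rel=0.02)

    def test_influence_decays_with_lag_for_one_step_learners(self):
        # a chooser whose repeat probability depends only on the most recent
        # outcome: the influence of a given reward on later choices is then
        # carried only through run persistence and must fade monotonically
        rng = np.random.default_rng(11)
        n = 8000
        rewards = rng.integers(0, 2, size=n)
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen = [pool[0]]
        for t in range(1, n):
            if rng.random() < 0.25 + 0.55 * rewards[t - 1]:
                chosen.append(chosen[-1])
            else:
                others = [p for p in pool if p != chosen[-1]]
                chosen.append(others[int(rng.integers(2))])
        s = make_session(chosen, rewards.tolist())
        curve = outcome_effect_curve(s, max_tau=5)
        assert np.all(np.diff(curve) < 0)
        assert curve[0] > 5 * curve[4] > 0

    def test_state_conditioned_index_restricts_outcome_trials(self, session_b):
        labels = session_b["latent_state"].to_numpy()
        i_exp = outcome_effect_index(session_b, 1, labels, "explore")
        i_rule = outcome_effect_index(session_b, 1, labels, "rule")
        assert np.isfinite(i_rule)
        assert i_exp != i_rule


class TestOutcomeDecayFit:
    def test_noiseless_recovery(self):
        taus = np.arange(1, 6)
        y = 0.5 + 1.0 * np.exp(-0.8 * (taus - 1))
        fit = fit_outcome_decay(y)
        assert fit.offset == pytest.approx(0.5, abs=1e-6)
        assert fit.scale == pytest.approx(1.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.8, abs=1e-6)

    def test_flat_curve_flagged_degenerate(self):
        fit = fit_outcome_decay(np.full(5, 0.7))
        assert fit.degenerate
        assert fit.offset == pytest.approx(0.7)

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(13)
        errs = []
        for _ in range(200):
            alpha = rng.uniform(0.3, 1.5)
            taus = np.arange(1, 6)
            y = 0.4 + 0.9 * np.exp(-alpha * (taus - 1)) + rng.normal(0, 0.02, 5)
            errs.append(abs(fit_outcome_decay(y).alpha - alpha))
        assert np.median(errs) < 0.1


class TestNovelChoices:
    def test_uniform_chooser_matches_enumeration(self):
        rng = np.random.default_rng(15)
        raw = {"rwd": [], "norwd": []}
        corr = {"rwd": [], "norwd": []}
        for _ in range(30):
            s = agent.simulate_session(UNIFORM_CHOOSER, 500, seed=rng)
            out = novel_choice_probability(s)
            for k in raw:
                raw[k].append(out[k])
                corr[k].append(out[k + "_corrected"])
        for k in raw:
            assert np.mean(raw[k]) == pytest.approx(4 / 9, abs=0.02)
            assert np.mean(corr[k]) == pytest.approx(1 / 3, abs=0.02)

    def test_color_repeater_never_novel(self):
        chosen = [("cyan", s) for s in ("circle", "star", "triangle") * 20]
        s = make_session(chosen, [0, 1] * 30)
        out = novel_choice_probability(s)
        assert out["rwd"] == 0.0
        assert out["norwd"] == 0.0

    def test_omission_boosts_novelty_for_sticky_explorers(self):
        p = AgentParams(0.95, 0.3, 0.05, 0.9)
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(10):
            s = agent.simulate_session(p, 500, seed=rng)
            out = novel_choice_probability(s)
            diffs.append(out["norwd"] - out["rwd"])
        assert np.mean(diffs) > 0

    def test_too_short_session_raises(self):
        with pytest.raises(ValueError):
            novel_choice_probability(make_session([("cyan", "circle")], [1]))


class TestChoiceAutocorrelation:
    def test_constant_sequence_is_null(self):
        s = make_session([("cyan", "circle")] * 30, [1] * 30)
        assert np.all(np.isnan(choice_autocorrelation(s, 3)))

    def test_strict_alternation_gives_minus_one_at_lag_one(self):
        chosen = [("cyan", "circle"), ("magenta", "star")] * 25
        s = make_session(chosen, [1] * 50)
        ac = choice_autocorrelation(s, 2)
        assert ac[0] == pytest.approx(-1.0)
        assert ac[1] == pytest.approx(1.0)

    def test_stickier_dynamics_raise_autocorrelations(self):
        sticky = AgentParams(0.995, 0.3, 0.2, 0.3)
        loose = AgentParams(0.9, 0.3, 0.2, 0.3)
        rng = np.random.default_rng(19)
        ac_s = np.mean(
            [
                choice_autocorrelation(agent.simulate_session(sticky, 500, seed=rng), 9)
                for _ in range(8)
            ],
            axis=0,
        )
        ac_l = np.mean(
            [
                choice_autocorrelation(agent.simulate_session(loose, 500, seed=rng), 9)
                for _ in range(8)
            ],
            axis=0,
        )
        assert np.all(ac_s > ac_l)


class TestSwitchKernel:
    def _wsls_session(self, n_runs=60, run_len=8):
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen, rewards = [], []
        for r in range(n_runs):
            stim = pool[r % 3]
            chosen.extend([stim] * run_len)
            rewards.extend([1] * (run_len - 1) + [0])  # switch iff unrewarded
        return make_session(chosen, rewards)

    def test_win_stay_lose_shift_has_sharp_kernel(self):
        weights, fit = switch_triggered_kernel(
            self._wsls_session(), min_run=5, max_lag=6
        )
        assert weights[0] == pytest.approx(0.0)
        assert np.all(weights[1:6] > 0.85)
        assert fit.last < 0.05
        assert fit.decay < 0.3

    def test_min_run_insensitivity_without_run_length_dependence(self):
        # choices switch with a fixed hazard, independent of run length and
        # of the iid reward stream, so the reward history preceding a switch
        # is flat and identical whichever minimum run length qualifies
        rng = np.random.default_rng(21)
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen = [pool[0]]
        for t in range(1, 8000):
            if rng.random() < 0.08:
                chosen.append(pool[(pool.index(chosen[-1]) + 1) % 3])
            else:
                chosen.append(chosen[-1])
        rewards = rng.integers(0, 2, size=8000).tolist()
        s = make_session(chosen, rewards)
        w5, fit5 = switch_triggered_kernel(s, min_run=5)
        w10, fit10 = switch_triggered_kernel(s, min_run=10)
        assert np.nanmax(np.abs(w5 - w10)) < 0.1
        assert abs(fit5.last - fit10.last) < 0.05

    def test_stickier_rule_states_need_longer_evidence(self):
        # raising p(stay in rule | no reward) -- the signature of deepened
        # rule attractors -- stretches the pre-switch reward deficit over
        # more trials, which the fit expresses as a larger decay timescale
        rng = np.random.default_rng(23)
        sticky = AgentParams(0.995, 0.1, 0.6, 0.4)
        loose = AgentParams(0.995, 0.1, 0.02, 0.4)
        s_sessions = [agent.simulate_session(sticky, 600, seed=rng) for _ in range(8)]
        l_sessions = [agent.simulate_session(loose, 600, seed=rng) for _ in range(8)]
        _, fit_sticky = switch_triggered_kernel(s_sessions)
        _, fit_loose = switch_triggered_kernel(l_sessions)
        assert fit_sticky.decay > fit_loose.decay

    def test_no_switches_raises(self):
        s = make_session([("cyan", "circle")] * 30, [1] * 30)
        with pytest.raises(ValueError):
            switch_triggered_kernel(s)


class TestMixture:
    def test_half_life_of_rate_ln2_is_one(self):
        fit = fit_exponential_mixture(np.array([1, 2, 3, 4] * 20), k=1)
        assert np.all(np.abs(fit.half_lives - np.log(2) / fit.rates) < 1e-12)
        assert (
            fit_exponential_mixture(np.array([1, 1, 2, 2, 3] * 20), k=1).half_lives[0]
            > 0
        )

    def test_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(25)
        x = np.concatenate(
            [rng.geometric(0.5, 2000), rng.geometric(0.08, 1000)]
        )
        fits, _, _ = select_order(x, k_max=4)
        lls = [f.loglik for f in fits]
        # non-decreasing up to EM convergence tolerance
        assert np.all(np.diff(lls) >= -1e-3)

    def test_single_geometric_selects_one_component(self):
        rng = np.random.default_rng(27)
        x = rng.geometric(0.35, size=20000)
        _, k_aic, k_bic = select_order(x)
        assert k_bic == 1
        assert k_aic in (1, 2)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(29)
        n = 20000
        q_short = np.exp(-np.log(2) / 1.4)
        q_long = np.exp(-np.log(2) / 9.0)
        comp = rng.random(n) < 0.6
        x = np.where(
            comp, rng.geometric(1 - q_short, n), rng.geometric(1 - q_long, n)
        )
        fits, k_aic, k_bic = select_order(x)
        assert k_aic == 2 and k_bic == 2
        fit = fits[1]
        hl = np.sort(fit.half_lives)
        assert abs(hl[0] - 1.4) / 1.4 < 0.1
        assert abs(hl[1] - 9.0) / 9.0 < 0.1

    def test_rejects_non_integer_intervals(self):
        with pytest.raises(ValueError):
            fit_exponential_mixture(np.array([1.5, 2.0]), k=1)


class TestShortStateExcess:
    def test_symmetry_gives_half(self):
        fit = fit_exponential_mixture(np.array([1, 2, 3, 5, 8] * 30), k=2)
        fit.weights = np.array([0.5, 0.5])
        fit.rates = np.array([0.3, 0.3])
        fit.__post_init__()
        assert short_state_excess(fit) == pytest.approx(0.5)

    def test_arithmetic_example(self):
        fit = fit_exponential_mixture(np.array([1, 2, 3, 5, 8] * 30), k=2)
        fit.weights = np.array([0.8, 0.2])
        fit.means = np.array([1.4, 9.0])
        assert short_state_excess(fit) == pytest.approx(
            (0.8 * 1.4) / (0.8 * 1.4 + 0.2 * 9.0), abs=1e-12
        )

    def test_requires_two_components(self):
        fit = fit_exponential_mixture(np.array([1, 2, 3] * 30), k=1)
        with pytest.raises(ValueError):
            short_state_excess(fit)

    def test_simulated_explore_state_yields_excess_above_half(self):
        rng = np.random.default_rng(31)
        intervals = np.concatenate(
            [
                interswitch_intervals(
                    agent.simulate_session(MONKEY_B_BASELINE, 600, seed=rng)
                )
                for _ in range(10)
            ]
        )
        fit = fit_exponential_mixture(intervals, k=2)
        assert short_state_excess(fit) > 0.5


class TestExploreMutualInformation:
    def test_history_independent_choices_match_null(self):
        s = agent.simulate_session(UNIFORM_CHOOSER, 2000, seed=33)
        out = explore_mutual_information(
            s, s["latent_state"].to_numpy(), n_shuffles=100, seed=1
        )
        for cond in out.values():
            null_sd = cond["null"].std()
            assert abs(cond["mi"] - cond["null_mean"]) < 4 * max(null_sd, 1e-3)

    def test_deterministic_history_dependence_beats_null(self):
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen = [pool[0]]
        for t in range(1, 400):
            chosen.append(pool[(pool.index(chosen[-1]) + 1) % 3])
        s = make_session(chosen, [1, 0] * 200)
        labels = np.array(["explore"] * 400)
        out = explore_mutual_information(s, labels, n_shuffles=50, seed=2)
        for cond in out.values():
            assert cond["mi"] > cond["null_mean"]
            assert cond["mi"] == pytest.approx(np.log2(3), abs=0.05)

    def test_mi_nonnegative(self, session_b):
        out = explore_mutual_information(
            session_b, session_b["latent_state"].to_numpy(), n_shuffles=20, seed=3
        )
        for cond in out.values():
            assert cond["mi"] >= 0
            assert np.all(cond["null"] >= 0)


class TestLogOddsRatio:
    def test_identity_and_symmetry(self):
        assert log_odds_ratio(0.4, 0.4) == 0.0
        assert log_odds_ratio(0.5, 0.2) == pytest.approx(-log_odds_ratio(0.2, 0.5))

    def test_worked_value(self):
        assert log_odds_ratio(0.8, 0.2) == pytest.approx(2 * np.log(4))

    def test_boundaries_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                log_odds_ratio(bad, 0.5)
            with pytest.raises(ValueError):
                log_odds_ratio(0.5, bad)


class TestRepeatAfterError:
    def test_invalid_horizon(self, session_b):
        labels = label_errors(session_b)
        with pytest.raises(ValueError):
            repeat_after_error_probability(session_b, labels, horizon=0)

    def test_never_repeating_agent_scores_zero(self):
        pool = [("cyan", "circle"), ("magenta", "star"), ("yellow", "triangle")]
        chosen = [pool[t % 3] for t in range(40)]
        rewards = [0] * 40
        blocks = [0] * 20 + [1] * 20
        s = make_session(chosen, rewards, blocks)
        labels = label_errors(s)
        out = repeat_after_error_probability(s, labels, horizon=2)
        for v in out.values():
            if not np.isnan(v):
                assert v == 0.0

    def test_uniform_chooser_classes_agree(self):
        rng = np.random.default_rng(35)
        lapse_vals, other_vals = [], []
        for _ in range(20):
            s = agent.simulate_session(UNIFORM_CHOOSER, 500, seed=rng)
            labels = label_errors(s)
            out = repeat_after_error_probability(s, labels, horizon=2)
            lapse_vals.append(out["lapse"])
            other_vals.append(out["other_error"])
        assert abs(np.nanmean(lapse_vals) - np.nanmean(other_vals)) < 0.05
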