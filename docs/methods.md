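# Methods

## The task

The simulated environment is a conceptual set-shifting task (CSST), a
primate analogue of the Wisconsin Card Sorting Task. Each trial offers three
compound stimuli drawn from 3 colors (cyan, magenta, yellow) x 3 shapes
(circle, star, triangle), arranged as a color<->shape bijection: every color
and every shape appears exactly once, so exactly one option matches any
given feature. One of the six features is the rewarded *rule*; choosing the
option that carries it yields reward. After 15 correct responses the rule
changes, uncued. By default the new rule is drawn uniformly from the other
five features; a `allow_rule_repeat` flag restores draws over all six
(repeats would produce invisible change points, which is why exclusion is
the default). Stimulus positions are randomized and recorded but carry no
behavioral consequence; presentation timing is not modeled.

Exhaustive enumeration over the six bijections and all previous-choice
configurations gives the chance baselines used for normalization: a random
lapse changes exactly one stimulus dimension with probability 1/3 and both
dimensions with probability 2/3, and a uniformly random choice is *novel*
(shares neither feature with the previous choice) with probability 4/9.
These are returned as exact rationals.

## The generative agent

The agent (`setshift.agent`) is an input-output hidden Markov process with
seven latent states: one *explore* state and six *rule* states. In a rule
state it deterministically chooses the option carrying the rule feature; in
explore it chooses uniformly among the three options. The state evolves
between trials, gated by the previous trial's reward, with four parameters:

| parameter | meaning | typical fitted range |
|---|---|---|
| `p_rule_stay_rwd` | stay in the current rule after a reward | 0.97-0.999 |
| `p_rule_stay_norwd` | stay in the rule after an omission | 0.02-0.2 |
| `p_explore_stay_rwd` | remain exploring after a reward | 0.25-0.75 |
| `p_explore_stay_norwd` | remain exploring after an omission | 0.15-0.55 |

Rule-to-different-rule transitions never occur: a new rule can only be
adopted from explore. On leaving explore the simulator adopts a rule
matching one of the two features of the last choice, chosen at random
(`explore_to_rule="last_choice"`); a `"uniform"` variant draws the adopted
rule uniformly over all six, exactly matching the fitted model's convention
(see below). The first trial of a session always starts in explore, and the
reward input "before" trial 1 is treated as an omission; state transitions
are evaluated between trials, so the state of trial t depends only on the
state and reward of trial t-1.

The generator is the package's synthetic-data source: every downstream
statistic is validated on sessions whose latent states are known. What it
deliberately does not emulate: within-session drifts (satiety, fatigue),
response times and eye movements, and any anticipation of change points.
Passing tests therefore demonstrate correctness of the machinery on data
obeying the model's assumptions, not that real behavior obeys them.

## The fitted model

`setshift.hmm` implements the inference side. The two 7x7 transition plates
(one per reward outcome) are tied: all rule states share one stay
probability, with the remainder going to explore; the explore row
distributes its leave probability uniformly over the six rules (1/6 each).
This deliberately differs from the simulator's last-choice constraint — the
fitting model must not assume knowledge of the choice sequence inside its
transition kernel. Emissions are 1/3 per option in explore and an indicator
of rule consistency in rule states; the initial distribution is a point
mass on explore.

Likelihoods use scaled forward-backward; an observation sequence that is
impossible under degenerate parameters reports `-inf` rather than raising.
Fitting is Baum-Welch EM with the M-step pooling expected transition counts
across the tied entries within each plate. Numerical choices:

- restarts: stay probabilities initialized Uniform(0.05, 0.95); the default
  is 100 restarts, and tests use 3 (the 4-parameter likelihood is
  well-behaved; restarts rarely disagree).
- convergence: relative log-likelihood improvement < 1e-6, cap 1000
  iterations.
- a parameter floor of 1e-6 keeps all rows strictly positive, so no restart
  can pin a transition at an absorbing zero.
- Viterbi ties break toward explore (conservative labeling of exploration);
  "most probable cause" labels come from the Viterbi path by default, with
  posterior-argmax decoding behind a flag.
- fitting is per session by default; a list of sessions is fitted pooled
  (used for simulation studies).

Parameter recovery is validated with the `"uniform"` generator variant
because the simulator/model mismatch otherwise biases
`p_rule_stay_norwd` upward: post-change runs in which the simulator adopts
a rule sharing a feature of the last (old-rule) choice look like rule
persistence through omissions to the fitted model. The rule-stay
probabilities recover to ~0.01-0.02 median absolute error per plate at 600
trials per session; the explore-stay probabilities are weakly identified in
single sessions (explore episodes are short and sparse), which matches the
large across-session spread of per-session estimates reported for this
model class.

### Stationary distributions and attractor depth

Each plate's stationary distribution is its eigenvalue-1 left eigenvector,
normalized; the explore entry is read as the *relative depth* of the
exploration attractor under that outcome's dynamics. Because rule
parameters are tied, the 7-state chain collapses to two effective states
with the closed form pi_explore = (1-a) / ((1-a) + (1-b)), a = rule-stay,
b = explore-stay; the eigenvector route and the closed form agree to 1e-12
and both satisfy piA = pi to 1e-10. When the eigenvalue-1 eigenspace is not
a unique nonnegative distribution (e.g. all stay probabilities exactly 1),
`StationaryNotFound` is raised and the session is excluded from depth
analyses rather than silently patched.

## Behavioral statistics

Error taxonomy (`stats.label_errors`): a *change point* sits between the
last trial of one block and the first trial of the next. The stable
pre-change window is the 10 trials ending at the last pre-change trial; the
post-change window is the 5 trials from the first post-change trial.
*Lapses* are pre-window errors deviating from the previous choice in at
least one dimension; *perseverative errors* are post-window errors
repeating at least one dimension; deviating errors elsewhere are
*lapse-like*; the remainder (exact repeats outside the post window, or the
first trial, whose dimension change is undefined) are *other errors*.
Categories are mutually exclusive per trial. Lapse rate is lapses per
pre-window trial; perseverative fraction is perseverative errors per error
trial in the post-change epoch (undefined, and excluded from aggregates,
when that epoch holds no errors). Dimension-change counts are normalized by
the 1/3 / 2/3 chance expectations above.

Outcome effect index: [p(repeat_t | reward_{t-tau}=1) - p(repeat_t |
reward_{t-tau}=0)] / p(repeat_t), computed per feature dimension and
averaged over color and shape; the normalization controls for baseline
repetition tendencies. Its decay over lags 1..5 is fitted as
index(tau) = offset + scale * exp(-alpha * (tau-1)), so scale is the
influence of the most recent outcome and alpha the learning rate. Flat
curves are flagged degenerate instead of reporting an arbitrary alpha.

Novel choices: frequencies of zero-shared-feature choices split by the
previous outcome, reported both raw and availability-corrected (novel
choices divided by novel options offered; a uniform chooser scores 4/9 raw
and exactly 1/3 corrected).

Switch-triggered reward history: switches are changes of chosen color (or
shape) after at least `min_run` = 5 identical choices, runs tracked
independently per feature dimension. The empirical kernel is the
probability of reward at lags 1..max_lag before a switch, fitted with
weight(tau) = 1 - (1-last) * exp(-(tau-1)/decay): `last` is the reward
probability on the trial immediately preceding the switch and `decay`
(trials) the kernel timescale. This parameterization was chosen over the
superficially simpler 1 - last*exp(-decay*(tau-1)) because only it
satisfies the optimal-decision-maker limit (switch iff the last trial went
unrewarded => last = 0 and decay -> 0) while making longer
evidence-accumulation kernels correspond to larger decay.

Interswitch intervals are treated as geometric ("discrete exponential")
with half-life ln2/rate; mixtures are fitted by EM on unique-value counts
with deterministic quantile initialization, and orders compared by AIC/BIC
with parameters counted as k rates + (k-1) weights. The short-state excess
of a 2-component fit is weight*mean of the short component over the total,
compared against 0.5.

Mutual information between explore-labeled choices and the previous choice
uses the plug-in estimate over the 9 stimulus identities, split by previous
outcome, against a within-split shuffle null.

## Study-level analyses

Treatment-vs-practice effects use OLS of a session statistic on an
intercept, a treatment step, a session-number ramp, and a monkey dummy;
explore-depth rows (session x plate) add reward, treatment, their
interaction, monkey and session terms. Covariation-axis projections fit an
OLS line to baseline sessions only and project every session's pair onto
that line's unit direction. Condition contrasts are Welch two-sample
t-tests with Satterthwaite degrees of freedom. Per-block perseveration is
compared across three single-predictor binomial models (previous-block
lapse rate, previous-block learning rate — operationalized as the
outcome-decay alpha fitted within that block — and global session lapse
rate) with AIC/BIC weights. Lag-wise contrasts of choice autocorrelations
use Holm-Bonferroni correction.

The grid study draws agent parameter quadruples uniformly in [0,1]^4,
simulates each in the task, and records reward and lapse rates. The
reward-optimal parameter set is the geometric mean over draws whose reward
probability lies within 1% (relative) of the grid maximum, widening to 2%
with a warning if fewer than two draws qualify. Default sizes are 3,000
draws x 2 sessions x 500 trials per draw, chosen as a desk-scale version of
the full study (15,000 x 100 x 500, available through configuration). At
the scaled size the per-draw reward estimate has a standard error of about
0.015, so the top-band membership is partly noise-driven and the optimum
estimate is correspondingly variable; the parameter-lapse correlation is
attenuated by lapse-rate estimation noise. Both caveats are inherent to the
scaled size, not to the method.

Change-point-aligned permutation tests compare the decoded explore-label
frequency per trial offset against a within-session label-shuffle null
(100 shuffles, 2.5% tails). Offset 0 is the first trial after the rule
changed. Because transitions are gated by the *previous* trial's reward,
the change is invisible to the agent until the inevitable error at offset 0
has been experienced: decoded exploration is therefore below chance at
offset 0 and above chance from offset 1 on. Analyses of "post-change
exploration" in this package consequently read offset 1 as the first
post-feedback bin.

## Known limitations

- The generative agent has no within-session nonstationarity, so session-
  level trends (error rates rising late in a session) cannot be reproduced,
  only analyzed when present in data.
- Because the agent's latent states persist for many trials, its outcome
  effect index need not decay over lags 1-5: the normalizing p(repeat)
  falls with lag at least as fast as the conditional difference. Decay of
  the index is a signature of one-step learners (and of subjects), not of
  every state-persistent process; the decay-fit machinery is validated on
  constructed one-step data.
- Conditioning switches on long same-feature runs (min_run) selects
  rule-dominated contexts in the agent, so kernels can differ between
  min_run settings even though the agent's switching has no run-length
  dependence; run-length insensitivity holds for genuinely fixed-hazard
  switching.
- Explore-stay parameters are weakly identified from single short sessions;
  pooled fits are recommended for simulation studies.
- The grid study's optimum is a noisy order statistic at desk scale (see
  above).
- Real-data effect sizes from the motivating experimental literature are
  treated as directional checks only; no deposited dataset ships with the
  package.
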