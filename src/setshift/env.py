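"""Simulated conceptual set-shifting task (CSST) environment.

The CSST is a primate analogue of the Wisconsin Card Sorting Task. On every
trial three compound stimuli are offered, each defined by one of three colors
and one of three shapes, arranged so that every color and every shape appears
exactly once. One of the six features (a color or a shape) is the rewarded
*rule*; choosing the option carrying that feature yields reward. After 15
correct choices under a rule the rule changes, uncued.

This module owns the task combinatorics: drawing option sets, stepping the
rule/block bookkeeping, and the analytic chance probabilities implied by the
3 x 3 feature design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

COLORS = ("cyan", "magenta", "yellow")
SHAPES = ("circle", "star", "triangle")
FEATURES = COLORS + SHAPES  # canonical feature order; indices 0-2 colors, 3-5 shapes
N_FEATURES = 6
N_OPTIONS = 3
CORRECT_PER_BLOCK = 15

#: The 6 color->shape bijections, in a fixed order. ``PERMUTATIONS[pid - 1][i]``
#: is the shape index paired with color index ``i`` under permutation id ``pid``.
PERMUTATIONS = tuple(itertools.permutations(range(3)))


@dataclass(frozen=True)
class Stimulus:
    """A compound option: exactly one color and one shape."""

    color: str
    shape: str

    def __post_init__(self):
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def features(self) -> tuple[str, str]:
        return (self.color, self.shape)

    def matches(self, feature: str) -> bool:
        return feature in (self.color, self.shape)

    def shared_features(self, other: "Stimulus") -> int:
        return int(self.color == other.color) + int(self.shape == other.shape)


@dataclass(frozen=True)
class Rule:
    """The currently rewarded feature (a color or a shape)."""

    feature: str

    def __post_init__(self):
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")


@dataclass(frozen=True)
class OptionSet:
    """An ordered triple of stimuli forming a color<->shape bijection.

    Each of the three colors and three shapes appears exactly once, so exactly
    one option matches any given feature.
    """

    options: tuple[Stimulus, Stimulus, Stimulus]
    permutation_id: int  # 1..6, identifies the color->shape bijection

    def __post_init__(self):
        if len(self.options) != N_OPTIONS:
            raise ValueError("an option set holds exactly 3 options")
        if sorted(o.color for o in self.options) != sorted(COLORS):
            raise ValueError("each color must appear exactly once")
        if sorted(o.shape for o in self.options) != sorted(SHAPES):
            raise ValueError("each shape must appear exactly once")
        if not 1 <= self.permutation_id <= 6:
            raise ValueError("permutation_id must be in 1..6")

    def index_matching(self, feature: str) -> int:
        """Index (0-based) of the unique option carrying ``feature``."""
        for i, opt in enumerate(self.options):
            if opt.matches(feature):
                return i
        raise ValueError(f"no option matches {feature!r}")  # pragma: no cover


@dataclass(frozen=True)
class EnvState:
    """Rule and block bookkeeping between trials."""

    rule: Rule
    correct_in_block: int = 0
    block_index: int = 0

    def __post_init__(self):
        if not 0 <= self.correct_in_block < CORRECT_PER_BLOCK:
            raise ValueError("correct_in_block must be in [0, 15)")


def permutation_id_of(options) -> int:
    """Recover the 1-based bijection id from a triple of stimuli."""
    mapping = [None] * 3
    for opt in options:
        mapping[COLORS.index(opt.color)] = SHAPES.index(opt.shape)
    return PERMUTATIONS.index(tuple(mapping)) + 1


def draw_option_set(rng: np.random.Generator) -> OptionSet:
    """Draw an option set uniformly over the 6 bijections x 6 position orders."""
    pid = int(rng.integers(6))
    perm = PERMUTATIONS[pid]
    stimuli = [Stimulus(COLORS[i], SHAPES[perm[i]]) for i in range(3)]
    order = rng.permutation(3)
    return OptionSet(tuple(stimuli[i] for i in order), permutation_id=pid + 1)


def draw_rule(rng: np.random.Generator, exclude: str | None = None) -> Rule:
    """Draw a rule uniformly, optionally excluding the outgoing one."""
    pool = [f for f in FEATURES if f != exclude]
    return Rule(pool[int(rng.integers(len(pool)))])


def initial_state(rng: np.random.Generator) -> EnvState:
    return EnvState(rule=draw_rule(rng))


def step(
    state: EnvState,
    chosen: Stimulus,
    rng: np.random.Generator,
    *,
    allow_rule_repeat: bool = False,
) -> tuple[bool, EnvState]:
    """Deliver reward for ``chosen`` and advance the block bookkeeping.

    Reward is delivered iff the chosen option carries the rule feature. On the
    15th correct choice the block ends and a new rule is drawn uniformly over
    the other five features (over all six if ``allow_rule_repeat``).
    """
    reward = chosen.matches(state.rule.feature)
    if not reward:
        return False, state
    n_correct = state.correct_in_block + 1
    if n_correct < CORRECT_PER_BLOCK:
        return True, EnvState(state.rule, n_correct, state.block_index)
    exclude = None if allow_rule_repeat else state.rule.feature
    new_rule = draw_rule(rng, exclude=exclude)
    return True, EnvState(new_rule, 0, state.block_index + 1)


def chance_probabilities() -> dict[str, Fraction]:
    """Analytic chance baselines, by exhaustive enumeration.

    Enumerates every previous choice, every feature of it as the putative rule,
    and every color->shape bijection for the next trial's option set, and
    counts:

    - ``change1`` / ``change2``: probability that a random lapse (an error
      deviating from the previous, rewarded choice) changes exactly 1 or 2
      stimulus dimensions;
    - ``novel``: probability that a uniformly random choice shares neither
      feature with the previous choice.
    """
    change_counts = {1: Fraction(0), 2: Fraction(0)}
    n_lapse_configs = 0
    novel = Fraction(0)
    n_configs = 0
    for c0 in COLORS:
        for s0 in SHAPES:
            prev = Stimulus(c0, s0)
            for perm in PERMUTATIONS:
                opts = [Stimulus(COLORS[i], SHAPES[perm[i]]) for i in range(3)]
                novel += Fraction(
                    sum(o.shared_features(prev) == 0 for o in opts), N_OPTIONS
                )
                n_configs += 1
                # Lapses: the previous choice was rewarded, so the rule is one
                # of its two features; error options are the two others.
                for rule_feature in prev.features:
                    errors = [o for o in opts if not o.matches(rule_feature)]
                    n_lapse_configs += 1
                    for err in errors:
                        d = 2 - err.shared_features(prev)
                        change_counts[d] += Fraction(1, len(errors))
    return {
        "change1": change_counts[1] / n_lapse_configs,
        "change2": change_counts[2] / n_lapse_configs,
        "novel": novel / n_configs,
    }
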