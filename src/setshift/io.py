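"""Session-table formats, configuration, and reproducibility plumbing.

Sessions are stored as UTF-8 CSV with one row per trial and 1-based trial
and choice indices. Parameters and fit results are serialized as JSON.
Configuration is a flat ``key = value`` text file.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import pandas as pd

from .agent import EXPLORE, AgentParams, state_feature
from .env import COLORS, FEATURES, SHAPES

SESSION_COLUMNS = [
    "session_id",
    "monkey",
    "condition",
    "trial_index",
    "block_index",
    "rule",
    "opt1_color",
    "opt1_shape",
    "opt2_color",
    "opt2_shape",
    "opt3_color",
    "opt3_shape",
    "choice_index",
    "reward",
]
OPTIONAL_COLUMNS = ["latent_state"]


class SessionFormatError(ValueError):
    pass


def validate_session_table(table: pd.DataFrame) -> None:
    """Schema validation; raises SessionFormatError naming the offending row."""
    missing = [c for c in SESSION_COLUMNS if c not in table.columns]
    if missing:
        raise SessionFormatError(f"missing columns: {missing}")
    checks = [
        ("choice_index", lambda v: v in (1, 2, 3)),
        ("reward", lambda v: v in (0, 1)),
        ("rule", lambda v: v in FEATURES),
    ]
    for j in (1, 2, 3):
        checks.append((f"opt{j}_color", lambda v: v in COLORS))
        checks.append((f"opt{j}_shape", lambda v: v in SHAPES))
    for col, ok in checks:
        bad = [i for i, v in zip(table.index, table[col]) if not ok(v)]
        if bad:
            raise SessionFormatError(
                f"invalid value in column {col!r} at row {bad[0]} "
                f"({table.loc[bad[0], col]!r})"
            )
    if "latent_state" in table.columns:
        for i, v in zip(table.index, table["latent_state"]):
            if v != EXPLORE:
                try:
                    state_feature(v)
                except ValueError:
                    raise SessionFormatError(
                        f"invalid latent_state at row {i} ({v!r})"
                    ) from None
    for sid, group in table.groupby("session_id", sort=False):
        t = group["trial_index"].to_numpy()
        if not (t[1:] > t[:-1]).all():
            raise SessionFormatError(
                f"trial_index not strictly increasing within session {sid!r}"
            )


def check_reward_consistency(session: pd.DataFrame) -> list[int]:
    """Trial indices whose reward flag contradicts the rule and chosen option.

    Returns the inconsistent 1-based trial indices and warns when any exist.
    """
    bad = []
    for _, row in session.iterrows():
        j = int(row["choice_index"])
        match = row["rule"] in (row[f"opt{j}_color"], row[f"opt{j}_shape"])
        if int(row["reward"]) != int(match):
            bad.append(int(row["trial_index"]))
    if bad:
        warnings.warn(
            f"reward column inconsistent with rule+choice at trials {bad[:20]}"
            + ("..." if len(bad) > 20 else "")
        )
    return bad


def write_sessions(sessions, path) -> None:
    """Write one or more session tables to a single CSV."""
    if isinstance(sessions, pd.DataFrame):
        sessions = [sessions]
    table = pd.concat(sessions, ignore_index=True)
    validate_session_table(table)
    table.to_csv(path, index=False)


def read_sessions(path) -> list[pd.DataFrame]:
    """Read a session CSV, validate it, and split it into per-session tables."""
    table = pd.read_csv(path)
    validate_session_table(table)
    return [
        group.reset_index(drop=True)
        for _, group in table.groupby("session_id", sort=False)
    ]


def write_params(params: AgentParams, path) -> None:
    Path(path).write_text(json.dumps(params.as_dict(), indent=2) + "\n")


def read_params(path) -> AgentParams:
    return AgentParams.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class RunConfig:
    """Defaults for every tunable of the pipeline; overridable from a flat
    ``key = value`` config file."""

    seed: int = 0
    pre_window: int = 10
    post_window: int = 5
    min_run: int = 5
    em_restarts: int = 100
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    grid_draws: int = 3000
    grid_sessions_per_draw: int = 2
    grid_trials_per_session: int = 500
    allow_rule_repeat: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "bool": lambda s: s.lower() in ("1", "true", "yes")}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = casts[fields[key]](value.strip())
        return cls(**values)
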