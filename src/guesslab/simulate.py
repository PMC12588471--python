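"""Trial-level simulator for the forced-choice guessing paradigm.

Each session consists of 36 guessing trials: the subject (a human participant
or, in counterfactual arms, a random event generator substituting for the
participant) guesses which side of the screen hides a reward image, after
which the target side is drawn independently with replacement.  Reward images
are drawn without replacement from a pool of 18 erotic and 18 non-erotic
pictures, which defines the trial condition:

* ``X``  – true-erotic trial (reward shown on a hit),
* ``O``  – true-neutral trial (reward shown on a hit),
* ``SX`` – sham-erotic trial (reward withheld regardless of outcome),
* ``SO`` – sham-neutral trial (reward withheld regardless of outcome).

A *pure* session holds 18 X and 18 O trials; a *mixed* session interleaves 18
true trials (9 X + 9 O) with 18 sham trials (9 SX + 9 SO).

The simulator models the hit process directly: only the hit indicator is
statistically identified, so the human-arm guess side is back-filled to be
consistent with the drawn target side.  Systematic biases can be injected to
emulate class-A (process-level side bias), class-B (drift over repeated
sessions) and class-C (control-condition offset) errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

CONDITIONS = ("X", "O", "SX", "SO")
TRUE_CONDITIONS = ("X", "O")
SHAM_CONDITIONS = ("SX", "SO")
SESSION_TYPES = ("pure", "mixed")
ARMS = ("human", "reg")
SIDES = ("left", "right")

#: Fixed column order of the on-disk trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "session_id",
    "session_type",
    "arm",
    "condition",
    "trial_index",
    "guess_side",
    "target_side",
    "hit",
    "reward_shown",
]

SESSION_LENGTH = 36
MAX_SESSION_LENGTH = 42

_EROTIC_IMAGES = tuple(f"E{i:02d}" for i in range(1, 19))
_NEUTRAL_IMAGES = tuple(f"N{i:02d}" for i in range(1, 19))


@dataclass(frozen=True)
class BiasSpec:
    """Injectable systematic-error parameters.

    ``class_a_side_delta`` shifts P(left) of both the target-side channel and
    the REG guess channel; ``class_b_drift`` adds a per-repeat log-odds drift
    for participants performing several sessions; ``class_c_control_delta``
    adds a log-odds offset to the true-neutral control condition only.
    With all three at zero the simulator is exactly null: the hit indicator
    of every condition is Bernoulli at its configured base rate.
    """

    class_a_side_delta: float = 0.0
    class_b_drift: float = 0.0
    class_c_control_delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < 0.5 + self.class_a_side_delta < 1.0:
            raise ValueError(
                f"class_a_side_delta={self.class_a_side_delta} pushes "
                "P(left) outside (0, 1)"
            )

    @property
    def is_null(self) -> bool:
        return (
            self.class_a_side_delta == 0.0
            and self.class_b_drift == 0.0
            and self.class_c_control_delta == 0.0
        )


def _implied_conditions(session_type: str) -> tuple[str, ...]:
    return TRUE_CONDITIONS if session_type == "pure" else CONDITIONS


@dataclass
class StudyConfig:
    """Full specification of one simulated study arm."""

    n_participants: int
    session_type: str = "pure"
    arm: str = "human"
    base_rates: Mapping[str, float] | None = None
    heterogeneity_sd: float = 0.0
    bias: BiasSpec = field(default_factory=BiasSpec)
    n_trials_target: int | None = None
    incomplete_session_prob: float = 0.0
    overrun_prob: float = 0.005
    overrun_max: int = 42
    sessions_per_participant: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValueError(f"unknown session_type {self.session_type!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        implied = _implied_conditions(self.session_type)
        if self.base_rates is None:
            self.base_rates = {c: 0.5 for c in implied}
        self.base_rates = dict(self.base_rates)
        if set(self.base_rates) != set(implied):
            raise ValueError(
                f"base_rates keys {sorted(self.base_rates)} do not match the "
                f"conditions {sorted(implied)} implied by session_type="
                f"{self.session_type!r}"
            )
        for cond, rate in self.base_rates.items():
            if not 0.0 < rate < 1.0:
                raise ValueError(f"base rate for {cond} must lie in (0,1)")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if not 0.0 <= self.incomplete_session_prob < 1.0:
            raise ValueError("incomplete_session_prob must lie in [0, 1)")
        if not 0.0 <= self.overrun_prob < 1.0:
            raise ValueError("overrun_prob must lie in [0, 1)")
        if not SESSION_LENGTH <= self.overrun_max <= MAX_SESSION_LENGTH:
            raise ValueError("overrun_max must lie in [36, 42]")
        if self.sessions_per_participant < 1:
            raise ValueError("sessions_per_participant must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        if "bias" in data and not isinstance(data["bias"], BiasSpec):
            data["bias"] = BiasSpec(**data["bias"])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "session_type": self.session_type,
            "arm": self.arm,
            "base_rates": dict(self.base_rates),
            "heterogeneity_sd": self.heterogeneity_sd,
            "bias": {
                "class_a_side_delta": self.bias.class_a_side_delta,
                "class_b_drift": self.bias.class_b_drift,
                "class_c_control_delta": self.bias.class_c_control_delta,
            },
            "n_trials_target": self.n_trials_target,
            "incomplete_session_prob": self.incomplete_session_prob,
            "overrun_prob": self.overrun_prob,
            "overrun_max": self.overrun_max,
            "sessions_per_participant": self.sessions_per_participant,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TrialSpec:
    """Planned trial: condition, position in the session, reward image."""

    condition: str
    trial_index: int
    image_id: str


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    session_id: str
    session_type: str
    arm: str
    condition: str
    trial_index: int
    guess_side: str
    target_side: str
    hit: bool
    reward_shown: bool


def build_session_plan(session_type: str, rng: np.random.Generator) -> list[TrialSpec]:
    """Plan one 36-trial session.

    The condition sequence is a uniform random permutation; the 18 erotic
    images are dealt without replacement onto the erotic-condition trials and
    the 18 neutral images onto the neutral ones, so the 36-image pool is
    exhausted exactly once.
    """
    if session_type not in SESSION_TYPES:
        raise ValueError(f"unknown session_type {session_type!r}")
    if session_type == "pure":
        conds = ["X"] * 18 + ["O"] * 18
    else:
        conds = ["X"] * 9 + ["O"] * 9 + ["SX"] * 9 + ["SO"] * 9
    conds = [conds[i] for i in rng.permutation(SESSION_LENGTH)]
    erotic = list(rng.permutation(np.array(_EROTIC_IMAGES)))
    neutral = list(rng.permutation(np.array(_NEUTRAL_IMAGES)))
    plan = []
    for idx, cond in enumerate(conds, start=1):
        pool = erotic if cond in ("X", "SX") else neutral
        plan.append(TrialSpec(condition=cond, trial_index=idx, image_id=str(pool.pop())))
    return plan


def _hit_probability(
    condition: str,
    participant_effect: float,
    config: StudyConfig,
    session_repeat: int,
) -> float:
    """Human-arm hit probability on the probability scale."""
    eta = logit(config.base_rates[condition]) + participant_effect
    eta += config.bias.class_b_drift * session_repeat
    if condition == "O":
        eta += config.bias.class_c_control_delta
    return float(expit(eta))


def draw_trial_outcome(
    spec: TrialSpec,
    participant_effect: float,
    config: StudyConfig,
    rng: np.random.Generator,
    *,
    participant_id: str = "P0001",
    session_id: str = "S0001",
    session_repeat: int = 0,
) -> TrialRecord:
    """Simulate one trial of the paradigm.

    The target side is always drawn with replacement at
    ``P(left) = 0.5 + class_a_side_delta``.  On the human arm the hit
    indicator is drawn directly at the configured probability and the guess
    side back-filled; on the REG arm the guess is an independent (possibly
    class-A-biased) coin and the hit is the agreement of the two channels.
    """
    if spec.condition not in CONDITIONS:
        raise ValueError(f"unknown condition {spec.condition!r}")
    p_left = 0.5 + config.bias.class_a_side_delta
    target = "left" if rng.random() < p_left else "right"
    if config.arm == "reg":
        guess = "left" if rng.random() < p_left else "right"
        hit = guess == target
    else:
        p_hit = _hit_probability(
            spec.condition, participant_effect, config, session_repeat
        )
        hit = rng.random() < p_hit
        if hit:
            guess = target
        else:
            guess = "right" if target == "left" else "left"
    reward = bool(hit) and spec.condition in TRUE_CONDITIONS
    return TrialRecord(
        participant_id=participant_id,
        session_id=session_id,
        session_type=config.session_type,
        arm=config.arm,
        condition=spec.condition,
        trial_index=spec.trial_index,
        guess_side=guess,
        target_side=target,
        hit=bool(hit),
        reward_shown=reward,
    )


def _session_trial_specs(
    config: StudyConfig, rng: np.random.Generator
) -> list[TrialSpec]:
    """Session plan plus incompleteness / overrun perturbations."""
    plan = build_session_plan(config.session_type, rng)
    if config.incomplete_session_prob > 0 and rng.random() < config.incomplete_session_prob:
        n_keep = int(rng.integers(1, SESSION_LENGTH))
        return plan[:n_keep]
    max_extra = config.overrun_max - SESSION_LENGTH
    if max_extra > 0 and config.overrun_prob > 0 and rng.random() < config.overrun_prob:
        n_extra = int(rng.integers(1, max_extra + 1))
        # latency duplicates: repeat the structure of the first trials
        extras = [
            replace(plan[j], trial_index=SESSION_LENGTH + 1 + j)
            for j in range(n_extra)
        ]
        return plan + extras
    return plan


def simulate_study(config: StudyConfig) -> pd.DataFrame:
    """Simulate a full study arm and return the trial table.

    Participant intercepts are drawn from Normal(0, heterogeneity_sd**2) on
    the log-odds scale (the REG arm has no participant effects).  The output
    is fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[TrialRecord] = []
    session_counter = 0
    for p_idx in range(config.n_participants):
        # the REG arm has no participants: all sessions share one pseudo-id
        pid = "REG" if config.arm == "reg" else f"P{p_idx + 1:05d}"
        if config.arm == "human" and config.heterogeneity_sd > 0:
            effect = float(rng.normal(0.0, config.heterogeneity_sd))
        else:
            effect = 0.0
        for repeat in range(config.sessions_per_participant):
            session_counter += 1
            sid = f"S{session_counter:06d}"
            specs = _session_trial_specs(config, rng)
            # vectorised outcome draws for the whole session
            m = len(specs)
            p_left = 0.5 + config.bias.class_a_side_delta
            target_left = rng.random(m) < p_left
            if config.arm == "reg":
                guess_left = rng.random(m) < p_left
                hits = guess_left == target_left
            else:
                p_hit = np.array(
                    [
                        _hit_probability(s.condition, effect, config, repeat)
                        for s in specs
                    ]
                )
                hits = rng.random(m) < p_hit
                guess_left = np.where(hits, target_left, ~target_left)
            for j, s in enumerate(specs):
                hit = bool(hits[j])
                rows.append(
                    TrialRecord(
                        participant_id=pid,
                        session_id=sid,
                        session_type=config.session_type,
                        arm=config.arm,
                        condition=s.condition,
                        trial_index=s.trial_index,
                        guess_side="left" if guess_left[j] else "right",
                        target_side="left" if target_left[j] else "right",
                        hit=hit,
                        reward_shown=hit and s.condition in TRUE_CONDITIONS,
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows], columns=TRIAL_COLUMNS)


def write_trials(path: str | Path, table: pd.DataFrame) -> None:
    """Write a trial table as CSV with the documented column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


_ENUM_COLUMNS = {
    "session_type": SESSION_TYPES,
    "arm": ARMS,
    "condition": CONDITIONS,
    "guess_side": SIDES,
    "target_side": SIDES,
}
_BOOL_MAP = {"True": True, "False": False, "true": True, "false": False}


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV, validating columns and enum values."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if extra:
        raise ValueError(f"unexpected columns: {extra}")
    table = table[TRIAL_COLUMNS]
    for col, allowed in _ENUM_COLUMNS.items():
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid value {table[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
    for col in ("hit", "reward_shown"):
        bad = ~table[col].isin(_BOOL_MAP)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid boolean {table[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            )
        table[col] = table[col].map(_BOOL_MAP)
    try:
        table["trial_index"] = table["trial_index"].astype(int)
    except ValueError as exc:
        raise ValueError(f"unparseable trial_index: {exc}") from exc
    return table.reset_index(drop=True)
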