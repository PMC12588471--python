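"""Preregistered multi-look sequential design.

The study is evaluated at up to three analysis points — 37,836 (minimum
sample size), 62,388 and 86,958 (maximum) completed trials of the condition
under test.  At each point four tests run simultaneously: the one-sided
Wald-CI rule from the mixed logistic model at a Bonferroni-adjusted level,
and the directional Bayes factor under the uniform, knowledge-based (BUJ)
and replication priors.  Data collection stops the first time all four tests
conclusively support the same model; if no point produces unanimity the
study ends inconclusive at the maximum sample size.

Inclusion rules: incomplete sessions (< 36 trials) are retained to prevent
optional-stopping bias, overrun sessions are retained up to 42 trials, and
everything beyond the pre-specified per-condition sample size is dropped in
arrival order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import PriorSpec, bf01_one_sided, classify_bf, log_bf01
from .freq import (
    aggregate_by_participant,
    ci_level_for_point,
    decide_frequentist,
    fit_random_intercept_logit,
    pooled_interval,
    wald_interval,
    IntervalEstimate,
)
from .simulate import MAX_SESSION_LENGTH

#: Preregistered analysis points (completed trials per analysed condition).
ANALYSIS_POINTS = (37836, 62388, 86958)

#: Pre-specified erotic-trial sample sizes of the consecutive studies
#: (the first study analysed pure- and mixed-session erotic trials at the
#: minimum sequential sample size; the follow-up studies were single-look).
STUDY_EROTIC_TRIALS = {
    "study1_pure": 37836,
    "study1_mixed": 37836,
    "study2": 127000,
    "study3": 217800,
}


def _default_priors() -> tuple[PriorSpec, ...]:
    return (PriorSpec.uniform(), PriorSpec.buj(), PriorSpec.replication())


@dataclass(frozen=True)
class DesignSpec:
    analysis_points: tuple[int, ...] = ANALYSIS_POINTS
    priors: tuple[PriorSpec, ...] = field(default_factory=_default_priors)

    def __post_init__(self) -> None:
        if list(self.analysis_points) != sorted(set(self.analysis_points)):
            raise ValueError("analysis points must be strictly increasing")
        if len(self.priors) != 3:
            raise ValueError(
                "the battery pairs one frequentist CI rule with exactly "
                "three Bayes-factor priors"
            )

    def level(self, point_index: int) -> float:
        if not 1 <= point_index <= len(self.analysis_points):
            raise ValueError(f"no analysis point {point_index}")
        return ci_level_for_point(point_index)


@dataclass(frozen=True)
class PointDecision:
    point_index: int
    n: int
    k: int
    interval: IntervalEstimate
    frequentist: str
    bf01: dict
    bf_support: dict
    joint: str


@dataclass(frozen=True)
class StudyOutcome:
    decision: str  # stop_M0 / stop_M1 / inconclusive
    stop_point: int | None
    point_decisions: list


def joint_decision(frequentist: str, bf_supports) -> str:
    """All-agree stopping rule over the four simultaneous tests."""
    supports = [frequentist, *bf_supports]
    if all(s == "M0" for s in supports):
        return "stop_M0"
    if all(s == "M1" for s in supports):
        return "stop_M1"
    return "continue"


def apply_inclusion_rules(sessions: pd.DataFrame, n_max: int) -> pd.DataFrame:
    """Retain incomplete and overrun sessions, truncate at the target N.

    ``sessions`` must be in completion (arrival) order; the table is cut at
    exactly ``n_max`` trials per condition, dropping later arrivals.
    """
    lengths = sessions.groupby("session_id")["trial_index"].count()
    too_long = lengths[lengths > MAX_SESSION_LENGTH]
    if not too_long.empty:
        sid = too_long.index[0]
        raise ValueError(
            f"session {sid!r} has {int(too_long.iloc[0])} trials "
            f"(> {MAX_SESSION_LENGTH})"
        )
    keep = sessions.groupby("condition").cumcount() < n_max
    return sessions[keep].reset_index(drop=True)


def evaluate_analysis_point(
    trials: pd.DataFrame,
    point_index: int,
    design: DesignSpec = DesignSpec(),
    condition: str = "X",
) -> PointDecision:
    """Run the four-test battery on the condition under analysis at one look."""
    n_expected = design.analysis_points[point_index - 1]
    sub = trials[trials["condition"] == condition]
    n = int(len(sub))
    if n != n_expected:
        raise ValueError(
            f"analysis point {point_index} requires exactly {n_expected} "
            f"{condition} trials, got {n}"
        )
    k = int(sub["hit"].sum())
    single_group = sub["arm"].nunique() == 1 and (sub["arm"] == "reg").all()
    counts = aggregate_by_participant(trials, condition)
    fit = fit_random_intercept_logit(
        counts, sigma_fixed=0.0 if single_group else None
    )
    interval = wald_interval(fit, design.level(point_index))
    freq_support = decide_frequentist(interval)
    bf01 = {}
    bf_support = {}
    for prior in design.priors:
        res = bf01_one_sided(k, n, prior)
        bf01[prior.name] = res.bf01
        bf_support[prior.name] = res.support
    return PointDecision(
        point_index=point_index,
        n=n,
        k=k,
        interval=interval,
        frequentist=freq_support,
        bf01=bf01,
        bf_support=bf_support,
        joint=joint_decision(freq_support, bf_support.values()),
    )


def run_sequential(
    sessions: pd.DataFrame,
    design: DesignSpec = DesignSpec(),
    condition: str = "X",
) -> StudyOutcome:
    """Evaluate the looks in order and stop at the first unanimous point."""
    available = int((sessions["condition"] == condition).sum())
    final_n = design.analysis_points[-1]
    if available < final_n:
        raise ValueError(
            f"session stream holds {available} {condition} trials but the "
            f"design needs {final_n}; short by {final_n - available}"
        )
    decisions = []
    for idx, n_point in enumerate(design.analysis_points, start=1):
        truncated = apply_inclusion_rules(sessions, n_point)
        decision = evaluate_analysis_point(truncated, idx, design, condition)
        decisions.append(decision)
        if decision.joint != "continue":
            return StudyOutcome(
                decision=decision.joint, stop_point=idx, point_decisions=decisions
            )
    return StudyOutcome(decision="inconclusive", stop_point=None, point_decisions=decisions)


def decide_counts(k, point_index: int, design: DesignSpec = DesignSpec()):
    """Vectorised joint decision from pooled success counts at one look.

    Applies the pooled-binomial version of the Wald-CI rule (exact for
    homogeneous participants) plus the three Bayes factors.  ``k`` may be an
    array of Monte-Carlo replicates; returns an array of
    ``{stop_M0, stop_M1, continue}`` codes (0/1/2 as int8: continue=0,
    stop_M0=1, stop_M1=2).
    """
    n = design.analysis_points[point_index - 1]
    k = np.atleast_1d(np.asarray(k))
    lo, hi, _ = pooled_interval(k, n, ci_level_for_point(point_index))
    freq_m0 = hi < 0.51
    freq_m1 = lo > 0.5
    all_m0 = freq_m0.copy()
    all_m1 = freq_m1.copy()
    for prior in design.priors:
        bf = np.exp(log_bf01(k, n, prior.alpha, prior.beta))
        all_m0 &= bf > 25.0
        all_m1 &= bf < 1.0 / 25.0
    out = np.zeros(k.shape, dtype=np.int8)
    out[all_m0] = 1
    out[all_m1] = 2
    return out
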