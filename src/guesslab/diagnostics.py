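"""Meta-experimental diagnostics: condition battery, class-A checks, calibration.

The counterfactual layer of the protocol runs the analysis battery not only
on the experimental condition but on every condition and arm present —
true-neutral and sham trials performed by participants, and REG-substituted
arms performed with no participant at all.  A non-null result on any REG arm
is evidence of class-A error (bias in the overall measurement process), since
the independent variable is absent there by construction.  Side-bias checks
verify the left/right channels of the random event generator directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .bayes import DEFAULT_PRIORS, PriorSpec, bf01_one_sided
from .freq import (
    aggregate_by_participant,
    confirm_bidirectional,
    fit_random_intercept_logit,
    pooled_interval,
    wald_interval,
)
from .power import PowerQuery, analytic_power
from .sequential import DesignSpec
from . import power as _power


@dataclass(frozen=True)
class ConditionReport:
    condition: str
    arm: str
    n: int
    k: int
    hit_pct: float
    se_pct: float
    p_value: float
    bf01: dict
    decision: str


@dataclass(frozen=True)
class ClassAReport:
    rejections: dict
    bias_estimate: float
    bias_ci: tuple
    alpha: float
    verdict: str


def condition_battery(
    trials: pd.DataFrame,
    priors: tuple = DEFAULT_PRIORS,
    level: float = 0.95,
) -> list[ConditionReport]:
    """One report per (condition, arm) present in the table.

    Human arms are analysed with the random-intercept model over participant
    counts; REG arms, which have no grouping structure, with the pooled
    binomial fit.  The reported decision is the two-sided confirmation rule:
    ``deviation`` when chance lies outside the CI, else ``null``.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    reports = []
    for (cond, arm), sub in trials.groupby(["condition", "arm"], sort=True):
        n = int(len(sub))
        k = int(sub["hit"].sum())
        counts = aggregate_by_participant(sub, cond)
        fit = fit_random_intercept_logit(
            counts, sigma_fixed=0.0 if arm == "reg" else None
        )
        interval = wald_interval(fit, level)
        bfs = {
            name: bf01_one_sided(k, n, PriorSpec.named(name)).bf01 for name in priors
        }
        decision = "deviation" if (
            np.isclose(level, 0.95) and confirm_bidirectional(interval)
        ) else "null"
        reports.append(
            ConditionReport(
                condition=cond,
                arm=arm,
                n=n,
                k=k,
                hit_pct=100.0 * k / n,
                se_pct=interval.se_pct,
                p_value=interval.p_value,
                bf01=bfs,
                decision=decision,
            )
        )
    return reports


def class_a_check(reg_trials: pd.DataFrame, alpha: float = 0.05) -> ClassAReport:
    """Test REG-arm hit rates against chance to detect class-A error.

    Each condition gets a two-sided pooled Wald test of p = 0.5 at ``alpha``;
    any rejection flags the whole arm, because a participant-absent process
    deviating from chance can only reflect bias in the measurement pipeline.
    The pooled deviation of the hit rate from 0.5 is reported with a
    (1 - alpha) CI as the estimated bias magnitude.
    """
    if reg_trials.empty:
        raise ValueError("no REG trials supplied")
    if (reg_trials["arm"] != "reg").any():
        raise ValueError("class-A check takes REG-arm trials only")
    rejections = {}
    for cond, sub in reg_trials.groupby("condition", sort=True):
        k, n = int(sub["hit"].sum()), len(sub)
        _, _, p_value = pooled_interval(np.array([k]), n, 1.0 - alpha)
        rejections[cond] = bool(p_value[0] < alpha)
    k_all, n_all = int(reg_trials["hit"].sum()), len(reg_trials)
    p_hat = k_all / n_all
    lo, hi = proportion_confint(k_all, n_all, alpha=alpha, method="normal")
    verdict = "class_a_detected" if any(rejections.values()) else "no_evidence"
    return ClassAReport(
        rejections=rejections,
        bias_estimate=p_hat - 0.5,
        bias_ci=(lo - 0.5, hi - 0.5),
        alpha=alpha,
        verdict=verdict,
    )


def side_bias_check(trials: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """95% CIs for P(left target) and P(left guess) per condition.

    The containment flags are True when the CI covers the theoretically
    expected 0.5, i.e. when the corresponding random channel shows no bias.
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    rows = []
    for cond, sub in trials.groupby("condition", sort=True):
        n = len(sub)
        row = {"condition": cond, "n": n}
        for channel, col in (("target", "target_side"), ("guess", "guess_side")):
            k_left = int((sub[col] == "left").sum())
            lo, hi = proportion_confint(k_left, n, alpha=1.0 - level, method="normal")
            row[f"p_left_{channel}"] = k_left / n
            row[f"ci_low_{channel}"] = lo
            row[f"ci_high_{channel}"] = hi
            row[f"unbiased_{channel}"] = bool(lo <= 0.5 <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_error_rates(
    scenarios: list[dict],
    reps: int = 500,
    seed: int = 0,
    design: DesignSpec = DesignSpec(),
) -> pd.DataFrame:
    """False-positive / false-negative rates of the full pipeline per scenario.

    Each scenario dict names a condition of the generator:

    * ``p_true`` – population hit rate (default 0.5),
    * ``tau`` – participant heterogeneity SD on the log-odds scale,
    * ``class_a_delta`` – side bias fed to both REG channels; the REG hit
      rate becomes 0.5 + 2*delta**2 and a class-A detection test at
      ``n_reg`` trials is simulated alongside the sequential pipeline.

    Returns one row per scenario with the fraction of Monte-Carlo runs
    reaching each sequential decision (and, where applicable, the class-A
    detection rate).
    """
    if reps < 100:
        raise ValueError("use at least 100 replicates per scenario")
    rows = []
    rng = np.random.default_rng(seed)
    for scenario in scenarios:
        name = scenario.get("name", "scenario")
        p_true = scenario.get("p_true", 0.5)
        tau = scenario.get("tau", 0.0)
        delta = scenario.get("class_a_delta", 0.0)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fractions = _power._sequential_fractions(p_true, tau, design, reps, sub_seed)
        row = {"name": name, "p_true": p_true, "tau": tau, **fractions}
        if delta:
            n_reg = int(scenario.get("n_reg", design.analysis_points[0]))
            p_reg = 0.5 + 2.0 * delta**2
            alpha = scenario.get("alpha", 0.05)
            reg_rng = np.random.default_rng(sub_seed + 1)
            k = reg_rng.binomial(n_reg, p_reg, size=reps)
            detect = _power._wald_reject(k, n_reg, alpha)
            row["class_a_detect_rate"] = float(detect.mean())
            row["class_a_analytic_power"] = analytic_power(
                PowerQuery(n=n_reg, p_true=p_reg, alpha=alpha)
            ).power
        rows.append(row)
    return pd.DataFrame(rows)
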