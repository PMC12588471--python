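"""Analytic and Monte-Carlo power for the proportion test and the sequential design.

The single-look test is the two-sided Wald z-test of H0: p = 0.5 on a pooled
proportion.  Analytic power uses the normal approximation

    power = Phi(|p - 0.5| / sqrt(p (1 - p) / n) - z_{1 - alpha/2})
          + Phi(-|p - 0.5| / sqrt(p (1 - p) / n) - z_{1 - alpha/2}),

whose second (minor-tail) term matters only near the null, where it makes the
null rejection rate equal alpha.  Monte-Carlo power draws binomial counts and
applies the same test; sequential power simulates whole studies through the
three-look, four-test stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sequential import DesignSpec, decide_counts


@dataclass(frozen=True)
class PowerQuery:
    n: int
    p_true: float
    alpha: float = 0.05
    reps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_true < 1.0:
            raise ValueError("p_true must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    method: str


def analytic_power(q: PowerQuery) -> PowerResult:
    """Normal-approximation power of the two-sided test of p = 0.5."""
    se = np.sqrt(q.p_true * (1.0 - q.p_true) / q.n)
    z_crit = stats.norm.ppf(1.0 - q.alpha / 2.0)
    z_eff = abs(q.p_true - 0.5) / se
    power = stats.norm.cdf(z_eff - z_crit) + stats.norm.cdf(-z_eff - z_crit)
    return PowerResult(power=float(power), mc_se=0.0, method="analytic")


def _wald_reject(k, n, alpha):
    p_hat = k / n
    se = np.sqrt(p_hat * (1.0 - p_hat) / n)
    z = np.where(se > 0, (p_hat - 0.5) / np.where(se > 0, se, 1.0), np.inf)
    return np.abs(z) > stats.norm.ppf(1.0 - alpha / 2.0)


def mc_power(q: PowerQuery) -> PowerResult:
    """Monte-Carlo power: binomial draws through the two-sided Wald test."""
    if q.reps < 1000:
        raise ValueError("use at least 1,000 Monte-Carlo replicates")
    rng = np.random.default_rng(q.seed)
    k = rng.binomial(q.n, q.p_true, size=q.reps)
    power = float(_wald_reject(k, q.n, q.alpha).mean())
    mc_se = float(np.sqrt(power * (1.0 - power) / q.reps))
    return PowerResult(power=power, mc_se=mc_se, method="mc")


def required_n(p_true: float, target_power: float, alpha: float = 0.05) -> int:
    """Smallest n whose analytic power reaches the target.

    Closed form: n = (z_{1-alpha/2} + z_{power})**2 * p(1-p) / (p - 0.5)**2,
    rounded up.
    """
    if p_true == 0.5:
        raise ValueError("required_n is undefined at the null rate 0.5")
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(target_power)
    n = (z_a + z_b) ** 2 * p_true * (1.0 - p_true) / (p_true - 0.5) ** 2
    return int(np.ceil(n))


def _sequential_fractions(
    p_true: float,
    heterogeneity_sd: float,
    design: DesignSpec,
    reps: int,
    seed: int,
) -> dict:
    """Fractions of simulated studies ending in each joint decision.

    Studies are simulated as cumulative pooled counts at the analysis points.
    With ``heterogeneity_sd`` > 0 the counts come from participant blocks of
    18 condition trials each with Normal log-odds intercepts; the decision at
    each look still uses the pooled rule, which is exact at tau = 0 and a
    close, slightly anticonservative approximation at the small tau values
    this paradigm exhibits.
    """
    rng = np.random.default_rng(seed)
    points = design.analysis_points
    if heterogeneity_sd == 0.0:
        increments = np.diff((0,) + tuple(points))
        k = np.zeros(reps, dtype=np.int64)
        outcome = np.zeros(reps, dtype=np.int8)
        for idx, dn in enumerate(increments, start=1):
            k = k + rng.binomial(int(dn), p_true, size=reps)
            undecided = outcome == 0
            codes = decide_counts(k[undecided], idx, design)
            outcome[np.flatnonzero(undecided)[codes > 0]] = codes[codes > 0]
    else:
        trials_per_participant = 18
        n_participants = int(np.ceil(points[-1] / trials_per_participant))
        beta0 = float(np.log(p_true / (1.0 - p_true)))
        outcome = np.zeros(reps, dtype=np.int8)
        for r in range(reps):
            u = rng.normal(0.0, heterogeneity_sd, size=n_participants)
            p_i = 1.0 / (1.0 + np.exp(-(beta0 + u)))
            k_i = rng.binomial(trials_per_participant, p_i)
            # truncate on whole participant blocks; binomially split the
            # partial block at each analysis point
            k_cum_blocks = np.cumsum(k_i)
            for idx, n_point in enumerate(points, start=1):
                if outcome[r] != 0:
                    break
                full, rem = divmod(n_point, trials_per_participant)
                k_point = int(k_cum_blocks[full - 1]) if full > 0 else 0
                if rem:
                    k_point += int(rng.binomial(rem, p_i[full]))
                code = int(decide_counts(np.array([k_point]), idx, design)[0])
                if code:
                    outcome[r] = code
    return {
        "stop_M0": float((outcome == 1).mean()),
        "stop_M1": float((outcome == 2).mean()),
        "inconclusive": float((outcome == 0).mean()),
    }


def sequential_power_tpp(
    p_true: float,
    heterogeneity_sd: float = 0.0,
    design: DesignSpec = DesignSpec(),
    reps: int = 10_000,
    seed: int = 0,
) -> PowerResult:
    """Probability that the full sequential design stops for M1."""
    if reps < 1000:
        raise ValueError("use at least 1,000 Monte-Carlo replicates")
    fractions = _sequential_fractions(p_true, heterogeneity_sd, design, reps, seed)
    power = fractions["stop_M1"]
    mc_se = float(np.sqrt(power * (1.0 - power) / reps))
    return PowerResult(power=power, mc_se=mc_se, method="sequential_mc")
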