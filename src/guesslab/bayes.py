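"""Directional Bayes factors for binomial success counts.

The test contrasts M0 (success rate exactly 0.5) against a directional M1
whose prior is a beta distribution truncated to success rates above chance,
(0.5, 1].  Three standard priors are provided:

* ``uniform``      – Beta(1, 1), flat over the admissible range;
* ``buj``          – Beta(7, 7), a knowledge-based prior calibrated so that
  90% of its above-chance mass lies below the success probability equivalent
  to a Cohen's d of 0.5 under the logistic conversion
  ``p = exp(d*pi/sqrt(3)) / (1 + exp(d*pi/sqrt(3)))``;
* ``replication``  – Beta(829, 733), the plus-one posterior of 828 successes
  in 1,560 trials from the original experiment being replicated.

All marginal likelihoods are evaluated in log space through log-beta and
regularized incomplete-beta functions; BF01 = m0/m1 is returned on the
natural scale.  BF01 > 25 is read as conclusive support for M0 and
BF01 < 1/25 as conclusive support for M1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

BF_THRESHOLD = 25.0

_NAMED_PRIORS = {
    "uniform": (1.0, 1.0),
    "buj": (7.0, 7.0),
    "replication": (829.0, 733.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """A beta prior for the success rate under M1."""

    name: str
    alpha: float
    beta: float
    directional: bool = True
    d90: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.name in _NAMED_PRIORS and _NAMED_PRIORS[self.name] != (
            self.alpha,
            self.beta,
        ):
            raise ValueError(
                f"prior named {self.name!r} must have shapes "
                f"{_NAMED_PRIORS[self.name]}"
            )

    @classmethod
    def uniform(cls) -> "PriorSpec":
        return cls("uniform", 1.0, 1.0)

    @classmethod
    def buj(cls) -> "PriorSpec":
        return cls("buj", 7.0, 7.0, d90=0.5)

    @classmethod
    def replication(cls) -> "PriorSpec":
        return cls("replication", 829.0, 733.0)

    @classmethod
    def custom(cls, alpha: float, beta: float) -> "PriorSpec":
        return cls("custom", float(alpha), float(beta))

    @classmethod
    def named(cls, name: str) -> "PriorSpec":
        if name not in _NAMED_PRIORS:
            raise ValueError(f"unknown prior name {name!r}")
        return getattr(cls, name)()


DEFAULT_PRIORS = ("uniform", "buj", "replication")


@dataclass(frozen=True)
class BayesResult:
    k: int
    n: int
    bf01: float
    m0: float
    m1: float
    log_m0: float
    log_m1: float
    support: str
    prior: PriorSpec


def d_to_probability(d: float) -> float:
    """Convert a Cohen's d effect size to a success probability.

    Uses the logistic bridge ``log-odds = d * pi / sqrt(3)`` (the standard
    logistic distribution has SD pi/sqrt(3)), then inverts the logit.
    """
    return float(special.expit(d * np.pi / np.sqrt(3.0)))


def make_replication_prior(rate: float, n: int) -> PriorSpec:
    """Beta prior from a previously observed success proportion.

    ``round(rate * n)`` successes and the complementary failures are turned
    into a Beta(successes + 1, failures + 1) plus-one-update prior.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    successes = int(round(rate * n))
    alpha, beta = successes + 1, n - successes + 1
    if (alpha, beta) == _NAMED_PRIORS["replication"]:
        return PriorSpec.replication()
    return PriorSpec("custom", float(alpha), float(beta))


def _log_binom_coeff(k, n):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def log_bf01(k, n, alpha: float, beta: float):
    """Vectorised log BF01 under a Beta(alpha, beta) prior truncated to (0.5, 1].

    m1 = C(n,k) * B(k+a, n-k+b)/B(a,b) * (1 - I_0.5(k+a, n-k+b)) / (1 - I_0.5(a, b))
    with the upper tails evaluated as I_0.5 of the swapped-parameter beta for
    numerical stability.
    """
    k = np.asarray(k, dtype=float)
    log_m0 = stats.binom.logpmf(k, n, 0.5)
    log_m1 = (
        _log_binom_coeff(k, n)
        + special.betaln(k + alpha, n - k + beta)
        - special.betaln(alpha, beta)
        + np.log(special.betainc(n - k + beta, k + alpha, 0.5))
        - np.log(special.betainc(beta, alpha, 0.5))
    )
    return log_m0 - log_m1


def bf01_one_sided(k: int, n: int, prior: PriorSpec) -> BayesResult:
    """Directional Bayes factor BF01 for k successes in n trials."""
    if n < 1:
        raise ValueError("the test is undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must lie in [0, n={n}]")
    log_m0 = float(stats.binom.logpmf(k, n, 0.5))
    lbf = float(log_bf01(k, n, prior.alpha, prior.beta))
    log_m1 = log_m0 - lbf
    bf = float(np.exp(lbf))
    return BayesResult(
        k=int(k),
        n=int(n),
        bf01=bf,
        m0=float(np.exp(log_m0)),
        m1=float(np.exp(log_m1)),
        log_m0=log_m0,
        log_m1=log_m1,
        support=classify_bf(bf),
        prior=prior,
    )


def classify_bf(bf01: float) -> str:
    """Three-way support classification with 25-fold evidence thresholds.

    Boundary values (exactly 25 or 1/25) are inconclusive: the decision rule
    requires the Bayes factor to be strictly beyond the threshold.
    """
    if not bf01 > 0:
        raise ValueError("BF01 must be positive")
    if bf01 > BF_THRESHOLD:
        return "M0"
    if bf01 < 1.0 / BF_THRESHOLD:
        return "M1"
    return "inconclusive"


def admissible_counts(percent: float, n: int, decimals: int = 2) -> list[int]:
    """All success counts whose percentage of ``n`` rounds to ``percent``.

    Printed summary tables report proportions rounded to two decimals, which
    leaves a handful of integer counts consistent with each figure; this
    helper enumerates them so analyses from printed aggregates can bound the
    rounding ambiguity.
    """
    lo = int(np.floor((percent - 0.5 * 10 ** -decimals) / 100.0 * n))
    hi = int(np.ceil((percent + 0.5 * 10 ** -decimals) / 100.0 * n))
    ks = [
        k
        for k in range(max(lo, 0), min(hi, n) + 1)
        if round(100.0 * k / n, decimals) == round(percent, decimals)
    ]
    if not ks:
        raise ValueError(f"no count of {n} rounds to {percent}%")
    return ks
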