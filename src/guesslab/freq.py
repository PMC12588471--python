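"""Random-intercept logistic regression and Wald decision rules.

The preregistered frequentist analysis fits an intercept-only mixed logistic
model to per-participant hit counts,

    k_i | u_i ~ Binomial(n_i, expit(beta0 + u_i)),   u_i ~ Normal(0, sigma**2),

by maximum likelihood with Gauss-Hermite quadrature over the random effect.
Per-participant binomial counts are the model's sufficient statistics, so the
fit never touches trial-level rows.  A Wald confidence interval around beta0
is mapped through the logistic function to the probability scale, where the
preregistered decision thresholds live: upper bound below 0.51 supports the
null model M0; failing that, lower bound above 0.5 supports M1; anything else
is inconclusive.  Repeated looks use Bonferroni-widened levels
(99.5% / 99.75% / 99.875% at the first/second/third analysis point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import expit, logit

_SIGMA_BOUNDARY = 1e-6


def _optimizer_converged(res, se_beta0: float) -> bool:
    # L-BFGS-B can report an abnormal line search once the objective stops
    # changing at machine precision; accept the fit when the Newton step
    # implied by the residual (finite-difference) gradient is negligible on
    # the standard-error scale.
    if bool(res.success):
        return True
    grad = float(np.max(np.abs(res.jac)))
    return grad * se_beta0 < 1e-4


@dataclass(frozen=True)
class ParticipantCounts:
    participant_id: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n or self.n < 1:
            raise ValueError(
                f"invalid counts k={self.k}, n={self.n} for "
                f"participant {self.participant_id!r}"
            )


@dataclass(frozen=True)
class ModelFit:
    beta0: float
    se_beta0: float
    sigma_u: float
    loglik: float
    n_quad: int
    converged: bool


@dataclass(frozen=True)
class IntervalEstimate:
    p_hat: float
    se_pct: float
    ci_low: float
    ci_high: float
    level: float
    p_value: float


def aggregate_by_participant(trials: pd.DataFrame, condition: str) -> list[ParticipantCounts]:
    """Collapse a trial table to per-participant (hits, trials) for one condition."""
    sub = trials[trials["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in trial table")
    grouped = sub.groupby("participant_id", sort=True)["hit"].agg(["sum", "count"])
    return [
        ParticipantCounts(participant_id=str(pid), k=int(row["sum"]), n=int(row["count"]))
        for pid, row in grouped.iterrows()
    ]


def _neg_loglik(params, k, n, logc, nodes, log_weights):
    beta0, sigma = params
    eta = beta0 + np.sqrt(2.0) * sigma * nodes[None, :]
    # log Binomial(k; n, expit(eta)) = logC + k*eta - n*log(1 + exp(eta))
    ll = logc[:, None] + k[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    return -float(special.logsumexp(ll + log_weights[None, :], axis=1).sum())


def fit_random_intercept_logit(
    counts: list[ParticipantCounts],
    n_quad: int = 25,
    sigma_fixed: float | None = None,
) -> ModelFit:
    """ML fit of the intercept-only binomial mixed model.

    ``sigma_fixed`` pins the random-effect SD (0 gives the pooled binomial
    model, appropriate e.g. for REG arms that have no grouping structure);
    otherwise sigma is profiled on [0, inf) and the boundary fit is reported
    when the maximum lies there.  The standard error comes from the observed
    information (finite-difference Hessian) at the maximum.
    """
    if not counts:
        raise ValueError("need at least one participant record")
    if n_quad < 5:
        raise ValueError("n_quad must be >= 5")
    k = np.array([c.k for c in counts], dtype=float)
    n = np.array([c.n for c in counts], dtype=float)
    logc = (
        special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
    )
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    pooled = k.sum() / n.sum()
    pooled = min(max(pooled, 1e-12), 1 - 1e-12)
    beta_init = float(logit(pooled))

    if sigma_fixed is not None:
        if sigma_fixed < 0:
            raise ValueError("sigma_fixed must be >= 0")
        res = optimize.minimize(
            lambda b: _neg_loglik((b[0], sigma_fixed), k, n, logc, nodes, log_weights),
            x0=[beta_init],
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        beta0, sigma = float(res.x[0]), float(sigma_fixed)
    else:
        res = optimize.minimize(
            _neg_loglik,
            x0=[beta_init, 0.1],
            args=(k, n, logc, nodes, log_weights),
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, None)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        beta0, sigma = float(res.x[0]), float(res.x[1])
        if sigma < _SIGMA_BOUNDARY:
            sigma = 0.0

    loglik = -_neg_loglik((beta0, sigma), k, n, logc, nodes, log_weights)
    se = _wald_se(beta0, sigma, k, n, logc, nodes, log_weights)
    converged = _optimizer_converged(res, se)
    return ModelFit(
        beta0=beta0,
        se_beta0=se,
        sigma_u=sigma,
        loglik=loglik,
        n_quad=n_quad,
        converged=converged,
    )


def _wald_se(beta0, sigma, k, n, logc, nodes, log_weights) -> float:
    """Observed-information SE of beta0.

    Uses the full (beta0, sigma) Hessian away from the sigma = 0 boundary and
    the one-dimensional information in beta0 on it (no sigma inference is
    attempted at the boundary).
    """
    f = lambda p: _neg_loglik(p, k, n, logc, nodes, log_weights)
    hb = 1e-5 * max(1.0, abs(beta0))
    if sigma <= _SIGMA_BOUNDARY:
        d2 = (f((beta0 + hb, sigma)) - 2 * f((beta0, sigma)) + f((beta0 - hb, sigma))) / hb**2
        return float(np.sqrt(1.0 / d2))
    hs = 1e-5 * max(1.0, sigma)
    H = np.empty((2, 2))
    f0 = f((beta0, sigma))
    H[0, 0] = (f((beta0 + hb, sigma)) - 2 * f0 + f((beta0 - hb, sigma))) / hb**2
    H[1, 1] = (f((beta0, sigma + hs)) - 2 * f0 + f((beta0, sigma - hs))) / hs**2
    H[0, 1] = H[1, 0] = (
        f((beta0 + hb, sigma + hs))
        - f((beta0 + hb, sigma - hs))
        - f((beta0 - hb, sigma + hs))
        + f((beta0 - hb, sigma - hs))
    ) / (4 * hb * hs)
    cov = np.linalg.inv(H)
    return float(np.sqrt(cov[0, 0]))


def wald_interval(fit: ModelFit, level: float) -> IntervalEstimate:
    """Probability-scale Wald CI, delta-method SE and two-sided p-value."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if not fit.converged:
        raise ValueError("model fit did not converge; no interval available")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    p_hat = float(expit(fit.beta0))
    lo = float(expit(fit.beta0 - z * fit.se_beta0))
    hi = float(expit(fit.beta0 + z * fit.se_beta0))
    se_pct = 100.0 * fit.se_beta0 * p_hat * (1.0 - p_hat)
    zstat = fit.beta0 / fit.se_beta0
    p_value = float(2.0 * stats.norm.sf(abs(zstat)))
    return IntervalEstimate(
        p_hat=p_hat, se_pct=float(se_pct), ci_low=lo, ci_high=hi,
        level=float(level), p_value=p_value,
    )


def decide_frequentist(interval: IntervalEstimate) -> str:
    """Preregistered one-sided CI decision.

    CI upper bound below 0.51 supports M0; otherwise a lower bound above 0.5
    supports M1; otherwise neither model is conclusively supported.
    """
    if interval.ci_high < 0.51:
        return "M0"
    if interval.ci_low > 0.5:
        return "M1"
    return "inconclusive"


def confirm_bidirectional(interval: IntervalEstimate) -> bool:
    """Two-sided confirmation: chance (0.5) falls outside the 95% CI.

    Endpoint containment is inclusive, so an interval exactly touching 0.5
    does not confirm.
    """
    if not np.isclose(interval.level, 0.95):
        raise ValueError("bidirectional confirmation is defined for 95% CIs")
    return not interval.ci_low <= 0.5 <= interval.ci_high


_POINT_LEVELS = {1: 0.995, 2: 0.9975, 3: 0.99875}


def ci_level_for_point(point_index: int) -> float:
    """Bonferroni-adjusted confidence level for an interim analysis point."""
    try:
        return _POINT_LEVELS[point_index]
    except KeyError:
        raise ValueError(f"analysis point index must be 1..3, got {point_index}")


def pooled_interval(k, n, level: float):
    """Vectorised probability-scale Wald CI for pooled binomial counts.

    Equivalent to the mixed-model interval with sigma fixed at 0; used by the
    sequential Monte-Carlo machinery where only totals are simulated.
    Returns (ci_low, ci_high, p_value) arrays.
    """
    k = np.asarray(k, dtype=float)
    p_hat = k / n
    beta0 = logit(p_hat)
    se = np.sqrt(1.0 / (n * p_hat * (1.0 - p_hat)))
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo = expit(beta0 - z * se)
    hi = expit(beta0 + z * se)
    p_value = 2.0 * stats.norm.sf(np.abs(beta0 / se))
    return lo, hi, p_value
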