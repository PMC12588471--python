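"""Mixed logistic model: quadrature accuracy, Wald intervals, decision rules."""

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

from guesslab import (
    ParticipantCounts,
    aggregate_by_participant,
    ci_level_for_point,
    confirm_bidirectional,
    decide_frequentist,
    fit_random_intercept_logit,
    wald_interval,
)
from guesslab.freq import IntervalEstimate, _neg_loglik, pooled_interval


def loglik_by_quadrature(counts, beta0, sigma):
    """Oracle: adaptive integration of each participant's random-effect integral."""
    total = 0.0
    for c in counts:
        def integrand(u):
            p = expit(beta0 + u)
            return stats.binom.pmf(c.k, c.n, p) * stats.norm.pdf(u, 0, sigma)

        val, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma, epsabs=0, epsrel=1e-12)
        total += np.log(val)
    return total


class TestFit:
    def test_homogeneous_data_reduce_to_pooled_binomial(self):
        # underdispersed per-participant counts: the heterogeneity MLE sits
        # on the sigma = 0 boundary and the fit degenerates to the pooled model
        counts = [
            ParticipantCounts(f"P{i}", k, 18)
            for i, k in enumerate([8, 9, 10] * 25)
        ]
        fit = fit_random_intercept_logit(counts)
        k, n = sum(c.k for c in counts), sum(c.n for c in counts)
        pooled = k / n
        assert fit.converged
        assert fit.sigma_u == 0.0
        assert fit.beta0 == pytest.approx(logit(pooled), abs=1e-6)
        binomial_se = 1.0 / np.sqrt(n * pooled * (1 - pooled))
        assert fit.se_beta0 == pytest.approx(binomial_se, rel=0.01)

    def test_sigma_fixed_zero_is_analytic_pooled_mle(self):
        counts = [ParticipantCounts("a", 40, 100), ParticipantCounts("b", 55, 100)]
        fit = fit_random_intercept_logit(counts, sigma_fixed=0.0)
        assert fit.beta0 == pytest.approx(logit(95 / 200), abs=1e-6)
        assert fit.sigma_u == 0.0

    # 50 Gauss-Hermite nodes carry the 1e-8 contract for the heterogeneity
    # magnitudes this paradigm produces; a diffuse sigma = 1 needs more nodes
    @pytest.mark.parametrize("sigma,n_nodes", [(0.05, 50), (0.3, 50), (0.5, 50), (1.0, 200)])
    def test_gh_loglik_matches_adaptive_integration(self, sigma, n_nodes):
        counts = [
            ParticipantCounts("a", 10, 18),
            ParticipantCounts("b", 7, 18),
            ParticipantCounts("c", 12, 20),
            ParticipantCounts("d", 3, 12),
            ParticipantCounts("e", 9, 18),
        ]
        beta0 = 0.1
        from scipy import special

        k = np.array([c.k for c in counts], float)
        n = np.array([c.n for c in counts], float)
        logc = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        lw = np.log(weights) - 0.5 * np.log(np.pi)
        gh = -_neg_loglik((beta0, sigma), k, n, logc, nodes, lw)
        assert gh == pytest.approx(loglik_by_quadrature(counts, beta0, sigma), rel=1e-8)

    def test_recovers_heterogeneity(self):
        rng = np.random.default_rng(4)
        tau = 0.5
        u = rng.normal(0, tau, size=300)
        counts = [
            ParticipantCounts(f"P{i}", int(rng.binomial(36, expit(ui))), 36)
            for i, ui in enumerate(u)
        ]
        fit = fit_random_intercept_logit(counts)
        assert fit.converged
        assert 0.3 < fit.sigma_u < 0.7
        assert abs(fit.beta0) < 0.15

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_random_intercept_logit([])

    def test_too_few_quadrature_nodes_rejected(self):
        with pytest.raises(ValueError):
            fit_random_intercept_logit([ParticipantCounts("a", 5, 10)], n_quad=3)


class TestAggregate:
    def test_per_participant_counts_and_conservation(self, mixed_null_table):
        counts = aggregate_by_participant(mixed_null_table, "X")
        assert len(counts) == mixed_null_table["participant_id"].nunique()
        assert all(c.n == 9 for c in counts)
        assert sum(c.k for c in counts) == int(
            mixed_null_table.loc[mixed_null_table["condition"] == "X", "hit"].sum()
        )

    def test_reg_arm_collapses_to_single_group(self, reg_null_table):
        counts = aggregate_by_participant(reg_null_table, "X")
        assert len(counts) == 1
        assert counts[0].n == int((reg_null_table["condition"] == "X").sum())

    def test_absent_condition_rejected(self, reg_null_table):
        with pytest.raises(ValueError, match="SX"):
            aggregate_by_participant(reg_null_table, "SX")


class TestWaldInterval:
    def test_symmetric_at_chance(self):
        counts = [ParticipantCounts("a", 50, 100)]
        fit = fit_random_intercept_logit(counts, sigma_fixed=0.0)
        iv = wald_interval(fit, 0.95)
        assert iv.p_hat == pytest.approx(0.5)
        assert iv.ci_low == pytest.approx(1 - iv.ci_high, abs=1e-10)

    @pytest.mark.parametrize(
        "pct,n,se_expected",
        [(49.65, 127_000, 0.14), (49.48, 37_836, 0.26)],
    )
    def test_reported_standard_errors(self, pct, n, se_expected):
        k = round(pct / 100 * n)
        fit = fit_random_intercept_logit([ParticipantCounts("all", k, n)], sigma_fixed=0.0)
        iv = wald_interval(fit, 0.95)
        assert round(iv.se_pct, 2) == se_expected

    def test_reported_p_value_study2_scale(self):
        """Pooled 49.65% of 127,000 trials gives two-sided p = 0.013."""
        k = round(0.4965 * 127_000)
        fit = fit_random_intercept_logit([ParticipantCounts("all", k, 127_000)], sigma_fixed=0.0)
        iv = wald_interval(fit, 0.95)
        assert round(iv.p_value, 3) == 0.013

    def test_delta_method_se_matches_binomial(self):
        k, n = 63_000, 127_000
        fit = fit_random_intercept_logit([ParticipantCounts("all", k, n)], sigma_fixed=0.0)
        iv = wald_interval(fit, 0.95)
        p = k / n
        assert iv.se_pct == pytest.approx(100 * np.sqrt(p * (1 - p) / n), rel=0.01)

    def test_widening_level_never_shrinks_ci(self):
        fit = fit_random_intercept_logit([ParticipantCounts("a", 45, 100)], sigma_fixed=0.0)
        widths = []
        for level in (0.8, 0.9, 0.95, 0.995, 0.99875):
            iv = wald_interval(fit, level)
            widths.append(iv.ci_high - iv.ci_low)
        assert all(a <= b for a, b in zip(widths, widths[1:]))

    def test_invalid_level_rejected(self):
        fit = fit_random_intercept_logit([ParticipantCounts("a", 45, 100)], sigma_fixed=0.0)
        with pytest.raises(ValueError):
            wald_interval(fit, 1.5)

    def test_coverage_of_95_ci_under_null(self):
        """95% CI covers 0.5 at nominal rate with mild heterogeneity."""
        rng = np.random.default_rng(10)
        reps, n_part, tau = 300, 60, 0.1
        covered = 0
        for _ in range(reps):
            u = rng.normal(0, tau, n_part)
            counts = [
                ParticipantCounts(f"P{i}", int(rng.binomial(18, expit(ui))), 18)
                for i, ui in enumerate(u)
            ]
            iv = wald_interval(fit_random_intercept_logit(counts), 0.95)
            covered += iv.ci_low <= 0.5 <= iv.ci_high
        rate = covered / reps
        mc_se = np.sqrt(0.95 * 0.05 / reps)
        assert abs(rate - 0.95) < 3 * mc_se


class TestDecisions:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.494, 0.505, "M0"),
            (0.501, 0.515, "M1"),
            (0.499, 0.512, "inconclusive"),
        ],
    )
    def test_one_sided_ci_rule(self, lo, hi, expected):
        iv = IntervalEstimate(
            p_hat=(lo + hi) / 2, se_pct=0.2, ci_low=lo, ci_high=hi,
            level=0.995, p_value=0.5,
        )
        assert decide_frequentist(iv) == expected

    def test_bidirectional_confirmation_study2_and_study3_scales(self):
        # ~49.65% of 127,000: chance excluded
        k = round(0.4965 * 127_000)
        fit = fit_random_intercept_logit([ParticipantCounts("all", k, 127_000)], sigma_fixed=0.0)
        assert confirm_bidirectional(wald_interval(fit, 0.95))
        # ~50.07% of 217,800: chance retained
        k = round(0.5007 * 217_800)
        fit = fit_random_intercept_logit([ParticipantCounts("all", k, 217_800)], sigma_fixed=0.0)
        assert not confirm_bidirectional(wald_interval(fit, 0.95))

    def test_touching_boundary_does_not_confirm(self):
        iv = IntervalEstimate(
            p_hat=0.503, se_pct=0.2, ci_low=0.5, ci_high=0.506,
            level=0.95, p_value=0.01,
        )
        assert not confirm_bidirectional(iv)

    def test_bidirectional_requires_95_level(self):
        iv = IntervalEstimate(0.5, 0.2, 0.49, 0.51, 0.995, 0.9)
        with pytest.raises(ValueError):
            confirm_bidirectional(iv)

    @pytest.mark.parametrize("idx,level", [(1, 0.995), (2, 0.9975), (3, 0.99875)])
    def test_bonferroni_levels(self, idx, level):
        assert ci_level_for_point(idx) == level

    def test_invalid_point_rejected(self):
        with pytest.raises(ValueError):
            ci_level_for_point(4)


class TestPooledInterval:
    def test_matches_model_fit_with_sigma_zero(self):
        k, n = 480, 1000
        lo, hi, p = pooled_interval(np.array([k]), n, 0.95)
        fit = fit_random_intercept_logit([ParticipantCounts("a", k, n)], sigma_fixed=0.0)
        iv = wald_interval(fit, 0.95)
        assert lo[0] == pytest.approx(iv.ci_low, rel=1e-4)
        assert hi[0] == pytest.approx(iv.ci_high, rel=1e-4)
        assert p[0] == pytest.approx(iv.p_value, rel=1e-3)
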