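# Methods

## The paradigm and what the simulator models

One session is 36 forced-choice trials. On each trial the subject guesses
left or right; the target side is then drawn independently, with
replacement, so every trial is a fair Bernoulli comparison of two binary
channels. Reward images are drawn without replacement from a 36-image pool
(18 erotic, 18 non-erotic), which labels each trial's condition. Pure
sessions contain 18 true-erotic (X) and 18 true-neutral (O) trials. Mixed
sessions interleave 18 true trials with 18 sham trials (S(X), S(O)) in which
the reward is withheld regardless of the outcome; sham-erotic and
sham-neutral labels differ only in the bookkeeping, never in what the
participant sees. REG arms replace the participant's guess with an
independent random channel, removing the tested independent variable while
keeping everything else fixed.

The simulator generates the hit process directly: only the hit indicator is
statistically identified by the analyses, so the human-arm guess side is
back-filled to be consistent with the drawn target side rather than
modelled as a behavioural choice. Condition-wise hit probabilities sit on
the log-odds scale as `logit(base_rate) + u_i + biases`, with participant
intercepts `u_i ~ N(0, τ²)`. On REG arms the hit is the agreement of two
independent coins, so a side bias δ applied to both channels yields a hit
rate of exactly 0.5 + 2δ² — the signature the class-A diagnostics look for.

Injectable systematic errors:

* **class-A** (`class_a_side_delta`): shifts P(left) of the target channel
  and the REG guess channel; emulates bias in the overall measurement
  process. Default 0.
* **class-B** (`class_b_drift`): additive log-odds drift per repeated
  session of the same participant. Default 0 (no such error was measured in
  the replication data this package models; the hook exists so the
  diagnostics can be exercised against it).
* **class-C** (`class_c_control_delta`): additive log-odds offset on the
  true-neutral control condition only, emulating an uncontrolled effect of
  the control condition.

Session-length irregularities mirror the field data: incomplete sessions
truncate uniformly between 1 and 35 trials (retained by the inclusion
rules, to prevent optional-stopping bias); overruns append 1–6
duplicate-structure trials up to the 42-trial cap. The default overrun
probability of 0.005 per session reproduces the "well under 0.05% of
trials" order of magnitude of unplanned extra trials. Image identities
carry no statistical effect; they exist so the session plan has the right
combinatorial structure (pool exhausted exactly once per session).

What the generator does *not* emulate: reaction times, image-level
psychological effects, questionnaire covariates, non-stationary participant
behaviour within a session, and the bit stream of the specific Alea PRNG
used by the original experiment software (any high-quality seeded generator
is statistically equivalent for these analyses; NumPy's PCG64 is used).
Passing tests therefore certify the statistical machinery, not the
behavioural realism of the hit sequences.

## The analysis battery

**Bayes factors.** M0 is a point null at 0.5; M1 truncates a Beta(α, β)
prior to (0.5, 1], following the directional hypothesis ("success rate
higher than 50%"). The marginal likelihood under M1 has the closed form

    m1 = C(n,k) · B(k+α, n−k+β)/B(α,β) · (1 − I₀.₅(k+α, n−k+β)) / (1 − I₀.₅(α,β))

computed in log space; upper tails are evaluated as `I₀.₅` of the
swapped-parameter beta to avoid cancellation. The 25-fold evidence
thresholds are strict inequalities; a BF of exactly 25 (or 1/25) is
classified inconclusive, matching the "higher than"/"lower than" wording of
the decision rule. Reproducing the published BF01 = 159 for the pure-session
erotic condition validates the truncated-prior reading of the directional
alternative.

**Replication prior.** Built as a plus-one update: `round(rate·n)` successes
give Beta(successes+1, failures+1) — Beta(829, 733) for 53.1% of 1,560.

**Mixed logistic model.** Intercept-only binomial GLMM on per-participant
counts, maximized by L-BFGS-B over (β₀, σ) with σ bounded at 0 and the
random-effect integral evaluated by 25-node Gauss–Hermite quadrature
(50 nodes reproduce adaptive quadrature to 1e-8 relative error for the
heterogeneity magnitudes this design produces, τ ≲ 0.5; the default 25 is
comfortably inside that regime). Initialization is deterministic at
β₀ = logit(pooled proportion), σ = 0.1. When the maximum lies on the σ = 0
boundary the boundary fit is reported and the information for β₀ is taken
one-dimensionally; no inference on σ is attempted there. REG arms carry a
single pseudo-participant id and are fitted with σ fixed at 0, i.e. the
pooled binomial model — they have no grouping structure to estimate.
Standard errors come from the finite-difference observed information; the
convergence flag accepts an "abnormal line search" exit from L-BFGS-B only
when the Newton step implied by the residual gradient is below 1e-4 of a
standard error, which is the machine-precision stall of a converged fit,
never a genuine failure.

Reported summaries follow the field's conventions: the hit percentage, the
delta-method SE in percentage points (`100·se(β₀)·p̂(1−p̂)`), and a two-sided
Wald p-value. One-sided conclusions come only from the CI decision rule.

**Sequential design.** Analysis points 37,836 / 62,388 / 86,958 with
Bonferroni CI levels 99.5% / 99.75% / 99.875%; "conclusive support" means
the frequentist CI rule decides M0 or M1 *and* all three Bayes factors are
beyond their threshold; any inconclusive member forces continuation. The
sequential evaluator applies to one condition at a time (the erotic
condition under analysis); truncation at each look keeps the first N
condition-trials in arrival order and is idempotent.

## Power machinery and problem sizes

Single-look power uses the two-sided Wald z-test on the pooled proportion —
equivalent to the mixed-model test when heterogeneity is negligible — with
the minor-tail term retained so the null case returns exactly α. Sequential
power simulates whole studies as cumulative binomial counts at the three
looks (10,000 replicates by default); with τ > 0 it draws participant
blocks of 18 trials with normal log-odds intercepts and still applies the
pooled decision rule, a close and slightly anticonservative approximation
at the small τ this paradigm exhibits. Monte-Carlo power runs use 100,000
replicates where a percentage is compared against a design threshold and
20,000–40,000 in unit tests; null-calibration checks use 2,000–10,000
replicates, sized so that three Monte-Carlo standard errors resolve the
quantity under test.

A note on the design-power figure: under the faithful reading of the
four-test all-agree rule above, the probability of a correct M1 stop at a
51% population rate with τ = 0 computes to ≈ 97%, a little above the 95%
figure quoted for the original protocol design, which derived from that
team's own participant-level simulation code (not re-derivable from the
published description and out of scope here). The package reports what its
own rule produces; at look 1 the binding member of the battery is the
uniform-prior Bayes factor, whose 1/25 threshold sits almost exactly on the
observed-rate contour of 51% at N = 37,836.

## Numerical and design choices

* Mixed-session composition of the 18 true trials is fixed at 9 X + 9 O
  (and 9 S(X) + 9 S(O)), the symmetric split consistent with the published
  session illustrations; the split is not otherwise documented.
* Printed proportions are rounded to two decimals, so analyses driven by
  published aggregates enumerate every integer count consistent with the
  figure (`admissible_counts`) instead of guessing one; the acceptance
  script uses the count closest to `percent·n/100` and the neighbouring
  counts move the Bayes factors by well under 1%.
* Class-C offsets apply to the true-neutral condition (O) only: a sham
  trial has no moderator whose uncontrolled performance could express it.
* Boundary conventions: CI exactly touching 0.5 does not confirm a
  two-sided deviation; BF exactly at threshold is inconclusive; the σ̂ = 0
  boundary is reported as such.
* Trial tables round-trip through CSV with a fixed column order and strict
  enum validation; identical seeds give byte-identical files.

## Known limitations

* The GLMM quadrature contract degrades for τ ≳ 1 at the default node
  count; such heterogeneity is far outside the observed regime but would
  need more nodes.
* Sequential Monte-Carlo power under heterogeneity uses the pooled decision
  rule rather than refitting the GLMM at every simulated look; the
  approximation error is second-order in τ.
* Printed mixed-model p-values from the original studies depend on
  participant-level raw data that the published record does not contain;
  they are covered by calibration properties, not reproduced digit-for-digit.
* REG-arm analyses assume exchangeable trials; serial structure in a real
  hardware REG would need its own diagnostics.
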