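# guesslab

Simulation and analysis machinery for **forced-choice guessing experiments**
of the kind used in precognition replication research: a participant (or, in
counterfactual control arms, a random event generator) guesses which side of
a screen hides a reward image, the target side is then drawn at random, and
the scientific question is whether the hit rate deviates from 50%.

The package is aimed at methodologists who want to study, calibrate or
stress-test this class of weak-effect designs: it pairs a trial-level
simulator of the paradigm (36-trial sessions, erotic/neutral reward images,
sham trials that withhold the reward, REG-substituted arms, participant
heterogeneity, injectable systematic biases) with the full preregistered
analysis battery used by the consensus-designed transparent-psi replication
protocol.

## The statistics

**Directional Bayes factor.** For `k` hits in `n` trials the null model M0
fixes the success rate at 0.5 while M1 places a beta prior truncated to
(0.5, 1] on it:

    BF01 = Binom(k; n, 1/2) / [ ∫₀.₅¹ Binom(k; n, p) Beta(p; α, β) dp / (1 − I₀.₅(α, β)) ]

evaluated in closed form through log-beta and regularized incomplete-beta
functions. Three priors are built in: uniform Beta(1,1); the knowledge-based
"BUJ" Beta(7,7), calibrated so that 90% of its above-chance mass lies below
the success probability equivalent to Cohen's d = 0.5 under
`p = exp(dπ/√3) / (1 + exp(dπ/√3))`; and the replication prior Beta(829,733)
built from 828 successes in 1,560 trials of the original experiment.
BF01 > 25 supports M0, BF01 < 1/25 supports M1.

**Mixed logistic model.** Hits are modelled as
`k_i | u_i ~ Binom(n_i, expit(β₀ + u_i))` with participant intercepts
`u_i ~ N(0, σ²)`, fitted by maximum likelihood with Gauss–Hermite
quadrature. The Wald CI around β₀ is mapped to the probability scale where
the preregistered rules live: CI upper bound < 0.51 ⇒ M0; CI lower bound
> 0.5 ⇒ M1; otherwise inconclusive. A two-sided variant confirms a
deviation when 0.5 falls outside the 95% CI.

**Sequential design.** The battery (the CI rule plus the three Bayes
factors) runs at up to three analysis points — 37,836 / 62,388 / 86,958
trials — with Bonferroni-adjusted CI levels 99.5% / 99.75% / 99.875%; the
study stops the first time all four tests agree.

**Counterfactual diagnostics.** REG arms remove the participant from the
process entirely; any deviation from chance there is evidence of *class-A*
error (bias in the measurement pipeline itself). The simulator can inject
such biases and the diagnostics module measures the pipeline's
false-positive and false-negative rates against them.

## Worked example

```python
from guesslab import PriorSpec, bf01_one_sided, admissible_counts

n = 37_836                      # trials in the first study's erotic condition
for k in admissible_counts(49.48, n):   # counts printed as "49.48%"
    res = bf01_one_sided(k, n, PriorSpec.buj())
    print(k, round(res.bf01, 1), res.support)
```

prints

```
18720 159.5 M0
18721 158.9 M0
18722 158.3 M0
18723 157.7 M0
```

i.e. a hit rate of 49.48% in 37,836 trials is about 159 times more likely
under the chance model than under the directional above-chance alternative —
conclusive support for M0. The same machinery from the shell:

```sh
guesslab bayes --k 18721 --n 37836 --prior buj
guesslab simulate --seed 1 --config config.yaml --out trials.csv
guesslab analyze trials.csv --condition X --json
guesslab power --n 127000 --p-true 0.4948
```

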