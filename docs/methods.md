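# Methods

## Model

A UQM condition observes `yes ~ Binomial(n, λ)` with marginal "yes"
probability

    λ(π_s) = p·π_s + (1 − p)·π_n,

where `p` is the probability of being routed to the sensitive question
and `π_n` the known "yes" probability of the neutral question. Both
are treated as fixed by design (not estimated). All analyses condition
on honest responding; deviations from honesty are a *simulation*
feature (see below), not part of the estimators.

### Design constants

The birthday randomizer is modelled on an average 365.25-day year
(February = 28.25 days, i.e. one leap day per four years). Day-range
probabilities are exact `fractions.Fraction`s with denominator 1461/4:

| quantity | value | decimal |
|---|---|---|
| p (one-third variant, day 21–31) | 125.25/365.25 | 0.342916 |
| p (two-thirds variant, day 11–31) | 245.25/365.25 | 0.671458 |
| π_n (birthday before 1 July) | 181.25/365.25 | 0.496235 |

Designs keep the rational form internally; floats appear only at
computation boundaries, so serialization round-trips are lossless.
Arbitrary `(p, π_n)` pairs are accepted for other randomizers.

## Estimation

`π̂_s = (a − (1−p)·π_n)/p` with `Var = a(1−a)/(n p²)` and a Wald
interval at z = 1.959964. The point estimate is **not truncated** to
[0, 1]: truncation would bias means over replicated surveys, and the
raw moment estimator is what the interval theory describes. A
`pi_hat_truncated` property provides a displayable value. Reported
percentages round half-away-from-zero to one decimal.

Two recomputed cells differ from the original report in the last
digit, both rounding-boundary artifacts rather than substantive
disagreements:

* cognitive doping, p≈2/3: the exact CI upper bound is 0.2344971,
  which rounds to 23.4 (printed: 23.5); the value sits ~4·10⁻⁶ below
  the 0.2345 boundary, so any intermediate rounding flips the digit;
* pooled physical CI upper bound 0.192759 → 19.3 (printed: 19.2).

Similarly the physical-doping likelihood-ratio statistic computes to
2.2441 → 2.24 at two decimals (printed: 2.25).

## Inference

Under H1 each condition has its own prevalence; the per-condition
likelihood is maximized at λ = a, i.e. at the closed-form estimate,
clipped to the [0, 1] boundary when the implied prevalence is outside
(this keeps χ² ≥ 0; the study's data are interior). Under H0 one
shared prevalence is fitted by a 1000-point grid pre-scan plus bounded
scalar minimization (xatol 10⁻¹⁰). The standard error of the pooled
estimate uses the analytic observed Fisher information

    I(π_s) = Σ_i p_i² · ( yes_i/λ_i² + no_i/(1−λ_i)² ).

`χ² = 2(ℓ₁ − ℓ₀)` is referred to chi-square with df = 1. The pooled
estimate is the MLE; an inverse-variance-weighted average is provided
as a cross-check utility (they agree to the printed decimal on the
study data).

## Bayes factors

H0 (equal prevalences) is nested in H1 (independent prevalences with
independent uniform priors), so the Savage–Dickey ratio applies: BF01
equals the posterior density of δ = π₁ − π₂ at 0 divided by its prior
density at 0. The prior of δ is triangular, exactly 1 at zero; the
posterior density at zero reduces to ∫ q₁(t)·q₂(t) dt with q_i the
normalized per-condition posteriors.

* **Quadrature route (primary)**: per-condition posteriors on a
  uniform grid (default 4001 points), trapezoid normalization; the δ
  posterior (for summaries) by discrete convolution. Deterministic;
  doubling the grid changes BF01 by < 0.1%.
* **MCMC + KDE route (validation)**: random-walk Metropolis on the two
  independent posteriors (4 chains × 50,000 draws after 2,000 burn-in,
  proposal scale 2.4× the closed-form SE), split-chain R̂ < 1.01
  required, Gaussian KDE at δ = 0 with Silverman's bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5). Agrees with quadrature within 5%
  at 200,000 draws.

With uniform priors the study counts give BF01 ≈ 2.04 (physical) and
≈ 4.82 (cognitive), versus 2.3 and 5.3 in the original report. The
original analysis did not state its priors, sampler settings or KDE
bandwidth, and the Bayes factor is sensitive to all three; the
package's values are reported as computed rather than tuned to match.
A Beta(a, b) prior option exposes the sensitivity (the prior density
of δ at 0 is then ∫ Beta(t;a,b)² dt, computed by quadrature).

Evidence labels for BF01 ≥ 1 follow the conventional grades weak
(1–3), positive (3–20), strong (20–150), very strong (> 150);
reciprocal grading below 1.

## Power

Wald test of H0: π_s = 0 with the variance evaluated at the null
(λ₀ = (1−p)π_n) for the critical value and at the alternative for the
power:

    power = Φ( (π_s − z_{1−α}·SE₀) / SE₁ ),   SE_k² = λ_k(1−λ_k)/(n p²).

The default is **one-sided** α = 0.05: that convention reproduces the
study's planning values (power 0.815 ≈ 0.8 at n = 550 under p≈1/3;
0.922 ≈ 0.9 at n = 150 under p≈2/3), whereas two-sided gives 0.72 and
0.88. Sidedness is always explicit in results. `required_sample_size`
returns the smallest n reaching the target (136 for power 0.90 under
p≈2/3 — the study's planned 150 was a round planning figure, not a
minimum).

The two-design difference test uses the two-sample Wald statistic with
per-condition variances at the assumed prevalences, plus a Monte-Carlo
mode that simulates both conditions and applies the LR test. The
original report also quotes difference powers of 0.33/0.78/0.98 at
n = 600 per condition for assumed prevalences 0.20/0.25/0.30 under
p≈1/3 against 0.15 under p≈2/3; the statistic, sidedness and variance
convention behind those figures are not stated, and no standard Wald
variant reproduces them. With each arm's own design variance this
package computes 0.122/0.342/0.640 (two-sided) or 0.194/0.463/0.749
(one-sided), agreeing with its own Monte-Carlo LR mode within 0.02;
the closest variant found uses the p≈2/3 variance for *both* arms
(0.254/0.723/0.966 two-sided, 0.363/0.818/0.984 one-sided), which
brackets the quoted figures. They are treated as descriptive context,
reported as computed rather than matched.

## Survey simulator

The generator emulates the study: 1,206 respondents by default, eight
counterbalanced questionnaire versions at the observed version
frequencies, true prevalences at the study's pooled estimates (0.144
physical, 0.188 cognitive), honest responding, and the observed
nonresponse rates (2.7% answer neither question, 0.7% only the first).
Birthdays are uniform over a 1461-day four-year cycle, so branch
probabilities equal the design fractions exactly in expectation. Each
question draws its own birthday (`share_birthday=True` reuses one);
demographics (gender, age, semester, field of study) are decorative
draws matching the study's margins and play no role in estimation.

Cheating is one-sided self-protective lying: a carrier routed to the
sensitive question answers "no" with a per-design probability. This
operationalizes the hypothesis that a larger p (higher disclosure
risk) induces more cheating; a directional test confirms the machinery
(higher cheating under p≈2/3 lowers that condition's estimate).

**Calendar dependence (a deliberate design choice).** In the printed
questionnaire one birthday determines both the branch (day-of-month)
and the neutral answer (month). Because every month has at least 20
days, conditional on the neutral branch (day 1–10 or 1–20) the
probability of "first half of the year" is exactly 1/2 — not the
marginal 181.25/365.25 used as π_n by the estimator. Wiring both
through one birthday therefore inflates recovered prevalences by
(1−p)/p · (1/2 − 181.25/365.25), i.e. +0.0072 at p≈1/3 and +0.0018 at
p≈2/3. The generator's default draws the neutral answer from an
independent uniform birthday, which makes the conditional neutral-yes
probability exactly the design constant and keeps the pipeline
estimator-consistent; `neutral_same_birthday=True` reproduces the
literal single-birthday questionnaire so the bias can be quantified
(a test asserts its size and direction). Real surveys add further
features the generator does not model: respondent-chosen birthdays are
not uniform, refusal may correlate with the sensitive attribute, and
lying need not be one-sided — so passing recovery tests validates the
statistical pipeline, not the behavioral assumptions.

## Numerical conventions and problem sizes

* Shared-prevalence optimization: grid pre-scan (1000 points) then
  bounded Brent, xatol 10⁻¹⁰; agreement with a 10⁶-point grid search
  to 10⁻⁶ is tested.
* Calibration tests use 2,000 replicated surveys of n = 600 for
  estimator bias/coverage and LR type-I error, 500 replicates of
  n = 20,000 respondents for full-pipeline parameter recovery, and
  10⁶ respondents for branch-probability checks — sizes chosen so
  Monte-Carlo error is well below the tolerances being asserted.
* KDE requires ≥ 1,000 draws; MCMC requires ≥ 1,000 samples per chain
  and flags (rather than raises on) non-convergence.
* Degenerate inputs: empty counts raise; λ ∈ {0,1} against a
  contradicting count yields −∞ log-likelihood; `disclosure_risk`
  returns 0 when prior and denominator both vanish.

## Known limitations

* Wald intervals only (no exact/Clopper–Pearson variants); intervals
  may extend outside [0, 1] for extreme counts.
* π_n is treated as known; uncertainty in the neutral question's
  "yes" rate is not propagated.
* Tests across more than two designs (df > 1) and covariate-adjusted
  analyses are out of scope.
* The Bayes-factor comparison to the originally reported 2.3/5.3 is
  necessarily loose because the original priors are unknown.
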