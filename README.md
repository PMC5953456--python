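# uqm — unrelated-question-model survey analysis

Tools for planning, simulating and analysing randomized-response
surveys that use the **unrelated question model (UQM)**. The package
was built around a two-arm survey of university students that measured
the 12-month prevalence of physical doping and cognitive doping
("brain doping") under two randomization probabilities, and it
reproduces that study's full statistical pipeline from its aggregated
counts.

## The model

In a UQM question, a private chance mechanism routes each respondent
either to the sensitive question (probability *p*) or to an unrelated
neutral question whose population "yes" probability *π<sub>n</sub>* is
known. Here the randomizer is the day-of-month of a self-chosen
birthday, and the neutral question asks whether that birthday falls
before 1 July. Over an average 365.25-day year the design constants
are exact fractions:

* *p* = 125.25/365.25 ≈ 1/3 (birthday on day 21–31) or
  *p* = 245.25/365.25 ≈ 2/3 (day 11–31),
* *π<sub>n</sub>* = 181.25/365.25 ≈ 1/2.

Only the respondent knows which question they answered, but the
overall "yes" proportion *a* identifies the sensitive prevalence:

    π̂_s = (a − (1 − p)·π_n) / p,      Var(π̂_s) = a(1 − a) / (n p²).

On top of this estimator the package provides

* **design**: exact birthday-fraction arithmetic and the disclosure
  risk P(carrier | "yes"), which grows with *p*;
* **inference**: binomial likelihoods in π<sub>s</sub>, a pooled
  maximum-likelihood estimate across designs, and the df = 1
  likelihood-ratio test of equal prevalence under two designs;
* **bayes**: Savage–Dickey Bayes factors for equality of the two
  prevalences (deterministic quadrature, plus an MCMC + kernel-density
  route), with uniform priors by default;
* **power**: Wald power and sample-size planning for detecting a
  nonzero prevalence or a between-design difference;
* **synthetic_data**: a respondent-level simulator of the whole
  questionnaire (eight counterbalanced versions, birthday branching,
  cheating, item nonresponse);
* **io / cli**: delimited-text readers/writers, JSON/markdown/TSV
  reports, and a `uqm` command line.

## Worked example

The published counts as a tab-separated file (`counts.tsv`):

```
item	design_label	yes	no
physical	one_third	233	345
physical	two_thirds	147	444
cognitive	one_third	238	352
cognitive	two_thirds	164	414
```

```sh
$ uqm estimate counts.tsv --format tsv
item	design_label	yes	no	a	pi_hat_pct	se_pct	ci_pct
physical	p≈1/3	233	345	0.403	22.5	5.9	10.8-34.1
physical	p≈2/3	147	444	0.249	12.8	2.6	7.6-18.0
cognitive	p≈1/3	238	352	0.403	22.5	5.9	11.0-34.1
cognitive	p≈2/3	164	414	0.284	18.0	2.8	12.5-23.4
```

Each row is one survey condition: `a` is the raw "yes" proportion and
`pi_hat_pct` the implied prevalence of the sensitive behavior with its
standard error and 95% Wald interval, all in percent. Physical doping
reads 22.5% under p≈1/3 but 12.8% under p≈2/3 — is that a real
difference or sampling noise? Compare the two conditions:

```sh
$ uqm compare counts.tsv --item physical
{
  "item": "physical",
  "chi2": 2.24,
  "df": 1,
  "p_value": 0.134,
  "pi_shared_pct": 14.4,
  "se_pct": 2.5,
  "bf01": 2.04,
  "evidence_label": "weak"
}
```

The likelihood-ratio test does not reject equality (χ² = 2.24,
p = 0.134), the pooled maximum-likelihood prevalence is 14.4%, and the
Savage–Dickey Bayes factor BF01 = 2.04 leans (weakly) toward equal
prevalences. For cognitive doping the same pipeline gives χ² = 0.49,
p = 0.482, pooled 18.8%, BF01 = 4.82 ("positive" support for
equality).

Planning a new survey:

```sh
$ uqm power --n 550 --n 150 --pi 0.15
design_label	n	pi_s	alpha	sided	power
p≈1/3	550	0.15	0.05	one	0.815
p≈1/3	150	0.15	0.05	one	0.386
p≈2/3	550	0.15	0.05	one	1.0
p≈2/3	150	0.15	0.05	one	0.922
```

i.e. detecting a 15% prevalence against π<sub>s</sub> = 0 takes about
550 respondents under p≈1/3 but only 150 under p≈2/3 — the price of
the stronger privacy protection of a small *p*.

Simulated respondent-level data with the same questionnaire mechanics:

```sh
uqm simulate --seed 7 --n 1206 --out respondents.tsv
uqm estimate respondents.tsv --respondents
```

or in Python, `uqm.fixture_study()` for a canned seed-fixed survey.

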