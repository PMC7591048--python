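# Methods

`econstress` implements two survey analyses and the synthetic data-generating
process (DGP) used to test them end to end.

## 1. The list experiment

Respondents are randomized into four arms: a control arm sees four
uncontroversial statements and reports *how many* they agree with; treatment
arms T1 and T2 see the same four plus one of two sensitive statements about
the economic cost of the COVID-19 lockdown; a smaller direct arm is asked
*which* of all six statements they agree with. Because adding a sensitive
statement raises a respondent's count by exactly one when they agree with it,

    support = E[count | treatment] − E[count | control]

identifies the population agreement share without any individual revealing
their answer. Two estimators are provided:

* **Difference in means**, with Welch (unequal-variance) standard errors.
  The paper behind the design does not state its variance estimator; Welch is
  the conservative default for two independent arms of different sizes.
* **OLS regression** of the item count on a treatment indicator plus
  covariates (female, age, marital status, unemployment, household size,
  children of school age, income, education, homeownership, living area, and
  country dummies for pooled fits), with HC1 robust standard errors. With an
  empty covariate set this reproduces the difference in means exactly (tested
  to 1e-10). Covariate adjustment is a precision refinement, not an
  identification requirement, because arms are randomized. Missing covariates
  are handled by listwise deletion with logged counts.

**Social-desirability bias (SDB)** is the list-experiment support minus the
direct-arm agreement share. The two subsamples are disjoint, so
`se = sqrt(se_list² + se_direct²)`.

**Design-effect diagnostic.** The identifying assumption is that the presence
of the sensitive item does not change answers to the control items. With
J = 4 control items and empirical count CDFs G (control) and H (treatment),
the proportion of respondents with control subtotal y who agree (z = 1) or do
not agree (z = 0) with the sensitive item is

    π(y, 1) = G(y) − H(y),        π(y, 0) = H(y) − G(y − 1).

Under no design effect all proportions are non-negative. The two boundary
types π(J, 1) = 1 − H(J) and π(0, 0) = H(0) are non-negative by construction,
leaving 2(J+1) − 2 = 8 testable proportions; each gets a one-sided normal
test (independent-sample binomial variances for G and H) and the family is
combined by Bonferroni at α = 0.05. This is deliberately conservative: the
calibration test requires a null rejection rate ≤ 6 % at nominal 5 %, and
simulation shows power above 50 % against a 0.3 drop in control-item
prevalence at n = 10,000. Arms smaller than 30 flag the result as low-power.

**Balance.** Each covariate gets a one-way ANOVA F test (numeric) or a
chi-square independence test (categorical) across the four arms; constant
covariates are skipped with a note.

## 2. Mental-health index

The instrument is an eight-item adaptation of DASS-21/SASRQ: symptom
frequency over the previous week on a 1–4 scale. The index is the item mean
divided by 4, so it lives on [0.25, 1] with 0.25 = no symptom even one day
and 1 = every symptom most or all of the time. Respondents missing at most
two items get a prorated mean; fewer than six answered items excludes the
respondent (logged). Reliability is Cronbach's alpha on complete cases;
per-item prevalence is the share with response ≥ 2 ("at least one or two
days"); association with the nine economic predictors uses Spearman rank
correlation (average ranks for ties, t-approximation p-values) to be robust
to monotone non-linearity and outlying responses.

## 3. Risk model and population projection

A random-forest regression (scikit-learn, 550 trees, bootstrap samples of
size n, one third of the predictors per split, unlimited depth) maps nine
economic-vulnerability predictors — income category, unemployment,
homeownership, living area, household size, children of school age, financial
buffer stock, negative events in the previous week, income loss — onto the
index. 550 trees is the production setting; the out-of-bag (OOB) error curve
is recorded (by reconstructing each tree's bootstrap membership, verified
against scikit-learn's own OOB predictions) so convergence can be inspected.
Predictions are clipped to the outcome range [0.25, 1].

High risk is `predicted index ≥ 0.5` (inclusive threshold). Classification
uses in-sample predictions, guarded by a holdout-stability diagnostic: models
trained on 15/25/33/50 % learning samples predict the held-out remainder and
are rank-correlated with the full-sample model's predictions.

**Post-stratification.** Weights calibrate the sample to external
gender × age-band (18–35 / 36–55 / 56–75) × macro-region population margins
(4 macro-regions for Italy, 5 each for Spain and the UK). Within a country,
`w = population cell share / sample cell share`, normalized to mean 1; the
weighted cell shares then reproduce the population shares exactly (identity
tested to 1e-10). Population cells with no sampled respondent collapse the
region dimension before erroring. The pooled high-risk share weights the
country shares by their population totals; normalizing weights within country
first is our reading of "weighting for the population" (the alternative — one
pooled weighting — differs only through cross-country weight scale and is not
what the per-country-then-pool presentation implies).

## 4. Exposure PCA

Three exposure dimensions are summarized: susceptibility (age, five
comorbidity flags, self-rated poor health), vulnerability (five
quarantine-compliance ordinals) and behavioural response (four care-seeking
flags). Items are standardized and the correlation matrix eigendecomposed;
components with eigenvalue > 1 are retained (Kaiser rule; a first eigenvalue
≤ 1 triggers a warning and a flag but still yields a score). The first
eigenvector is oriented so a designated anchor item (poor health, work
obligations, sought test) loads positively — "increasing in exposure" — and
the score is min-max rescaled onto [0.25, 1]. Rescaling is a sample min-max
map because no other mapping is canonical; it preserves ranks, which is all
the downstream CDF comparison uses. Ordinal and binary items are treated as
numeric (polychoric correlations are out of scope). Sampling adequacy is the
Kaiser–Meyer–Olkin statistic computed from the inverse correlation matrix;
note that for mutually independent items KMO tends to 0.5, not 0 (raw and
anti-image partial correlations vanish at the same rate), and that KMO is
undefined (reported NaN) for a singular correlation matrix.

## 5. Stochastic dominance

All four indices share the [0.25, 1] scale, so their empirical CDFs are
directly comparable. Index A first-order stochastically dominates B when
F_A(x) ≤ F_B(x) everywhere. Both CDFs are step functions, so the supremum of
F_A − F_B is attained on the union of the two samples' points, which is the
exact evaluation grid (equivalence with a dense-grid brute force is tested).
A tolerance ε = 0.01 lets near-coincident CDFs count as weak dominance, with
the actual maximum excess always reported. The check is descriptive; no
inferential dominance test is applied.

## 6. The synthetic DGP — what it emulates and what it does not

The generator reproduces the *design* of the study: three countries with
n = 3,504 / 3,524 / 3,523, exact 30/30/30/10 arm allocation (largest-remainder
apportionment, then permuted), four control items, the direct arm answering
all six statements, and gender/age/region demographics over the study's
post-stratification cells (uniform by default).

Substantively it encodes one latent economic-vulnerability factor
V ~ N(0, 1) per respondent:

* covariates are monotone in V through documented link functions (e.g.
  income and buffer stock are discretized linear functions of −V; stress
  events are Binomial(8, logistic(−1.3 + 0.7 V)); income loss is
  Bernoulli(logistic(−0.4 + 0.7 V)));
* the mental-health latent is M = βV + ε with β = 1 and ε ~ N(0, 1); each
  Likert item discretizes M plus independent N(0, 1) item noise at fixed
  thresholds placed at the 25/50/75 percentiles of the item-latent marginal.
  The item noise is what makes the eight items distinct, parallel measures of
  M — without it they would be copies and alpha would be exactly 1;
* sensitive-statement agreement is Bernoulli(logistic(logit(p_k) + γV)) with
  defaults p = (0.62, 0.70), γ = 0; under direct questioning an agreeing
  respondent denies agreement with probability λ (defaults 0.09, 0.05), so
  the expected SDB is λ·p;
* control items are independent Bernoullis with prevalences
  {0.35, 0.45, 0.9, 0.55} — two polarized opinions, one high-consensus health
  item — and an optional design-effect injection lowers their prevalence in
  the treatment arms by a configurable shift (used for power tests only);
* each exposure block has its own one-factor structure (health frailty,
  compliance obstacles, care seeking) so the PCA has a dominant first
  component, as in the study's data.

What it does *not* emulate: the real covariate joint distribution, real
prevalence levels (the quartile thresholds make each item uniform on {1..4},
so prevalences sit near 75 % and the high-risk share near 70 % rather than
the study's levels), panel recruitment, non-response, or any dependence
between exposure blocks and economic vulnerability. Passing tests therefore
certify the *estimators and identities* — unbiasedness, coverage, test
calibration, calibration-to-margins, dominance logic — not that the synthetic
population matches the surveyed one.

## Numerical choices and degenerate inputs

* Deterministic given the seed: one `numpy` Generator drives the whole
  dataset; the forest uses `random_state = seed` and a single thread. A
  byte-identity test runs the full pipeline twice.
* Problem sizes in the test suite: full study scale (n = 10,551, 550 trees)
  for the determinism and completeness checks; 100–200 replicates at study
  scale for coverage and test-calibration; smaller n and tree counts for
  unit-level properties where the property does not depend on scale.
* Degenerate inputs raise typed errors: empty arms name the arm and scope;
  rank-deficient regression designs name the collinear columns (pivoted QR);
  zero-variance alpha, singular KMO matrices, empty ECDF samples and
  unmatched post-stratification cells all raise with actionable messages.
* Ties in Spearman correlations use average ranks; the high-risk threshold is
  inclusive (≥ 0.5); Bonferroni p-values are capped at 1.

## Known limitations

* No causal interpretation: the risk model is a conditional-prediction
  exercise by construction.
* No uncertainty intervals for the projected high-risk share, and no
  maximum-likelihood list-experiment estimators; the "no liars" assumption is
  untestable and only the design-effect diagnostic is implemented.
* Exposure PCA on binary/ordinal items uses Pearson correlations of numeric
  codes; polychoric PCA and factor rotation are out of scope.
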