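# econstress

Tools for two linked survey analyses of the economic side effects of COVID-19
lockdowns, for survey methodologists and epidemiologists working with
multi-country online-panel microdata:

1. **List-experiment elicitation.** How much do citizens agree that
   governments should also avert an economic crisis and explain the way out of
   lockdown — once social-desirability bias (SDB) is controlled? Respondents
   randomized into a treatment arm report only *how many* of 4+1 statements
   they agree with, so support for the sensitive statement is identified as a
   mean difference against a 4-statement control arm,
   `support = E[count | T] − E[count | C]`, and SDB as the gap to a
   direct-questioning arm. Design-effect diagnostics (respondent-type
   proportions `π(y, z)` from the two count CDFs) and covariate balance tests
   guard the identifying assumptions.
2. **Mental-health risk projection.** An eight-item stress/anxiety/depression
   scale (adapted DASS-21/SASRQ, 1–4 responses) is averaged into an index on
   [0.25, 1]; a 550-tree random-forest regression predicts the index from
   nine economic-vulnerability covariates; respondents with predicted index
   ≥ 0.5 are classified high-risk; post-stratification on
   gender × age band × macro-region projects the high-risk share to the
   population. PCA scores for COVID-exposure (susceptibility, vulnerability,
   behavioural response, each min-max rescaled to [0.25, 1]) are compared
   with predicted stress through empirical CDFs and first-order stochastic
   dominance: stress FOSD-dominates exposure j when
   `P(stress ≤ x) ≤ P(j ≤ x)` for all x.

A fully documented synthetic-survey generator (`econstress.simulate`)
reproduces the design — three countries (n = 3,504 / 3,524 / 3,523), a
30/30/30/10 arm split, a latent-vulnerability factor linking economics to
mental health, and a configurable lying mechanism — so every stage is
testable without the study's microdata. See `docs/methods.md` for the models
and `docs/data_dictionary.md` for the columns.

## Worked example

```bash
$ econstress simulate --out data/ --seed 1
$ econstress list-exp --data data/survey_pooled.csv --what sdb
statement 1 [pooled]: list 0.6174, direct 0.5464, SDB 0.0710 (se 0.0286)
```

The list experiment estimates 61.7 % support for "also avoid a major economic
crisis" (covariate-adjusted regression), but only 54.6 % admit it when asked
directly: a 7.1-point social-desirability gap. (The generator's defaults are
62 % true support with a 9 % lying rate, so the expected gap is
0.09 × 0.62 ≈ 5.6 points; the estimate is well within sampling error.)

```bash
$ econstress mhealth --data data/survey_pooled.csv --what alpha
0.9214
$ econstress risk --data data/survey_pooled.csv --margins data/margins.csv --seed 1
{ "IT": 0.7048, "ES": 0.7195, "UK": 0.7105, "pooled": 0.711 }
$ econstress exposure --data data/survey_pooled.csv
susceptibility: KMO 0.758, eigenvalue1 2.077 (29.7% variance), 1 component(s) retained
vulnerability: KMO 0.821, eigenvalue1 2.521 (50.4% variance), 1 component(s) retained
behaviour: KMO 0.653, eigenvalue1 1.568 (39.2% variance), 1 component(s) retained
```

The scale is highly reliable (Cronbach's α = 0.92); roughly 71 % of the
synthetic population is projected to be at high mental-health risk after
post-stratification (the synthetic item thresholds sit at latent quartiles,
which places the index higher than real survey responses would — see
`docs/methods.md`); and each exposure block is adequately summarized by one
principal component (KMO ≥ 0.65, single eigenvalue > 1).

Python API equivalents live in `econstress.listexp`, `econstress.mhealth`,
`econstress.riskmodel`, `econstress.exposure`, `econstress.dominance`, and
`econstress.pipeline.run_pipeline` runs everything at once.

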