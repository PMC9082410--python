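# healthineq

Socioeconomic inequality in health education, measured and decomposed.

During an epidemic, how much of the population's health-education
attainment is concentrated among the well-off?  This package implements
the standard health-economics toolkit for that question on household
survey microdata — a 0–32 four-item health-education score as the
outcome, a PCA composite of five household-consumption dimensions as the
socioeconomic ranking variable — together with a calibrated synthetic
survey generator, because the motivating study's microdata are not
publicly deposited.  It is aimed at epidemiologists and health economists
who want a tested, seeded, end-to-end pipeline rather than a pile of
one-off scripts.

## What it computes

**Concentration index.**  With fractional (weighted midpoint) ranks
$R_i \in (0,1)$ in the consumption distribution and outcome mean $\mu$,

$$CI = \frac{2}{\mu}\,\mathrm{Cov}_w(y_i, R_i),$$

positive when health education concentrates among high-consumption
households (concentration curve below the diagonal).  A
heteroskedasticity-robust SE comes from the convenient regression
$2\sigma^2_R\, y_i/\mu = \alpha + \beta R_i + u_i$, whose slope equals the
CI; Erreygers and Wagstaff corrections for the bounded 0–32 outcome are
available behind a flag.

**Wagstaff decomposition.**  For a linear model
$y_i = \beta_0 + \sum_k \beta_k x_{ki} + \varepsilon_i$,

$$CI = \sum_k \eta_k C_k + \frac{GC_\varepsilon}{\mu}, \qquad
\eta_k = \frac{\beta_k \bar x_k}{\mu},$$

attributing inequality to each covariate through its elasticity and its
own concentration index; the adding-up identity is asserted on every run.

**Horizontal inequity.**  $HI = CI - \sum_{k \in \text{need}} \eta_k C_k$,
netting out the contributions of need factors (age, gender, education
years, health status): the inequality that remains after legitimate need
differences are removed.

**Post-double-selection Lasso.**  The exposure effect of the consumption
composite is estimated by Lasso-selecting controls twice (for the outcome
and for the exposure; cyclic coordinate descent, 10-fold CV over a
log-spaced penalty grid) and running OLS of the outcome on the exposure
plus the union, with sandwich SEs.  City/community fixed effects are
penalized during selection and always included in the final OLS.

**Synthetic survey generator.**  A Gaussian copula induces target rank
correlations between covariates and a latent consumption factor; marginals
follow the published sample profile (51% male, 9.86 mean education years,
85 cities / 301 communities, five-item Likert consumption battery with
Cronbach's α ≈ 0.85).  The latent outcome is linear with known
coefficients — the default world has a true consumption effect of 0.30 on
the log score and a population CI calibrated to ≈ 0.032 — then discretized
onto 0–32 and split into four exchangeable items that sum exactly to the
total.

## Worked example

```bash
python analysis/01_simulate.py    # draw the 7,715-respondent survey (scratch/survey.csv)
python analysis/02_scores.py      # scores, composite, reliability
python analysis/03_lasso.py       # OLS vs post-double-Lasso exposure effect
python analysis/04_inequality.py  # CI, HI, decomposition, subgroups
```

The last two steps print (seed 20200301):

```
post-double exposure coefficient: 0.2593 (robust SE 0.0292)

CI (score ranked by consumption): 0.0251 (robust SE 0.0041; bootstrap SE 0.0041)
HI (need = gender, education_years, health_status, age_sq): 0.0451 (bootstrap SE 0.0043)
decomposition residual: -1.24e-04 (-0.49% of CI)
```

Reading: the exposure estimate sits 1.4 robust SEs from the simulated
truth of 0.30.  CI > 0 says health education is concentrated among
high-consumption households; HI > CI because the age profile (older
respondents consume more but know less) masks part of the inequity that
reappears once need factors are netted out.  The decomposition residual is
a fraction of a percent of the CI, as expected when the decomposition uses
the Lasso-selected covariate set.

Equivalently in one shot: `healthineq run --simulate --seed 1 --outdir results/run1`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch at the study scale — generates a
7,715-respondent survey with the given seed, builds the scores and
composite, fits OLS and post-double-Lasso, and computes CI, HI, the
decomposition and the subgroup table — then writes the results file.

## Layout

- `src/healthineq/` — library: `synthetic` (generator), `scores`
  (outcome/composite/reliability), `lasso` (CD solver, CV,
  post-double selection), `inequality` (ranks, CI, curve, decomposition,
  HI, bootstrap), `pipeline` (validation + orchestration), `cli`.
- `analysis/` — numbered narrative drivers reproducing the study's tables.
- `docs/methods.md` — modelling assumptions, calibration, and limitations.
- `tests/` — unit, property and acceptance tests.
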