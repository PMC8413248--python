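# inflamr

Inflammation and affective symptoms: a tested pipeline for quantile
dose-response regression with floating absolute risks, disorder-specificity
testing by bivariate probit, and one- and two-sample Mendelian randomisation
(MR) with Cochran's Q and inverse-probability-weighted (IPW) selection-bias
correction — exercised end-to-end on a synthetic biobank-style cohort whose
generative model encodes the hypothesised causal chain

```
IL6R variants ──► IL-6 activity ──► log CRP ──► depression / anxiety liability
CRP variants  ────────────────────────┘                 │
            shared confounding (BMI, deprivation, ...) ─┘
PHQ-9 / GAD-7 scores ──► optional-survey participation (collider)
```

It is written for epidemiologists and biostatisticians who want the whole
inferential chain — simulation, observational dose-response, joint outcome
modelling, and summary-statistic MR — as composable, unit-tested Python.

## Methods at a glance

- **Dose-response** — serum CRP (mg/L) is cut into quintiles/deciles on the
  analysis sample; symptom scores enter as log(score+1) (exponentiated
  coefficients reported as OR-style ratios) and probable diagnoses
  (PHQ-9 ≥ 10, GAD-7 ≥ 10) by logistic regression, with four nested
  adjustment sets. Floating absolute risks give every quantile, reference
  included, its own variance λ_k with Var(β_i − β_j) ≈ λ_i + λ_j.
- **Specificity** — probable depression and anxiety are modelled jointly as
  a bivariate probit (latent bivariate-normal errors, correlation ρ; orthant
  probabilities via Owen's T). A likelihood-ratio test with 1 df compares
  free vs equality-constrained CRP coefficients; probit estimates convert to
  ORs as exp(1.6·b).
- **Mendelian randomisation** — per-SNP Wald ratios θ_j = β_Yj/β_Xj with
  first-order SEs combine into the inverse-variance-weighted estimate
  β_IVW = Σ w_j θ_j / Σ w_j, w_j = β_Xj²/se_Yj²; Cochran's
  Q = Σ w_j (θ_j − β_IVW)² ~ χ²(J−1) screens for heterogeneity/pleiotropy.
  Allele harmonisation (strand flips, palindromic-SNP frequency rule) aligns
  external instrument tables. IL-6 exposure uses IL6R-region variants with
  CRP as the downstream readout of classic IL-6 signalling.
- **Selection bias** — survey participation is modelled by logistic
  regression on symptom scores and demographics; weighting selected rows by
  1/p̂ recovers full-cohort estimands distorted by outcome-dependent
  participation.

## Worked example

```python
import dataclasses
from inflamr import SimulationConfig, generate_cohort, fit_doseresponse, run_mr

cfg = dataclasses.replace(SimulationConfig(), n_participants=50_000,
                          theta_il6_dep=0.3, theta_crp_dep=0.0, seed=3)
cohort, truth = generate_cohort(cfg)

dose = fit_doseresponse(cohort, outcome="dep_dx", K=5, model=4)
print(round(dose.odds_ratios[-1], 3), round(dose.trend_p, 4))

mr = run_mr("one_sample", "il6", "dep_score", cohort=cohort)
print(round(mr.beta, 3), round(mr.se, 3), round(mr.odds_ratio, 2))
```

prints (seed 3):

```
5.952 0.0
0.373 0.061 1.45
```

In this cohort a strong IL-6 effect (θ = 0.3) drives both CRP and the
depression liability, so the observational top-vs-bottom quintile odds ratio
is large (5.95, trend p < 10⁻⁴ shown as 0.0) — causal signal and shared
upstream drive are entangled.  The one-sample IVW estimate over the three
IL6R instruments isolates the causal component: 0.373 ± 0.061 on the
log-ratio scale (OR 1.45 per SD of genetically predicted IL-6 activity),
whose 95% CI covers the simulated θ = 0.3.

The same analyses are available from a shell:

```
inflamr simulate --seed 1 --n 50000 --out sim/
inflamr observational --cohort sim/cohort.csv --outcome dep_dx --k 10 --model 4
inflamr mr --design 2sample --exposure il6 --outcome dep_score \
        --cohort sim/cohort.csv --instruments sim/instruments.tsv
inflamr run --seed 1 --out results/
```

## Layout

```
src/inflamr/simulate.py       synthetic cohort generator + ground truth
src/inflamr/observational.py  quantiles, floated variances, IPW, dose-response
src/inflamr/specificity.py    bivariate probit / Gaussian system, LRT
src/inflamr/mr.py             Wald ratios, IVW, Cochran's Q, harmonisation
src/inflamr/io.py             cohort CSV, instrument TSV, VCF export, pipeline
src/inflamr/cli.py            click-based command-line interface
docs/methods.md               modelling assumptions and numerical choices
```
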