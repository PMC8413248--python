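# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `inflamr`, at the level of detail a maintainer or reviewer
needs to judge what the package's tests do and do not establish.

## 1. The synthetic cohort

The generator produces a mid-life population cohort with CRP assays and
web-questionnaire symptom scores. The generative order is fixed: genotypes →
latent IL-6 activity → log-CRP → bivariate symptom liabilities → integer
scores → survey-participation flag.

**Genotypes.** Biallelic variants in two regions (4 CRP-region, 3
IL6R-region by default) are drawn under Hardy–Weinberg equilibrium with
allele frequencies uniform on `eaf_range = (0.15, 0.45)`, mutually
independent (an LD-pruned instrument set). Dosage for a SNP with frequency
p has mean 2p and variance 2p(1−p).

**IL-6 activity and CRP.** IL-6 activity A is a unit-variance latent:
per-allele effects `gamma_il6r = (0.12, 0.10, 0.08)` SD/allele plus a normal
residual. Log-CRP is

    log CRP = c0 + δ·A + Σ α_j g_j + confounder terms + ε,  ε ~ N(0, 0.18²)

with `alpha_crp = (0.10, 0.08, 0.06, 0.05)` log(mg/L)/allele and
δ = `delta_il6_to_crp` = 1.0. The unit δ makes serum CRP a faithful
downstream readout of classic IL-6 signalling: one SD of IL-6 activity moves
log-CRP by one unit, so MR estimates "per unit genetically predicted IL-6
activity" and "per unit log-CRP induced through IL6R variants" coincide.
Consequently most CRP variance is IL-6-driven; confounders (latent U, BMI,
smoking, age, sex) add modest direct loadings on top.

**Liabilities and scores.** Depression and anxiety liabilities receive the
causal terms θ_il6·A and θ_crp·(log CRP − c0) (scaled per sex by
`sex_effect_multipliers`), confounder loadings (U, BMI, Townsend index, sex,
age, smoking), and a bivariate-normal residual pair with SDs (0.99, 1.20)
and correlation 0.895. A score is a negative-binomial draw with log-mean
`intercept + liability` (unit slope — per-unit liability effects are
directly effects on the log symptom-score scale), NB size 30, truncated at
the instrument maximum (PHQ-9: 27, GAD-7: 21).

**Calibration.** The defaults (score-link intercepts 0.428/−0.012, residual
SDs, residual correlation, CRP intercept 0.099) were calibrated once, by
simulation at n = 1.5M, to the marginal statistics of the target population:
median CRP 1.15 mg/L, mean scores 2.76 and 2.15, score correlation 0.68,
probable-diagnosis prevalences 5.5% and 4.4%. These six targets pin the
calibration tightly: hitting the 0.68 score correlation forces most score
variance through the correlated liability (an NB-noise-dominated calibration
cannot exceed correlation ≈ 0.5), which fixes the liability SD near 1 and
hence the shape of the upper score tail.

**Selection.** Participation in the optional follow-up survey is logistic in
(dep score −0.09/point, anx score −0.04/point, age +0.012/yr, female +0.15,
Townsend −0.05/unit, intercept 0.55; ≈ 57% participate). Because the linear
predictor contains the outcomes themselves, conditioning on participation
opens a collider path; the coefficients sit in the config and can be zeroed.

**What the generator does not emulate.** LD structure, imputation
uncertainty, population stratification, relatedness, assay error in CRP,
item-level questionnaire structure, missing covariates, and the recruitment
(as opposed to survey) selection of a volunteer cohort. Passing tests
therefore show the estimators are correct under the assumed causal
structure, not that the substantive findings transfer to any real cohort.

## 2. Observational dose-response

Quantile cut points are empirical quantiles (`inverted_cdf`, so cut points
are observed values) of the analysis sample; ties at a cut point go to the
lower group. Symptom scores are analysed as log(score+1) by linear
regression — exponentiated coefficients are reported as OR-style ratios,
the interpretation adopted for "anti-logged" linear-model coefficients —
and probable diagnoses by logistic regression. Adjustment sets are
cumulative: model 1 unadjusted; 2 + age, sex, BMI; 3 + smoking, alcohol,
physical activity, ethnicity, Townsend index; 4 + diabetes, cardiovascular
disease; categorical covariates enter as indicator sets and constant columns
are dropped. Analyses are complete-case.

**Floating absolute risks.** Given the covariance V of the K−1 non-reference
log-OR contrasts, the reference variance is the mean off-diagonal element
λ₀ = mean(V_ij, i≠j) and λ_k = V_kk − λ₀ (floored at 10⁻¹²). Under compound
symmetry this is exact and Var(β_i − β_j) = λ_i + λ_j identically; an
optional least-squares refinement minimises Σ_{i<j} [(λ_i+λ_j) −
Var(β_i−β_j)]² over all pairs including the reference, with non-negativity
bounds. Floated 95% CIs are exp(β_k ± 1.96√λ_k) with β_ref = 0.

**Trend, curvature, interaction.** The trend OR uses the quantile index as a
numeric predictor; curvature adds a centred (log CRP)² term (centring
decorrelates the linear and quadratic terms); the sex interaction adds
sex × log CRP with stratified fits reported alongside.

**IPW.** The selection model is logistic in (dep score, anx score, age, sex,
Townsend index) — in the synthetic world these are observed for everyone, so
a correctly specified fit is possible; with real data the unselected rows
must carry the model's covariates. Estimated probabilities are floored at
10⁻³ (truncations counted); weights are 1/p̂ for selected rows and 0
otherwise, so weighted full-table fits equal weighted selected-only fits.
All weighted fits use HC0 sandwich variances; a stabilised variant
multiplies by the marginal selection fraction.

## 3. Disorder specificity

The categorical analysis is a bivariate probit: latent bivariate-normal
errors with correlation ρ, orthant probabilities computed from Owen's T
function (absolute accuracy ~10⁻¹⁴, verified against 2-D quadrature to
10⁻⁸). The log-likelihood is maximised by BFGS with analytic gradients,
started from the two univariate fits and ρ = 0; ρ is parameterised as
0.9999·tanh(z) so boundary cases (e.g. duplicated outcomes) converge
smoothly. Convergence requires the per-observation mean gradient below
10⁻⁶ (flagged on the fit); optimisation aborts with diagnostics if it
exceeds 10⁻³. Standard errors come from the observed information (central
differences of the analytic gradient) with a delta-method map back to
(β₁, β₂, ρ).

The equality test constrains the CRP coefficient to be shared across
equations (covariates stay free): LR = 2(llf_free − llf_constrained) ~ χ²(1).
Probit coefficients convert to ORs as exp(1.6·b), the standard
probit-to-logit slope rescaling; at the small effect sizes typical of
CRP–symptom associations this tracks a directly fitted logistic OR within a
few percent, degrading as effects grow.

The "continuous outcome" analysis uses the same machinery on a bivariate
Gaussian system for the transformed scores (identical regressors, so the
unconstrained MLE is per-equation OLS; the constrained fit is iterated
feasible GLS, which converges to the MLE). A probit likelihood is undefined
for continuous responses, so this is the package's chosen continuous
analogue; no attempt is made to reproduce any particular published per-unit
scaling of continuous probit ORs.

## 4. Mendelian randomisation

Per-SNP associations are one regression per variant of the analysis variable
on dosage plus covariates (default age and sex; sex is dropped within sex
strata; genetic principal components are out of scope because the simulator
has no stratification). Families: linear for log-CRP; log-link
quasi-Poisson with HC0 sandwich SEs for the count scores; logistic for
probable diagnoses. The log link for counts means per-allele effects are on
the multiplicative symptom-score scale — the scale on which the generative
model is linear — so IVW estimates are directly comparable to the simulated
θ parameters and exponentiate to OR-style ratios.

**Ceiling correction.** Bounded instruments compress multiplicative effects
near their maximum: at the default calibration ≈ 0.2% of people sit at the
PHQ-9 ceiling, attenuating log-mean slopes by ~5–7%. Per-SNP score effects
are therefore rescaled by the attenuation factor
c = d log E[min(S, cap)]/d log E[S] of an NB-lognormal measurement model
fitted by ML to the marginal score histogram (Gauss–Hermite quadrature,
61 nodes). The factor is computed from observable data only, reported on
the association table, and reverts to exactly 1 when no mass approaches the
ceiling. Censoring-only corrections (censored Poisson/NB) do not work here
because the ceiling mass comes from the heavy lognormal liability tail
rather than count noise.

**Estimator.** Wald ratios θ_j = β_Yj/β_Xj carry first-order SEs
se_Yj/|β_Xj| (exposure uncertainty ignored — standard for strong
instruments; the simulated per-SNP F statistics are in the hundreds).
Fixed-effect IVW is the default; the multiplicative random-effects option
scales the SE by max(1, √(Q/(J−1))). Cochran's Q uses the same first-order
weights and is reported as missing with df 0 for a single instrument.

**Harmonisation.** External instrument tables are aligned to the outcome
table by allele: matching pairs pass, swapped pairs flip the beta and
complement the frequency, opposite-strand codings are complemented first.
Palindromic (A/T, C/G) variants are aligned by allele frequency only when
both frequencies are outside (0.42, 0.58), otherwise dropped; flip/drop
counts are attached to the result. One-sample designs skip harmonisation
(both tables inherit the dosage coding).

**Designs.** `one_sample` estimates SNP-exposure and SNP-outcome
associations on the same cohort (overlap permitted, as in a single-cohort
design; no winner's-curse correction since instruments are fixed a priori).
`two_sample` takes exposure betas from an external instrument table. The
IL-6 exposure uses IL6R-region variants with CRP as readout; the CRP
exposure uses CRP-region variants with log-CRP. IPW variants re-estimate
SNP-outcome associations with selection weights and sandwich SEs.

## 5. Numerical and testing choices

- Single global seed; the generator and the selection re-draw use distinct
  fixed substream keys, so re-applying selection is deterministic and stage
  toggling does not shift other stages' draws. JSON outputs serialise at
  full double precision; the pipeline is byte-reproducible given config and
  seed.
- The regression backend is a compact IRLS implementation (Gaussian,
  logistic, Poisson, weights, HC0) cross-checked against statsmodels in the
  test suite; statsmodels remains the reference implementation in those
  cross-checks. Logistic fits raise on diverging coefficients
  (quasi-separation).
- Monte-Carlo test sizes were chosen so the assertion thresholds sit ≥ 2.5
  Monte-Carlo SEs from the expected values: simulator calibration is checked
  once at n = 146,954; Q null calibration uses 2,000 summary-statistic
  replicates; the specificity LRT null uses 400 replicates at n = 5,000;
  effect recovery uses 200 replicates at n = 50,000; the collider/IPW
  comparison uses 200 replicates (n = 30,000 observational arm, n = 120,000
  MR arm, paired against the full-cohort estimate because the weighted MR
  estimator has ~2.5× the unweighted sampling SD).
- Known limitations: the ceiling correction assumes the NB-lognormal family;
  floated variances are a heuristic outside compound symmetry (the refined
  fit is provided but not default); the bivariate probit does not handle
  sample weights; trend ORs use the quantile index, not group-median CRP.
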