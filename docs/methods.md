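# Methods

## Scope and data model

`survmeta` analyses right-censored time-to-event data in flat patient-level
tables: one row per subject, a non-negative observed time (any unit), an
event flag (1 = event, 0 = censored), and covariates that are either
continuous (interval/ratio measurement) or categorical (nominal/ordinal,
recoded to integer codes through the layer-3 dictionary). Left censoring,
left truncation, interval censoring, time-varying covariates, competing
risks and date arithmetic (deriving survival time from diagnosis/last-contact
dates) are out of scope; the time column is consumed as given.

The canonical event coding after recoding is 0 = censored/alive, 1 =
event/dead. When an analysis names an `endpoint_level`, the event indicator
becomes `raw_code == endpoint_level`; otherwise the canonical 0/1 coding is
used directly.

## Metadata inference

`generate_metadata` classifies a numeric column as continuous when it has
more than `max_levels` distinct non-missing values, default 6. The default
is a deliberate compromise: clinical categoricals coded as integers (stage
1–4, grade 1–3, 0/1 flags) almost never exceed 6 levels, while genuine
measurements (age, counts, lab values) almost always do. It is configurable
because count covariates with a tiny support can fall on either side.
Layer-3 token matching is whitespace-trimmed but case-sensitive (m and M are
distinct tokens that may map to the same code).

## Filtering semantics

Criteria are conjunctive and ordered. A missing value fails every criterion
except `missing` / `not-missing`, so filters never silently admit subjects
whose eligibility cannot be established. Excluded rows are attributed to the
first criterion they fail; the attribution depends on criterion order, the
included set does not. Complete-case elimination for the statistical
procedures happens inside each procedure (per variable for Table 1, listwise
over the formula columns for KM/log-rank/Cox), not at load time, so each
analysis uses the maximal available data.

## Table-1 test selection

The selection flow is a total, deterministic function of
(analysis class, number of groups, normality verdict):

| class       | groups | normal | test              |
|-------------|--------|--------|-------------------|
| continuous  | 2      | yes    | Welch t-test      |
| continuous  | >2     | yes    | one-way ANOVA     |
| continuous  | 2      | no     | Wilcoxon rank-sum |
| continuous  | >2     | no     | Kruskal–Wallis    |
| categorical | any    | —      | chi-square        |

Design choices where the flow was genuinely open:

* Normality is tested **per group**, and the parametric branch requires every
  group to pass; a pooled test can pass on a mixture of shifted groups that
  are individually normal and vice versa, and the per-group form matches the
  assumption the t-test/ANOVA actually make. Groups with fewer than 3
  observations cannot be tested and route to the nonparametric branch.
* Shapiro–Wilk is used for 3 ≤ n ≤ 5000 and Anderson–Darling (with the
  D'Agostino–Stephens p-value approximation, via statsmodels) above, where
  the SW p-value approximation degrades. α for the normality gate is 0.05,
  configurable.
* The two-group rank test generalises to Kruskal–Wallis for >2 groups.
* Welch's unequal-variance t-test is the default (`pooled_t=True` restores
  the pooled form): it holds its level under variance heterogeneity at
  negligible cost under homogeneity.
* Chi-square is Pearson's without continuity correction; on a 2×2 table with
  any expected count < 5 the Fisher exact test is substituted and recorded in
  the selection trace. The fallback is never silent.
* All tests are two-sided. No multiplicity adjustment is applied across
  table rows.
* A constant sample is reported as decisively non-normal (p = 0) rather than
  erroring, so degenerate covariates fall through to the rank tests or are
  flagged untestable.

## Survival estimators

**Kaplan–Meier.** Event times are the distinct times with ≥ 1 event; the
risk set at t contains every subject with observed time ≥ t, so a subject
censored exactly at an event time remains at risk for it (standard
convention). Ŝ is the cumulative product of (n−d)/n; the variance is
Greenwood's sum, set to 0 once Ŝ reaches 0 (consistent with the
no-censoring closed form Ŝ(1−Ŝ)/n). Confidence bands default to the
log(−log) transformation, which keeps the band inside [0, 1]; a linear
(plain Greenwood) band is available. The median is the smallest event time
with Ŝ ≤ 0.5, undefined (reported "not reached") when the curve never
crosses one half. An all-censored sample yields a constant-1 curve with a
warning rather than an error.

**Log-rank.** At each event time with risk set n, d events and group counts
(n_g, d_g), the observed d_g is compared with expectation d·n_g/n; the
covariance of the per-group observed-minus-expected uses the multivariate
hypergeometric form with the tie factor d(n−d)/(n−1), and a risk set of
size 1 contributes zero variance. The k-group statistic is the quadratic
form of the first k−1 components of O−E in the inverse covariance, df = k−1
(matrix inversion falls back to a pseudoinverse if the covariance is
singular). Stratified tests sum O−E and the covariance over strata before
forming the quadratic form — the same per-stratum-risk-set semantics the
Cox fitter uses for its strata.

**Cox proportional hazards.** The partial likelihood is maximised by
Newton–Raphson from β = 0 with per-stratum risk sets and either the Efron
(default) or Breslow tie correction; Efron is the accepted default under
ties, and Breslow makes the score test at β = 0 identical to the (unstratified,
tie-free) log-rank statistic, which the test suite exploits as a
cross-check. Implementation notes:

* Risk-set sums S₀ = Σ e^η, S₁ = Σ e^η x, S₂ = Σ e^η xxᵀ are suffix
  cumulative sums over subjects sorted by time, so Breslow quantities are
  fully vectorised; the Efron adjustment replaces the Breslow contribution
  only at event times with d ≥ 2.
* η is shifted by its maximum before exponentiation (the partial likelihood
  is invariant to this shift) to avoid overflow.
* Step-halving keeps the log-likelihood non-decreasing; convergence is
  declared when the score sup-norm < 1e-9 or the relative log-likelihood
  change does, max 50 iterations, and failure raises an error carrying the
  iteration trace.
* Separation (monotone likelihood) is reported when any |β_j| exceeds 50 or
  any per-SD magnitude |β_j|·sd(x_j) exceeds 10 — a hazard ratio above e¹⁰
  per standard deviation does not arise from estimable data. Globally
  constant covariates are rejected up front.
* Standard errors come from the inverse observed information at the
  optimum; CIs are Wald.

**Formula expansion.** A KM/log-rank formula with covariates expands the
groups over every combination of unique observed covariate values — numeric
covariates included — and refuses beyond 20 groups, since a continuous
covariate silently exploding into hundreds of single-subject curves is
always a design error.

## Synthetic cohorts

`simdata` draws covariates (Bernoulli, normal, categorical, Poisson — the
Poisson kind exists so count covariates like positive-node counts are
genuinely discrete), forms the linear predictor η = βᵀx with continuous
covariates centred at their design means, and inverts the cumulative hazard:
T = H₀⁻¹(−log U / e^η) for an exponential or Weibull baseline. Censoring is
administrative (fixed horizon), exponential with a given rate, or targeted:
an exponential censoring rate solved by root-finding so the expected
censored fraction equals the target (closed form μ/(μ+λ_i) per subject for
the exponential baseline, quadrature for Weibull). All randomness flows
through one `numpy` generator seeded from the spec, so a cohort is
byte-reproducible from its seed.

The default cohort mirrors a two-arm colon-cancer adjuvant trial: n = 600,
exponential baseline 4×10⁻⁴/day (untreated median ≈ 4.7 years), treatment
log-hazard −0.5, +0.08 per positive node, +0.01 per year of age, sex
balanced, differentiation 10/73/17 % and extent 2/11/81/6 %, with a 50 %
target censored fraction — magnitudes typical of adjuvant colon-cancer
cohorts. What it deliberately does not emulate: covariate correlation
(covariates are independent), non-proportional hazards, informative or
administrative-calendar censoring, measurement error, or structured
missingness (cells are only missing if an analysis introduces them). Tests
passing on these cohorts therefore demonstrate correctness of the
estimators under the proportional-hazards model with independent censoring,
not robustness to violations of it.

## Calibration and problem sizes

The test suite and `scripts/acceptance.py` verify, at fixed seed policies:

* KM/Greenwood closed forms exactly (no-censoring samples up to n = 200) and
  a hand-evaluated censored product at n = 3;
* the log-rank O/E/Var against direct per-event-time summation, and its
  type-I error under a two-arm exponential null (n = 100 per arm, 2000
  replicates, acceptance band 0.04–0.06);
* the Cox maximiser against a 1e-4 grid search of the partial likelihood
  (n = 15) and against lifelines with ties (efron) to 1e-6; score-test /
  log-rank equivalence to 1e-8;
* Cox recovery of HR = 2 at n = 2000 with 30 % censoring (mean β̂ within
  0.05 of log 2; 95 % Wald coverage within [0.93, 0.97]; 500 replicates in
  the test suite, 300 in the acceptance script);
* type-I error of each Table-1 comparison path at 1000 replicates with a
  three-binomial-SE tolerance;
* inverse-transform correctness of the simulator (sup-norm KM error ≤ 0.02
  at n = 10 000, uncensored exponential).

These sizes keep the full suite under half a minute on one CPU while leaving
Monte-Carlo error well inside each acceptance band.

## Known limitations

* The Cox fitter targets small-to-moderate p (tens of covariates); S₂ is a
  dense n×p×p suffix sum, so memory grows as n·p².
* Fisher's exact fallback applies only to 2×2 tables; larger sparse tables
  still use the asymptotic chi-square and can be anti-conservative.
* The Anderson–Darling p-value is an asymptotic approximation (capped near
  1), adequate for routing decisions rather than precise tail inference.
* `median_survival` reports the point estimate only, without a CI.
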