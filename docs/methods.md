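# Methods

## Model and procedure

A continuous risk factor Z is categorized by K strictly increasing
cutpoints c₁ < … < c_K into K + 1 ordinal risk groups,
group(v) = #{cₖ : v ≥ cₖ} (a value equal to a cutpoint joins the upper
group). The groups enter a regression model through K dummy variables:

* **Survival** (right-censored time T, event indicator δ): Cox
  proportional hazards, h(t|Z*) = h₀(t)·exp(Σₖ βₖZₖ), estimated by the
  partial likelihood with Efron tie handling (the default of the standard
  survival engines). The baseline hazard h₀ is profiled out.
* **Binary** (Y ∈ {0,1}): logistic regression,
  logit P(Y=1|Z*) = β₀ + Σₖ βₖZₖ. An intercept is always included; a
  model through the origin would force the reference group's probability
  to ½, which is not a sensible reference semantics for risk groups.

Two dummy codings are supported and are exact linear reparameterizations
of each other (identical likelihood, fitted values and tests, verified in
the test suite): *cumulative* coding (Zₖ = 1 iff group ≥ k; βₖ is the
adjacent-group log-HR/log-OR increment) and *one-hot* coding (group 0 as
reference; βₖ is group k versus reference, the form used in validation
reports).

**Locating K cutpoints.** Every strictly increasing K-tuple drawn from the
candidate grid is evaluated and the criterion is maximized (equivalently,
p minimized at fixed df):

| criterion | outcome | statistic | df |
|---|---|---|---|
| `logrank` | survival | (K+1)-sample log-rank (heterogeneity form) | K |
| `cox_lrt` | survival | 2(ℓ̂ − ℓ₀) of the Cox fit | K |
| `logistic_lrt` | binary | 2(ℓ̂ − ℓ₀) of the logistic fit | K |
| `max_auc` | binary | AUC of the fitted group probabilities | — |
| `chi2` | binary | Pearson χ² of the (K+1)×2 table | K |

A 1-df *trend* log-rank (ordinal scores) is available in `stats_core` by
flag; the heterogeneity form is the default for K ≥ 2 because it does not
presume monotone risk (the U-shaped BMI case is the motivating
counterexample). The unadjusted logistic model is saturated in the groups,
so its fitted group probabilities equal the observed event fractions; AUC
is scored on those fractions and is *not* forced to be monotone in the
group index. Ties in any criterion break toward the smallest cutpoints in
lexicographic order, so results are deterministic.

**Choosing the number of cutpoints.** For each K in the scanned range the
criterion-optimal cuts are located first, the categorized model is fitted
there, and AIC = 2k − 2·log L is recorded (k = K coefficients for Cox,
K + 1 with the intercept for logistic; cutpoint *locations* are not
counted as parameters — this is the standard AIC of the fitted model).
K = 0 (no split) is included as a sanity floor. The minimizing K is
selected; ties go to the smaller K. BIC and AICc are offered as flags but
are not part of the default procedure. Scoring AIC at each K's best cuts
is the only self-consistent ordering of the "choose K, then locate"
workflow, which as literally drawn is circular; `--fixed-quantile-cuts`
emulates the alternative of scoring K at equally spaced quantile cuts.

**Hold-out validation.** The cohort is split uniformly at random (seeded,
unstratified) into training and testing halves; cuts discovered on the
training half are applied to the testing half as a one-hot group factor in
a multivariate Cox/logistic model with the adjustment covariates.
Categorical covariates are one-hot encoded with the most frequent level as
reference.

## Candidate grid and search constraints

Candidates default to the *distinct observed values* of Z (reported
cutpoints are then attainable data values); a midpoint grid is available
by flag. Two floors make the minimal-p search well-posed — unconstrained
searches drift to the edges of the observed range where variance explodes:

* `min_group_frac` (default **0.10**): each induced group must keep at
  least ⌈0.10·n⌉ subjects. Applied once per single candidate when the grid
  is built (either side of the cut) and to every group of every tuple
  during the search.
* `min_events_per_group` (default **5**, survival only): each group must
  contain at least 5 events.

Tuples violating a floor, with a singular log-rank covariance, a
non-convergent Cox fit (monotone likelihood), or a quasi-separated
logistic group (all-0 or all-1 outcomes) are counted in `n_invalid` and
excluded from the argmax.

## Computation

The scan is exhaustive — no pruning, exactness is the point — but
organized so it stays fast. Sorting subjects by Z once makes every
group-level count a prefix quantity: with N(t, c) the number of subjects
below cut c at risk at time t, the log-rank O − E vector and its
hypergeometric covariance are linear and bilinear forms in the prefix
at-risk matrix, and the full two-cut surface over m candidates needs one
m×m matrix product (`G = CᵀC`). Binary criteria are closed forms in
per-group subject/event counts (the saturated likelihood, Pearson χ², and
a group-level Mann–Whitney AUC with exact integer tie handling). Only the
`cox_lrt` criterion fits a model per tuple — a dedicated Newton solver for
the Efron partial likelihood on grouped covariates, O(#events) per
iteration — so it scales as O(m²) small fits and is the slowest criterion
on dense grids. The kernels are cross-checked in the tests against
lifelines, statsmodels, scipy and a naive per-tuple double-loop reference.

Public model fits go through the standard engines (lifelines Cox and
Kaplan–Meier, statsmodels logistic, scipy χ², scikit-learn AUC).
Convergence: Newton/IRLS with the library defaults; a fit with any
|coefficient| > 15 is flagged non-convergent and its candidate rejected.
Likelihood-ratio statistics negative by < 1e-8 (float noise) are clipped
to zero; larger violations raise, since they indicate a failed fit.

## Synthetic cohorts

`findcut.synthetic` generates cohorts with *known* true cutpoints so every
claim is testable without private data. Event times are exponential with a
constant hazard per latent group — proportional hazards holds exactly and
true adjacent-group log-HRs are ln(h_{g+1}/h_g) analytically; censoring is
the minimum of an exponential censoring time and an administrative
follow-up cap. Binary outcomes are per-group Bernoulli draws. Identical
seeds give byte-identical tables.

Four shipped scenarios mimic common gynecologic-oncology analyses, sized
like a single-center cohort (n = 797, split 497/300):

| scenario | z distribution | true cuts | effect | outcome |
|---|---|---|---|---|
| `lymph_nodes` | Poisson(2.5) counts | 5 | hazard 0.03 → 0.12/yr | survival |
| `tumor_size` | lognormal, median 3.5 cm | 3.25 | P(event) 0.12 → 0.42 | binary |
| `bmi` | lognormal, median 24.3, ~13% deaths | 19.88, 29.59 | U-shaped hazard 0.06/0.02/0.06 per yr | survival |
| `stromal` | Beta(1.4, 1) fraction | 0.32, 0.88 | P(event) 0.12/0.40/0.85 | binary |

Censoring defaults (exponential rate 0.20/yr, 22-year cap) give the
`bmi`/`lymph_nodes` scenarios a realistic ~90% censoring level; the
calibration studies instead use a well-followed design (rate 0.05/yr,
10-year cap, hazards 0.3/0.1/0.3 → ~65% events) so that recovery is a
property of the estimator rather than of follow-up length. The `stromal`
upper cut sits at 0.88 rather than at the extreme tail so that the top
group clears the default 10% group-size floor.

What the generator does *not* emulate: covariate-dependent censoring,
non-proportional hazards, measurement error in Z, correlated covariates,
competing risks. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated generative model, not
robustness to those violations.

## Study sizes used in tests and the acceptance script

Oracle-equivalence checks run 20 cohorts of n = 150 with an
integer-rounded risk factor (grids ≤ 40 candidates, all five criteria,
K ∈ {1, 2}). Cut recovery uses n = 500, HR 3, true cuts at the 33rd/67th
percentiles, 50 replicates (25 in the acceptance script), scored as both
cuts within 0.5 adjacent-group SDs. AIC selection uses n = 600 with
adjacent-group OR 4 on a count-valued risk factor, 50 replicates, against
a matched null; type-I calibration uses 200 null replicates of n = 200
with a fixed median cut. Large-sample recovery checks use n = 10⁴ (Cox)
and 4×10⁴ (logistic log-odds, where the ±0.1 tolerance needs ~3σ heroom).

## Known limitations

* **Minimal-p optimism.** The selected p-values, effect sizes — and, on
  dense candidate grids, the AIC gain from an extra cutpoint — are biased
  upward by the search; no multiplicity correction is applied, by design.
  With hundreds of distinct Z values the null probability of preferring
  K = 2 over K = 1 by AIC approaches 1; with the modest grids of recorded
  clinical measurements (tens of distinct values) it stays well below ½.
  Hold-out validation is the intended safeguard and is built into the
  workflow.
* The search handles K > 2 (general tuple enumeration) but is tuned for
  K ∈ {1, 2}, the cases of practical interest; K > 2 falls back to
  per-tuple evaluation and grows combinatorially.
* Sensitivity/specificity for K ≥ 2 groups require collapsing to a binary
  prediction; the default thresholds the fitted group probability at 0.5
  (`rule="prob"`), with highest-group-versus-rest available
  (`rule="top_group"`). Neither is canonical.
* No stratified splitting, time-varying covariates, stratified Cox, exact
  logistic regression, Firth correction, interval censoring or competing
  risks. Missing data are handled by listwise deletion with logged counts.
* The smoothed HR curve's spline degrees of freedom (default 4, knots at
  evenly spaced quantiles of the 5th–95th percentile range) are a display
  choice; the curve is a visual aid, not an inferential statement, and its
  pointwise bands ignore the df selection.
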