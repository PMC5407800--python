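# findcut

Optimal **number** and **location** of cutoff points for a continuous risk
factor, for right-censored survival outcomes and for binary outcomes.

Clinicians and epidemiologists routinely turn a continuous biomarker
(tumor size, BMI, a node count, an invasion fraction) into ordinal risk
groups. One threshold is standard practice; often two or more are needed —
a drug dose or a BMI can be risky at *both* ends — and there is rarely a
principled answer to "how many groups, and where?". `findcut` answers both
questions with outcome-driven model selection:

1. **How many cutpoints (K)?** For each candidate K, fit the categorized
   model at its best cutpoints and compare AIC = 2·k − 2·log L; the
   minimizing K wins (ties go to the smaller K).
2. **Where?** With K + 1 risk groups encoded as dummy variables
   Z₁,…,Z_K, exhaustively scan every strictly increasing K-tuple of
   candidate thresholds and keep the most significant split:
   - survival: Cox proportional hazards
     h(t|Z*) = h₀(t)·exp(Σₖ βₖZₖ), scored by the K-sample **log-rank**
     statistic or the Cox **likelihood-ratio** statistic;
   - binary: logistic regression
     logit P(Y=1|Z*) = β₀ + Σₖ βₖZₖ, scored by the **likelihood-ratio**
     statistic or by **maximum AUC**;
   - baseline: the traditional Pearson **χ²** contingency-table criterion,
     for comparison.
3. **Does it hold up?** Split the cohort into training/testing halves,
   locate cuts on the training half, and validate them on the held-out
   half in a multivariate Cox/logistic model alongside adjustment
   covariates (age, stage, histology, …).

A smoothed hazard-ratio curve (natural-spline Cox fit of ln HR(z) against
the risk factor) and per-group Kaplan–Meier curves provide the graphical
aid for choosing K. A value exactly equal to a cutpoint joins the *upper*
group, so "cut at 5" reads as "5 or more = higher risk".

The exhaustive scan is exact but fast: because every candidate threshold
splits one sorted axis, all group-level risk tables reduce to prefix sums,
and the two-cut log-rank scan over *m* candidates costs one m×m matrix
product rather than O(m²) model fits.

## Worked example

No real cohort ships with the package; seeded synthetic scenarios with
*known* true cutpoints stand in (`findcut.synthetic`). The `bmi` scenario
draws 797 subjects with a U-shaped death risk: true cuts at 19.88 and
29.59, hazard 0.06/yr in the outer groups versus 0.02/yr in the middle,
~13% observed deaths.

```python
import findcut as fc

cohort = fc.simulate_scenario("bmi", seed=1)          # 797 subjects, survival outcome
train, test = fc.split_cohort(cohort, 497, seed=2)

profile = fc.findcutnum(train, k_range=(0, 1, 2))     # how many cutpoints?
print(fc.compare_aic(profile).to_string(index=False))

res = fc.search_cutpoints(train, 2, "logrank")        # where are they?
print(f"cuts: {res.best.cuts}  logrank stat: {res.best_value:.1f}  p: {res.best_p:.2e}")

val = fc.validate_holdout(test, res.best)             # do they hold up?
print(val.table.round(3).to_string())
print(f"hold-out log-rank p = {val.logrank.p:.4f}")
```

prints

```
 k      loglik  n_params        aic  delta_aic        cuts  best
 2 -272.104698         2 548.209396   0.000000 19.61,24.24  True
 1 -275.131254         1 552.262508   4.053111       19.61 False
 0 -281.567608         0 563.135217  14.925820             False
cuts: (19.61, 24.24)  logrank stat: 22.5  p: 1.33e-05
          coef     hr     se  hr_low95  hr_high95      p
group_1 -1.186  0.305  0.404     0.138      0.674  0.003
group_2 -0.588  0.555  0.344     0.283      1.090  0.088
hold-out log-rank p = 0.0093
```

Reading it: AIC prefers two cutpoints over one (Δ = 4.1) and over no split
(Δ = 14.9), matching the U-shaped truth. The search places the cuts at
19.61 and 24.24 on this training half — the lower cut lands next to the
true 19.88; the upper one is pulled low because only ~56 deaths inform the
training scan (minimal-p cut locations are noisy in event-poor data; see
`docs/methods.md`). On the held-out 300 subjects the middle group's hazard
is 0.31× the low-BMI reference (p = 0.003) and the three Kaplan–Meier
curves separate (log-rank p = 0.009).

The same workflow is available from the shell:

```
findcut simulate --scenario bmi --seed 1 --out cohort.csv
findcut split    --input cohort.csv --z z --mode survival --time time --event event \
                 --n-train 497 --seed 2 --out-dir work
findcut findnum  --input work/cohort.train.csv --z z --mode survival --time time --event event
findcut locate   --input work/cohort.train.csv --z z --mode survival --time time --event event --k 2
findcut validate --input work/cohort.test.csv  --z z --mode survival --time time --event event \
                 --cuts 19.61,24.24
findcut plot     --input cohort.csv --z z --mode survival --time time --event event --cuts 19.61,24.24
```

For pipeline use, the scikit-learn style transformer wraps the search:

```python
binner = fc.OptimalCutpointBinner(n_cuts="auto", outcome="binary").fit(z, y)
binner.cutpoints_, binner.transform(z)   # learned cuts, ordinal groups
```

## A caution on minimal-p cutpoints

Choosing the threshold that maximizes significance is an optimistic
procedure: the selected p-value and effect size are biased away from the
null, and no multiplicity correction is applied here (by design — the
method is reported as defined). Always confirm cutpoints on a held-out
cohort, as `validate_holdout` does, and prefer clinical arguments for the
number of groups when they exist. The AIC comparison inherits the same
optimism when the candidate grid is very dense; see `docs/methods.md`.

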