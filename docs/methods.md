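# Methods

## Model and procedure

Let `Y ∈ {0,1}` be the outcome, `X ∈ ℝ^p` predictors, and `E ∈ {0,1}` an
environment label. The working assumption is a structural causal model in
which `Y` is generated as

    Y ~ Bernoulli( σ( β₀ + Σ_{j∈S*} β_j X_j ) ),

with `S*` the direct causal parents, and in which the environments arise
from interventions (mechanism changes) on variables *other than* `Y`. Under
that assumption the conditional law `Y | X_{S*}` is identical in both
environments, while `Y | X_S` for a set `S` that fails to block the
environment's influence generally is not.

The estimator tests each candidate subset `S`:

1. **Pooled logistic fit.** `Y` on `X_S` over all rows, by Newton/IRLS
   maximum likelihood. Pooling (one fit across environments) follows the
   plain reading of the procedure; per-environment fitting is out of scope.
2. **Residuals.** Response residuals `r = y − p̂` by default. Pearson and
   deviance residuals are available (`residual_type=`), because "residuals
   from model predictions" is ambiguous for a binary model; decisions can
   differ across residual types and no equivalence is claimed.
3. **Welch t-test.** Two-sided, unequal-variance comparison of residual
   means between the environment levels, with Welch–Satterthwaite degrees
   of freedom. Welch rather than the pooled-variance test because the
   environment groups are unbalanced and nothing guarantees equal residual
   variances. Two identical samples define `p = 1`.
4. **Decision.** `S` is accepted when `p ≥ α` — invariance *not rejected*.
   The convention matters: accepting when `p < α` would make stricter
   levels accept more subsets, which contradicts both the guarantee's logic
   and the way significance grids are read. A `reject_direction="reversed"`
   flag exists purely for sensitivity analysis.
5. **Intersection.** `Ŝ = ⋂ accepted`. Three outcomes are distinguished:
   `ok` (non-empty intersection), `empty_by_intersection` (subsets were
   accepted but share no predictor — indeterminacy), and `model_rejected`
   (nothing accepted, including the empty set — the invariance assumption
   fails everywhere). In rendered tables these appear as the set, `None`,
   and `-` respectively; which of the latter two a published dash denotes
   is a reporting convention we document rather than assert.

The guarantee `P(Ŝ ⊆ S*) ≥ 1 − α` needs only that the test on `S*` has
level `α`: when `S*` is accepted, any intersection that includes it is
contained in it.

A note on monotonicity in `α`: stricter (smaller) levels accept more
subsets, so the estimate can only shrink as `α` grows — but only *where the
estimate is defined*. At a level where every subset is rejected the
intersection runs over an empty family, which is vacuously the full
predictor set; reporting it as an empty estimate would spuriously break the
chain. `estimate_chain_monotone` therefore skips model-rejected levels
(which, by nestedness of the accepted collections, can only occur at the
widest levels of a chain).

### Numerical choices

* IRLS tolerance `1e-10` on the step, max 60 iterations, step-halving on
  the penalized deviance.
* **Separation.** If the fit does not converge or `|η|` exceeds 30 (fitted
  probabilities numerically 0/1), the model is refit with a ridge penalty
  of `1e-6` on slopes only, and flagged (`regularization_used="tiny-ridge"`).
  Subsets are never silently dropped: an untestable subset raises, because
  dropping one would bias the intersection.
* Rank-deficient Newton systems fall back to the pseudo-inverse with a
  warning.
* The empty subset uses the closed-form intercept-only fit
  (`logit(ȳ)`), so its residual test compares raw event rates across
  environments.
* Environment labels may be missing for rows whose raw value maps to
  neither level (e.g. gender responses outside the male/female dichotomy);
  such rows are excluded from that environment's analysis only.

### Subset search and screening

Enumeration is size-then-lexicographic in the given predictor order, empty
set first, so reports are byte-reproducible. `2^p` fits are permitted but a
`max_size` cap bounds the exhaustive method for large `p`. The lasso method
screens first: L1-penalized logistic regression on standardized predictors,
penalty chosen by 10-fold cross-validated deviance (folds seeded,
deviance-minimizing rather than one-standard-error, because the screen
should over-select — the intersection is robust to extra candidates but
broken by missing parents), keeping at most `k_max` predictors by absolute
coefficient (default 8, giving 256 subsets; published invariant sets in
this setting have ≤3 members, so 8 leaves headroom). No multiplicity
correction is applied across subsets, environments or α levels, matching
how such grids are reported.

## Synthetic data

### Structural causal models

`simulate_scm` draws predictors in topological order as linear-Gaussian
equations, applies per-environment interventions (`shift` adds a constant,
`scale` multiplies the noise SD, `do` pins the value), then draws `Y` from
the logistic mechanism. The outcome mechanism is never intervened on (a
contract violation), and the outcome has no children in this generator —
environments built from outcome descendants would be invalid anyway.
`calibrate_intercept` bisects the intercept on a large reference draw so
the pooled marginal event rate hits a target.

The default intervention regime (`default_interventions`) mean-shifts every
non-parent by one noise SD in environment 1. An important consequence,
visible throughout the simulations: with interventions confined to
non-parents, any upstream driver of a parent is itself a valid blocker of
the environment's influence, so several disjoint subsets are genuinely
invariant and the intersection is empty. Coverage holds (trivially, with
margin), but positive identification requires environments that perturb the
parents' own mechanisms — which ICP permits, since only the outcome's
mechanism must be spared. The test suite therefore exercises both regimes:
the shipped presets (`strong`, `weak`, `rare`; shifts on non-parents, per
the study conditions) for coverage and indeterminacy, and an identifiable
design (shifts on the parents themselves) to verify the estimator can
return exactly `S*`.

### Cohort emulator

`generate_study_like` emulates the applied study's schema: 18 predictor
scales with the published mean/SD/range, six binary environments with the
published prevalences, and a 2.1% outcome rate in a default cohort of
2,744. Design choices:

* **Marginals.** Truncated normals on the instrument bounds. The location
  is root-found so the *truncated* mean matches the published mean exactly;
  the scale is then chosen to minimize the SD gap. For strongly skewed
  scales (e.g. a scale with mean 6.6, SD 11.0 on [0, 64]) no truncated
  normal attains the published SD — on a left-bounded support the family's
  SD/mean ratio is bounded — so those SDs are matched only as closely as
  the family allows. Published range and mean are reproduced faithfully;
  heavy right tails are not.
* **Dependence.** One exchangeable latent correlation (default 0.3) among
  the clinical scales, reflecting that such instruments share substantial
  variance without inventing a specific correlation matrix. Age is
  independent of the scales.
* **Environments.** History variables (prior ideation/attempt/self-injury)
  add small *centered* latent shifts to a few risk scales, so environments
  are associated with the outcome through the predictors while marginal
  means stay on target; demographics are neutral. The age environment is
  the continuous age column dichotomized at ≤23 vs 24+ by the pipeline
  rule; gender is drawn with its full response categories and unmapped
  responses carry missing environment labels. One tension inherited from
  the published design is kept as-is: age appears both among the 18
  predictor scales and (dichotomized) as an environment.
* **Outcome.** A logistic model with small positive weights on shame,
  suicidogenic beliefs, and negative affect. These weights are *synthetic
  placeholders* chosen to make the pipeline exercise realistic; they are
  not estimates of any real cohort, whose raw data are not publicly
  deposited. The intercept is bisected on the realized sample so the
  marginal event rate converges to the target.

What passing tests show about real data is therefore limited: the emulator
reproduces first moments, prevalences, rarity and plausible cross-scale
dependence, but not item-level structure, skewness beyond the truncated
normal, missingness, or true effect sizes.

## Simulation experiments

`coverage_experiment` replicates simulate→estimate and reports empirical
coverage `P(Ŝ ⊆ S*)`, mean recovered fraction `|Ŝ ∩ S*|/|S*|` (for
`S* = ∅`, a replicate counts as recovered only when `Ŝ = ∅`), and the
fraction of empty estimates. Default 200 replicates (coverage SE ≈ 1.5% at
the 0.95 level); a sequence of α levels shares the per-replicate subset
tests, which is exact because p-values do not depend on α.
`rare_event_experiment` recalibrates the intercept to a target prevalence
(default comparison: half the default cohort per environment) and
quantifies how recovery collapses as events become rare — with ~29 events
per environment at 2.1%, residual-mean tests have almost no power, nearly
every subset is accepted, and the estimate is empty: the mechanism behind
the predominance of empty cells in the applied grid.

## Problem sizes

The shipped experiments run at: coverage — 200 replicates × 32 subsets at
n=4,000; α-monotonicity — 100 datasets at n=600; study grid — one 2,744-row
cohort, exhaustive method capped at subset size 2 (172 subsets/cell) and
lasso at `k_max=8` (≤256 subsets/cell) over 6 environments × 3 α; lasso
consistency — 100 replicates at n=5,000 with 18 predictors. These sizes
keep the full validation desk-scale while leaving the statistical
assertions at their stated replicate counts.

## Known limitations

* Two-level environments only; multi-level environments must be
  dichotomized.
* The t-test compares residual *means*; a variance-only invariance
  violation is invisible to it (the corresponding F-test is deliberately
  out of scope).
* Pooled fitting assumes the parents' coefficients are identical across
  environments — which is exactly the invariance being tested, so
  violations surface as rejections, not silent bias.
* No confidence intervals for accepted-set coefficients, no missing-data
  mechanism beyond per-environment label exclusion, and no correction for
  testing many environments.
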