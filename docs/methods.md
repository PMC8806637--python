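# Methods

## Pair indicators

The elementary feature is the within-sample comparison
`I(a,b) = 1{expr(a) > expr(b)}`, with ties scored 0 (equality falls in
the "otherwise" branch of the rule; with continuous expression ties have
measure zero, and the convention only matters for degenerate inputs).
Pairs are stored in a canonical lexicographic orientation; the published
signature keeps its own printed orientation and the scorer respects it,
flipping `1 − I` when only the reversed canonical row is available.
Because each indicator compares two genes inside one sample, the whole
downstream chain — screening, selection, scoring — is invariant to any
strictly increasing per-sample transform of expression; this is asserted
as a property test over random affine/exponential/cubic/rank transforms.

## Candidate-pair funnel

* **Variability filter.** Per platform, immune genes with
  MAD > `mad_threshold` (default 0.5) are retained; a gene must pass on
  every platform used for intersection. MAD is the bare
  `median |x − median x|` without the 1.4826 normal-consistency
  constant, which is exposed as an option but off by default — the
  threshold is conventionally quoted on the raw MAD scale. MAD is
  computed on log2 values by default (a config flag allows the linear
  scale); the indicators themselves are scale-free either way.
* **Prevalence filter.** A pair is kept only when its majority indicator
  class covers strictly less than `prevalence_bound` (default 0.8) of
  samples — a near-constant pair carries almost no information and is
  disproportionately likely to be a chance survivor of the screen. The
  boundary (exactly 80%) is excluded.
* **Cross-platform intersection.** Only pairs surviving the prevalence
  filter on every platform become candidates.

## Signature selection

Each candidate's 0/1 indicator enters a single-covariate Cox
proportional-hazards model; pairs with Wald p < 0.001 advance. The
screen is a vectorised Newton solver (Efron tie handling, damped steps,
divergence guard at |β| > 15 for separated likelihoods) because a run
fits thousands of models; it agrees with lifelines to ~1e-5 on coef,
SE and p, with and without tied event times. Constant or separated
pairs are skipped with a warning rather than crashing the screen.

LASSO-Cox selection fits the full L1 path (scikit-survival Coxnet,
`max_iter` 10,000) and scores each penalty by 10-fold cross-validated
partial-likelihood deviance (Breslow form) with seeded fold assignment;
the deviance-minimising penalty's non-zero coefficients form the
signature. Folds may truncate the path, so per-fold coefficients are
interpolated in log-penalty onto the common grid. The CV-minimum rule
and the fold count are deliberate choices where convention varies (the
1-SE rule is the common alternative); both are exposed as parameters.

Risk scores are the dot product of indicators with coefficients, and
each cohort is split at its own median score (strictly greater ⇒ high
risk; ties low). Stratifying validation cohorts at their own medians
rather than the training median keeps the two groups balanced per
cohort; a reference cutoff can be supplied to override this.

## Evaluation

* **KM / log-rank** wrap lifelines; the log-rank statistic is
  chi-squared with (groups − 1) degrees of freedom.
* **Time-dependent AUC** is the IPCW cumulative-case / dynamic-control
  estimator (scikit-survival): cases are events by the horizon, controls
  are event-free beyond it, censoring is reweighted by the KM estimate
  of the censoring distribution. Without censoring this reduces exactly
  to the empirical probability that a random case outranks a random
  control (ties half), which the tests verify against a brute-force
  pairwise count. Published AUC values from nearest-neighbour-smoothed
  estimators will differ slightly; no bit-level replication is claimed.
* **Harrell's C** uses the convention: a subject pair is comparable when
  the strictly earlier time is an observed event; tied scores earn 0.5;
  tied times are not comparable. An exhaustive double-loop oracle and
  scikit-survival (on tie-free data) agree exactly.
* **Cox tables**: univariate fits for age, gender (male = 1), grade,
  stage (ordinal 1–4) and score; covariates at p ≤ 0.001 enter a joint
  lifelines fit. Ordinal coding of stage/grade matches the
  single-hazard-ratio-per-factor reporting convention.

## United nomogram model

A two-covariate Cox fit (stage + risk score) with a Breslow baseline
cumulative hazard anchored at covariates = 0, so survival lookups are
`S0(t)^exp(βᵀx)` with the uncentred linear predictor — verified to match
lifelines' predictions exactly at observed event times (lifelines
interpolates between steps; this package treats the baseline as the
right-continuous step function it is). Nomogram points are affine per
covariate: the lowest-risk end of the training-cohort range earns 0
points and the widest-range covariate spans exactly 0–100; validation
samples outside the training range may exceed 100, which is reported
rather than clipped. Calibration bins a cohort into predicted-survival
tertiles by default (stable for cohorts of a few hundred) and compares
mean predicted survival with the bin's KM estimate at the horizon; bins
with no usable follow-up at the horizon are flagged, not dropped.
`simulate_from_model` draws survival from the fitted model by inverse
transform through the step baseline (administrative censoring past the
last baseline time), giving an internal self-consistency check:
at n = 2,000 every tertile agrees with its KM estimate within 0.05 at
the 1/3/5-year horizons.

## Synthetic cohorts

The generator emulates a two-platform retrospective study: a
log2-scale RNA-seq-like cohort and a linear-scale microarray-like
cohort (exercising the log2 ingest step), one shared gene universe, an
immune subset, and clinical covariates. Defaults mirror the target data
regime: cohort sizes 537 and 101; stage marginals 0.50/0.10/0.22/0.18
and grade marginals 0.03/0.44/0.39/0.14 (training-cohort composition of
the motivating study); ~67% male; censoring target 0.7 (≈30% observed
deaths); baseline hazard 0.12 events/year for the typical patient,
putting median OS near 6 years and the 1/3/5-year horizons inside
follow-up; five true pairs at conditional log-HR 0.7; per-sample
biological noise SD 1.0 on the log2 scale.

Mechanics and their consequences:

* Per-gene baselines are drawn once (normal on log2 scale, i.e.
  lognormal expression); true-pair members share a baseline so their
  indicator is a fair coin per sample and survives the prevalence
  filter. Platform gain/offset is a strictly increasing affine map of
  the log2 signal, so emitted-scale indicators equal base-signal
  indicators exactly — the hazard's linear predictor is reproducible
  from the written files, which a test asserts bit-for-bit.
* Survival is proportional-hazards with a Weibull baseline (shape 1 =
  exponential default, enabling closed-form KM checks). The hazard is
  centred at the analytic mean linear predictor so `baseline_hazard`
  retains its meaning regardless of effect sizes; Cox fits are
  invariant to the shift.
* Censoring is independent Uniform(0, c) with c solved numerically
  (bisection on the mean survival integral) to hit the target censored
  fraction in expectation; the empirical event fraction lands within a
  few percentage points over seeds.
* Age, gender and grade are simulated as pure nuisance (no hazard
  effect); stage is ordinal with a configurable log-HR per level,
  independent of expression. Real data differ in ways the generator
  deliberately omits: gene–gene correlation structure, stage–expression
  association, non-proportional hazards, informative censoring, batch
  effects beyond monotone transforms. Passing tests demonstrate the
  machinery recovers planted truth under the stated model, not that the
  published biology replicates.

## Numerical and statistical caveats

* Marginal screen power is attenuated by non-collapsibility: with five
  independent pair effects of conditional log-HR 0.7, the *marginal*
  log-HR per pair is ≈0.6–0.65, and per-pair screen power at p < 0.001
  with ~280 events is ≈0.92 — so requiring all five simultaneously
  succeeds in only about two thirds of runs. This is a property of Cox
  marginalisation, not an implementation defect; the recovery tests
  therefore phrase most guarantees per pair or as "≥4 of 5".
* Problem sizes in the test suite (cohorts of 120–400 samples, 10–100
  genes, 10–20 Monte-Carlo seeds per property) are chosen so the whole
  suite completes in well under a minute of statistics per property
  while leaving the binomial slack of each threshold comfortably wide.
* The pipeline evaluates AUC only at horizons inside a cohort's
  follow-up and records skipped horizons in the manifest notes; the
  united model is fitted only when both stage and score clear the
  multivariable significance gate, mirroring how the nomogram is meant
  to be built from independent prognostic factors.
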