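# Methods

This note documents the generative assumptions, estimators, numerical
choices and known limitations of `eftrial`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort

Each simulated child carries a latent ability z-score for eight domains
(response inhibition, interference control, verbal and visuospatial
working memory, switching, matching, everyday EF, social/emotional
wellbeing).  Baseline abilities are multivariate normal with a common
cross-domain correlation (default 0.3 — EF domains correlate in this age
band, and the generator makes that the default assumption) plus a
classroom random intercept shared across domains: with ICC ρ the ability
is √(1−ρ)·individual + √ρ·u_classroom, so every domain has unit marginal
variance and classroom ICC ρ at every occasion.  (The effective
cross-domain correlation becomes (1−ρ)·0.3 + ρ; at the default ρ = 0.1
this is a negligible shift.)  Across occasions the individual component
follows an AR(1) with autocorrelation 0.7 (a typical test–retest value
for child cognitive measures), keeping marginal variance stable.

The intervention enters as a mean shift of `effect_sizes[domain]` SD on
intervention-arm abilities at the post occasion, retained at a
configurable fraction (default 1.0) at follow-up.  Because the latent
scale is unit variance, the injected shift equals the standardized latent
group difference; the cohort tests verify recovery within ±0.1 at
500/arm.  A per-timepoint drift (both arms) is available for practice
effects and defaults to 0 so that null calibration is exact.

Demographics match the emulated trial's baseline table: age ~ N(7.46,
0.61) truncated to [6, 9), IQ ~ N(104.75, 14.22) resampled above the
eligibility floor of 70, 55% male, motivation ~ N(3.26, 0.89) on a 1–5
scale, family functioning ~ N(1.44, 0.38) on 1–4.  The continuous
`ses_index` is a synthetic standard-normal stand-in (the emulated survey
records only categorical caregiver education) and is used solely as an
imputation auxiliary and compliance covariate.  Adherence propensity is
Beta(6, 4) (mean 0.6), and sessions completed ~ Binomial(20, propensity),
giving the observed cohort mean of ~12 of 20 sessions.

## Ability → behaviour link

`POLICY_LINKS` maps latent z linearly to behavioural parameters, clipped
to physical ranges; z = 0 sits at the documented population defaults and
higher z is never worse on any parameter.  Defaults chosen for 6–8
year-olds: true SSRT 350 − 40z ms; timed-lift go distribution N(800,
60 − 10z) ms toward the 800 ms target; flanker base RT 750 − 60z ms with
a 100 − 25z ms congruency cost, 40 ms alerting and orienting benefits and
120 ms trial noise; span capacities 3.8 + z (verbal) and 4.3 + z
(spatial) with lapse 0.08 − 0.03z; card-sorting perseveration 0.45 −
0.15z and attention-slip 0.15 − 0.05z; per-phase card-sort accuracies
0.95/0.86/0.78 (+z slopes).  Rating composites are generated at subscale
level and summed by the scorer.  Because capacity thresholds are
deterministic, scored span totals rise in steps with z while lapse varies
continuously; the monotonicity test uses grid averages.

The closed-form attenuation of a latent effect d on a scored outcome
follows from the link: e.g. for the flanker conflict score, slope β = 25
ms/z and per-subject sampling noise σ² = noise²·(1/72 + 1/72) give an
observed standardized effect β·d / √(β² + σ²) ≈ 0.62·d at defaults; the
simulation test agrees within Monte-Carlo error.

## Task engines

All engines are deterministic given (policy, seed) and emit per-trial
records.

* **Stop task (anticipated response).** Schedule: 10 practice go, 20
  mixed practice (15 go / 5 stop), then 3 × 60 test trials at 25% stop,
  shuffled within block.  A planned lift time drawn from the go
  distribution races the stop process finishing at SSD + true SSRT; the
  stop process wins ties (a race needs a deterministic tie rule).  The
  staircase starts at 500 ms and moves +50 ms after a successful stop,
  −50 ms after a failed one, clamped to [300, 700] ms.  Published descriptions of this
  staircase are ambiguous about direction; the implementation follows the
  standard stop-task tracking convention, and treats the
  [300, 700] range as hard clamps rather than an initial sampling range
  (flagged: treating them as an initial sampling range only is a defensible alternative).
* **Flanker/attention task.** 24 practice trials (12 target-only, 12
  flankered — the emulated protocol does not fix the practice composition; the
  12/12 split is a documented choice, and practice never enters scoring),
  then 3 × 48 experimental trials fully crossed over 2 congruency × 4 cue
  cells.  RT = base + cost·incongruent − alerting·(any informative cue) −
  orienting·(spatial cue) + N(0, noise), with omissions and rare fast
  guesses (< 100 ms) to exercise the exclusion rule.
* **Digit span (backwards).** Spans ascend from 2; exactly two trials per
  span, advance on ≥ 1 correct, end when both fail.  Only the discontinue rule is fixed by the emulated protocol;
  two-trials-per-span is the minimal schedule consistent with it.
* **Block tapping.** Advance requires two *consecutive* correct at a
  length; two failures at a length discontinue.  A 1-of-2 length is
  re-presented once (hard cap 3 trials/length; pass with 2 of 3).  Spans
  run 2–9.
* **Card sorting (48 trials).** Criterion cycles colour → shape → number,
  switching unannounced after 6 consecutive correct.  The default
  responder is a feedback learner: keep the dimension after positive
  feedback; after negative feedback perseverate with probability p or
  step deterministically to the next dimension; attention slips
  substitute a random other dimension.  Omniscient and fixed-dimension
  strategies exist as probes for ceiling and perseveration traces.
* **Dimensional card sort.** 6 pre-switch + 6 post-switch trials;
  the 12-trial cued advanced phase is administered only on ≥ 5/6
  post-switch.  The emulated protocol fixes only the post-switch and advanced pass
  criteria; the pre-switch criterion is set to ≥ 5/6 by analogy (flagged).
* **Training session.** Six exercises in seeded random order, 3 minutes
  each (trial budget default 40 per block — the protocol specifies minutes, not
  counts).  Stop: ±50 ms SSD staircase; flanker: level ±1 on 8-correct /
  2-error streaks (level sets distractor count and target-onset delay);
  spans: length ±1 on 2-correct / 2-error streaks; switching: one- vs
  two-dimension rules with reversal events at levels ≥ 4; matching: the
  dimension-change run-length ladder 12 → 8 → 6 → 4.  Difficulty persists
  across sessions.

## Scoring

Integration-method SSRT uses the empirical inverse-CDF (type-1) quantile
(SSRT moves a few ms across quantile conventions, so the convention is
pinned); omitted go trials take the maximum observed lift time before
quantiling; a stop-respond rate of exactly 0 or 1 is flagged degenerate
and fails QC.  Go "accuracy" has no standard definition
for an anticipated-response task; a lift within ±150 ms of the 800 ms target counts as
accurate (window configurable).  The "RTs < 400 ms" exclusion is applied
to the mean go RT (a per-trial reading is a flagged alternative).  A perseverative sorting error is one matching the
*immediately preceding* criterion (the alternative "any earlier
criterion" reading is flagged); proportions divide by all 48 trials and
partition exactly.  The wellbeing total sums the four deficit subscales,
excluding prosocial.  Rating-scale T-score conversion is out of scope
(proprietary norm tables); all composites are raw.

## Trial operations

Power uses the two-sided two-sample t-test under the noncentral t
(statsmodels), solving for the smallest integer per-group n meeting the
target; solve-then-evaluate round-trips are tested.  Blocked 1:1
randomisation permutes within blocks of 10 (final partial block balanced
within 1); the allocation record is blinded until an explicit, logged
unblind call.  The balance check quantifies an informally stated rule as
|standardized age difference| < 0.2 and gender proportion difference
< 0.15, both configurable, with rejection sampling over fresh sub-seeds.

Missingness defaults emulate the study conditions: stop task 34/45/56%
across occasions (software corruption), caregiver EF rating 27/32/38%
(response rates), others ≤ 15%, all MCAR; a MAR hook tilts rates by a
logistic term in one covariate but is off by default.  The MCAR screen
regresses each measure's missingness indicator on the covariates
(logistic likelihood-ratio test) and combines per-measure p-values by
Fisher's method — no specific test is prescribed, so this documented choice stands in; its null calibration is tested.  Imputation is
fully-conditional-specification chained equations via statsmodels
`MICEData` (predictive-mean-matching flavour, Gaussian perturbation),
auxiliaries joined by participant, executed once by default (m ≥ 1
supported with Rubin pooling).  With small tables each conditional model
caps its predictor set at the max(3, n/5) most-correlated columns to keep
designs full rank.  Observed cells are never altered.

## Latent change score models

Two-occasion, two-indicator Near/Far factors; first indicator anchors
(loading 1, intercept 0), second loading and intercept free but invariant
over time and groups; indicator residual SDs shared across occasions.
The occasion-2 factor loads 1 on baseline and 1 on the latent change.
Structural part and the four-model ladder are as in the README; the
arm-specific parameters are parameterised as control baseline +
intervention offset, so each freed parameter's arm difference is explicit
("=" rows in rendered tables correspond to absent offsets).  The
two-indicator form is primary; a single-indicator option exists for the
measurement-error-free specification sometimes preferred at small n.

Priors: N(0, 1) on standardized loadings, intercepts and regressions;
half-normal(1) on every SD, sampled on the log scale with the Jacobian
term; N(0, 1) on the Fisher-z of the baseline factor correlation.  All
indicators are standardized against the pooled baseline mean/SD (applied
to both occasions, preserving change); covariates are standardized.

Sampling: the exact multigroup Gaussian likelihood is evaluated from
sufficient statistics (per-group cross-moments), vectorised over the
ensemble; emcee's affine-invariant stretch move, walkers = max(2·dim+6,
48), initialised from a Laplace approximation at the MAP (numeric
Hessian, covariance inflated 1.3×).  The Laplace initialisation matters:
a tight initial ball leaves the ensemble measurably under-dispersed
within practical chain lengths, and the differential-evolution moves were
rejected after producing posterior SDs at 0.81× a known Gaussian target's
truth despite clean scale-reduction diagnostics.  Defaults: 600 burn-in +
2400 kept steps, thinned ×10.  Convergence is summarised by a split-chain
scale-reduction statistic over walker groups and a crude autocorrelation
ESS; because walkers within one ensemble are correlated, this statistic
reads ≈ 1.015 even at exact equilibrium (verified on a known Gaussian),
so the non-convergence flag triggers at 1.03 rather than the 1.01 a
multi-chain sampler would use — the value itself is always reported, and
fits are never silently accepted.

PPP uses a deviance discrepancy (−2 log-likelihood of the data vs a
same-size replicate at each posterior draw).  A likelihood-ratio-vs-
saturated discrepancy was rejected because evaluating it on a replicate
not used for fitting inflates the statistic by the fitted-parameter
degrees of freedom, pushing the p-value toward 1 even for the generating
model; the deviance form is centred near 0.5 there (tested).  LOOIC comes
from pointwise log-likelihoods on ~200 posterior draws via arviz PSIS;
LOO differences are reported on the deviance scale (negative favours the
first fit) with SE from pointwise contributions.  The Bayes factor is a
Savage–Dickey density ratio on the Near change-intercept arm offset under
Model 2 (posterior density at zero by Gaussian KDE, floored at 1e−12;
prior N(0, 1)); the BF ≥ 3 decision rule is exposed as evidence flags.

ICC is the one-way random-effects ANOVA estimator with the unbalanced
cluster-size correction, floored at 0 and NaN for zero-variance input.
FWER control defaults to step-down Holm (a documented choice; no method is prescribed).
Thorndike's Case 2: r_c = r·u / √(1 − r² + r²u²), clipped inside (−1, 1).
The adherence correlation reports df = complete pairs − 2 (the standard
Pearson convention; the printed-report style "r(df)" follows from it).

## Pipeline and reproducibility

`run_pipeline` derives every stage seed from the master seed via
`SeedSequence.spawn` (cohort, allocation, battery, missingness,
imputation, sessions, analysis), logs them to an audit file, and is
byte-identical across runs with the same seed.  The cohort is generated
effect-free, arms come from the blinded block randomiser, and the
configured effect is then injected — so allocation and effect assignment
cannot drift apart.

## Problem sizes

Replicate studies in the test suite are scaled-down versions of the full
designs: SSRT recovery uses 500 administrations; staircase convergence
200; null type-I calibration 120 replicate mini-trials (15/arm);
parameter-recovery coverage pools 8 fits at 200/group over ladder rungs 1
and 2; LOO misspecification and pipeline Bayes-factor checks use 3–4
replicates.  These sizes are the package's chosen defaults for its own
continuous verification; the same machinery runs at larger sizes by
changing the counts.

## Limitations

* Task behaviour is generated directly from latent abilities through
  low-dimensional parametric links; real children show strategy shifts,
  fatigue, RT skew (no ex-Gaussian modelling) and item-level effects
  (no IRT for questionnaires).  Passing tests show the *pipeline* is
  correct and calibrated under these assumptions, not that the links
  describe real children.
* Practice/retest effects are a single configurable per-occasion drift.
* The LCS likelihood is multivariate normal; ordinal indicators (the 0–12
  advanced-sort count, error proportions) are treated as continuous, as
  is standard at these sample sizes but approximate at the extremes.
* The Bayes factor depends on the N(0, 1) offset prior; Savage–Dickey
  with a KDE floor caps expressible evidence near 4×10¹¹.
* Only the MCAR mechanism is exercised by default; the MAR hook exists
  but imputation validity under strong MNAR is out of scope.
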