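# Methods

## Scope and design

`actimood` reproduces a three-group observational comparison — probable
bipolar disorder (BD), probable unipolar mania/hypomania (UM), and controls —
on objective (wrist-accelerometer) and subjective (questionnaire) rest,
activity and mental-health measures. Because the motivating cohort data are
access-restricted, the package pairs the analysis code with a synthetic
cohort generator whose defaults encode the study conditions the analysis
assumes. The generator is first-class, tested code: every downstream claim
the test suite makes is a claim about the pipeline's behaviour on data whose
ground truth is known.

## Phenotyping algorithm

Labels are assigned from self-report items only:

* **Exclusions first.** Any of: severe neurological diagnosis, brain
  cancer/injury, personality disorder, psychosis, schizophrenia, sleep
  apnoea/insomnia, or shift work as the main job → `EXCLUDED`, regardless of
  other answers.
* **Mania core**: "hyper" **or** "irritable" for two days or more, **and**
  manic symptom count ≥ 3. The two instrument dialects offer 4 (touchscreen)
  and 8 (online) candidate symptoms; the absolute threshold of 3 is applied
  to both, since the rule is stated once for both instruments.
* **Depression**: depressed mood **or** anhedonia for 2+ weeks, **and**
  depressive symptom count ≥ 5, **and** a professional was consulted.
* BD = mania ∧ depression; UM = mania ∧ ¬depression; control = ¬mania ∧
  ¬depression; `DEPRESSION_ONLY` = depression without mania. Depression-only
  participants are *not* folded into controls — doing so would contaminate
  the comparison group with mood-disordered participants — and are not
  analysed.
* The online follow-up instrument, when completed, takes precedence over the
  touchscreen instrument (it is the more detailed assessment).
* **Missing data rule** (a design choice, since none is stated for the
  original): a missing gate or branch item that leaves a criterion
  undecidable yields `UNCLASSIFIABLE`, which is excluded from analysis and
  counted in the run manifest — never silently treated as control.

## Accelerometer signal model (synthetic cohorts)

Days run noon-to-noon so each day contains exactly one main sleep period.
For participant-day *d*, a phase shift δ_d ~ N(0, jitter_sd) moves the whole
profile; awake epochs are

    mesor + amplitude · max(0, cos(2π(t − peak − δ_d)/24)) + |N(0, noise_sd)|

in milli-g (noise half-normal, keeping magnitudes nonnegative). The sleep
window (onset ~ N(onset_mean, onset_sd) + δ_d; length ~ N(len_mean, len_sd),
clipped to the day) has half-normal residual activity |N(0, sleep_noise_sd)|
except per-epoch Bernoulli wake bouts at daytime magnitude, so expected
detected efficiency is ≈ 1 − wake_prob. Daytime fragmentation bouts
(Bernoulli starts at rate·Δt, geometric lengths with mean 15 min) drop
activity to the sleep level, raising IV. Non-wear is an i.i.d. epoch mask
(default 0).

Defaults: 60 s epochs (any divisor of an hour accepted), 7 days, and
group-conditional parameters chosen once to produce the qualitative ordering
the comparison is about — UM highest daytime activity and shortest sleep
(mesor 38 mg, window 8.6 h), BD lowest activity, longest sleep, most
fragmentation and most wake bouts (mesor 31 mg, window 10.6 h, wake
probability 0.22), controls in between (mesor 34 mg, window 9.5 h, wake
probability 0.18). What the generator deliberately does **not** emulate:
device calibration and temperature drift, triaxial raw output, naps,
autocorrelated wake/sleep bout structure, weekday/weekend differences, or
informative non-wear. Passing tests therefore demonstrate correctness of the
*pipeline* under a plausible signal model, not validity of the detector on
real accelerometry.

Questionnaire response probabilities are group-conditional constants set
from the emulated study's printed descriptive tables (demographics,
wellbeing and sleep-item prevalences, neuroticism means), and the diagnostic
criterion items are drawn so that a participant's generated answers satisfy
their own group's criteria with probability ≥ 0.99 — making phenotyping
recovery of generator truth a meaningful end-to-end check. Injected binary
exposures with named log odds ratios (relative to control) support
parameter-recovery tests of the model stack.

## Circadian metrics

* **AA**: mean of worn-epoch magnitudes over the full record.
* **M10/L5/RA**: within each noon-to-noon day, sliding windows at epoch
  resolution (no wrap-around across the day boundary; a 10 h and a 5 h
  window). Daily RA = (M10 − L5)/(M10 + L5); the record value averages daily
  RAs (averaging the daily M10/L5 first is available behind a flag —
  `StatsParams.ra_per_day=False` — the two differ only through day-to-day
  covariance of M10 and L5). Days with under 20 h of wear, or with
  M10 + L5 = 0, are dropped with a log entry.
* **IS/IV** are computed on clock-aligned hourly means (bin width follows
  the classic nonparametric convention; hours under 50% worn are missing,
  days under 20 complete hours are dropped). Zero-variance signals make both
  ratios undefined: the functions return NaN, never 0.

Useful calibration points (all enforced by tests): IS = 1 for a perfectly
repeated day; E[IS] ≈ 1/d for i.i.d. noise over d days; IV = 4 for hourly
alternation; IV = 2(1 − cos(π/12)) ≈ 0.0681 for an hourly-sampled 24 h
cosine; IV → 2 for white noise.

## Sleep detection

The original study's detector operates on raw triaxial angles, which cannot
be derived from magnitude-only epochs; this package uses a deliberately
simple threshold detector. Per noon-to-noon day with ≥ 20 h wear: smooth
with a centred 30-min rolling median, threshold θ = 10% of the participant's
typical daytime activity, and take the longest contiguous below-θ block of
≥ 3 h as the sleep window; epochs inside it are asleep iff their raw value
is below θ. The daytime reference is the 75th percentile of worn epochs
(not the median: sleep plus rest bouts can occupy over half the day, which
would collapse the median to the sleep level). All constants are exposed in
`SleepDetectorParams`. Duration = mean slept hours; efficiency = mean of
slept/window; categories short < 7 h, regular 7–9 h (endpoints inclusive,
"between 7 and 9"), long > 9 h. One window per day; naps are not scored,
matching an objective duration that excludes napping.

## Comparison statistics

* **Outcome orientation**: the first-named group of a pair is coded 1, so
  OR > 1 means the exposure is more likely in that group.
* **Covariates**: partly = age, sex, Townsend score, education, ethnicity
  (+ meteorological season of wear start — Dec–Feb winter, etc. — for
  objective exposures); fully = partly + BMI, smoking, alcohol, psychotropic
  medication. Wald 95% intervals.
* **Quintiles**: type-7 sample quantile boundaries on the pooled analysed
  sample, ties to the lower bin; RA, IS, AA and sleep efficiency are negated
  before binning (higher quintile = more negative outcome); IV is not.
  Quintile exposures enter the models as a single ordinal term (one OR per
  measure).
* **Category condensation**: chronotype → early / intermediate (both
  mid-levels) / late, reference intermediate; happiness items → happy /
  unhappy, reference happy; getting up → difficult / not difficult,
  reference not difficult; sleep duration reference regular; "do not know" /
  "prefer not to answer" are excluded as missing.
* **Sparse cells**: when a level-vs-reference 2×2 has any expected cell
  < 5, that level is reported from Fisher's exact test (conditional-MLE OR,
  two-sided exact p, unadjusted) instead of the logistic model.
* **Sleep discrepancy**: regular nappers excluded (subjective reports
  include naps; the objective estimate does not); objective duration rounded
  to the nearest hour (half up); diff = subjective − rounded objective, with
  diff > 0 an overestimation, 0 accurate, < 0 an underestimation. This sign
  convention is a deliberate choice: it is the orientation under which the
  published group pattern (the group with the largest positive mean
  difference also having the highest underestimation share) is internally
  consistent. The unrounded difference in minutes is carried alongside. The
  three-level outcome is modelled with multinomial logistic regression
  (accurate as reference, control as reference group).
* **FDR**: Benjamini–Hochberg applied to all fully-adjusted p-values across
  the three comparisons as one family (the family definition is not pinned
  down externally; pooling is the conservative single-family reading), with
  significance at adjusted p < 0.05.
* **Model hygiene**: non-convergence, perfect separation, or quasi-separation
  (|log OR| > 20, or a missing/huge standard error) produce flagged results
  (`converged=False`) that are excluded from the FDR family, never crashes;
  a singular Newton step is retried with BFGS before flagging.
* **Descriptives**: Pearson chi-squared (no continuity correction) with
  Cramér's V = √(χ²/(N·min(r−1, c−1))); one-way ANOVA reconstructed from
  group means/SDs/sizes with η² = SSB/SST — algebraically identical to the
  raw-data ANOVA, which allows recomputation from printed summary tables.

## Reproducibility and problem sizes

All randomness flows from one root seed: the cohort stream seeds
demographics, questionnaires and per-participant actigraphy sub-seeds, so
every stage is independently re-runnable; identical seeds give byte-identical
CSVs. The simulation-based checks use n = 20,000 participants (20 replicate
seeds) for odds-ratio recovery, 500 replicates for the type-I error rate,
and cohorts of 1,500–10,000 with 3–7 recorded days for pipeline-level
checks — sizes at which binomial sampling error is small relative to the
tolerances being asserted while a full run stays at desk scale.

## Known limitations

* The sleep detector is a simplified stand-in; its constants (θ fraction,
  3 h minimum block, 30 min smoothing, 20 h wear minimum) are config-exposed
  and logged, but its agreement with angle-based detectors on real data is
  untested here.
* Adjusted odds ratios from the motivating study are not reproducible
  without the restricted individual-level data; the package checks instead
  recompute descriptive test statistics from printed counts and verify the
  model stack by parameter recovery on synthetic data.
* The generator's wellbeing items are drawn independently given group;
  real item correlations (e.g., anxiety with neuroticism) are not emulated,
  so multivariable coefficients on synthetic data should not be interpreted
  as estimates of real-world associations.
* Wear-time and valid-night inclusion thresholds are package defaults
  (no external values exist); both are configurable and recorded per run.
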