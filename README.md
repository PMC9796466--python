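# actimood

Rest–activity rhythms and sleep in **probable unipolar mania (UM)**,
**probable bipolar disorder (BD)** and controls.

There is a long-standing question whether people who experience mania or
hypomania without depressive episodes (unipolar mania) are nosologically
distinct from people with bipolar disorder. One way to probe this is to
compare the two groups — and a no-mood-disorder control group — on objective,
accelerometer-derived rest/activity measures and on subjective sleep reports.
`actimood` implements that comparison pipeline end to end for epidemiologists
and computational psychiatrists, together with a synthetic cohort generator
so the whole analysis is runnable and testable without access-restricted
biobank data.

The pipeline has four stages:

1. **Phenotyping** — a rule-based algorithm assigns each participant a
   probable mood-disorder label from questionnaire items. Mania core:
   "hyper" or "irritable" for ≥ 2 days *and* ≥ 3 manic symptoms. Depression:
   ≥ 2 weeks of low mood or anhedonia, ≥ 5 depressive symptoms, and a health
   professional consulted. BD = mania + depression, UM = mania alone,
   control = neither; depression-only participants are set aside, and
   participants reporting neurological illness, psychosis, schizophrenia,
   personality disorder, brain cancer/injury, sleep apnoea/insomnia or
   shift work are excluded up front. A more detailed online instrument takes
   precedence over the baseline touchscreen instrument when both exist.
2. **Circadian metrics** — from epoch-level wrist acceleration (milli-g),
   the classic nonparametric variables:
   average acceleration *AA*; the most/least active window means *M10*, *L5*
   and relative amplitude *RA = (M10 − L5)/(M10 + L5)*; interdaily stability
   *IS = (N·Σₕ(x̄ₕ − x̄)²)/(24·Σᵢ(xᵢ − x̄)²)* on hourly means; and intradaily
   variability *IV = (N·Σ(xᵢ − xᵢ₋₁)²)/((N−1)·Σ(xᵢ − x̄)²)*.
3. **Sleep** — a threshold detector finds the main nightly sleep window
   (longest low-activity block per noon-to-noon day) and yields mean sleep
   duration, mean sleep efficiency, and short/regular/long categories
   (< 7 h / 7–9 h / > 9 h).
4. **Comparison statistics** — three pairwise logistic models
   (BD vs UM, UM vs control, BD vs control) per exposure, partly adjusted
   (age, sex, Townsend deprivation, education, ethnicity, + season of wear
   for objective exposures) and fully adjusted (+ BMI, smoking, alcohol,
   psychotropic medication); Fisher's exact test replaces the model when a
   2×2 cell is sparse; an objective-vs-subjective sleep-duration discrepancy
   is analysed with a multinomial model; Benjamini–Hochberg FDR (< 0.05) is
   applied to the fully adjusted family. Narrow-range continuous exposures
   enter as quintiles (RA, IS, AA and efficiency inverted so higher = worse).

## Worked example

```python
import actimood as am

cfg = am.RunConfig(cohort=am.CohortConfig(n_participants=2000), seed=7)
out = am.run_pipeline(cfg, "runs/demo")
print({k: out["manifest"][k] for k in
       ("n_input", "n_excluded", "n_depression_only", "n_BD", "n_UM", "n_control")})
```

prints the filtering ledger of the run:

```
{'n_input': 2000, 'n_excluded': 105, 'n_depression_only': 198,
 'n_BD': 118, 'n_UM': 36, 'n_control': 1543}
```

— 2000 simulated participants, of whom 105 met an exclusion criterion and
198 met depression criteria without mania (neither stratum is analysed),
leaving a BD : UM : control split similar to a population biobank. The run
directory contains `cohort.csv`, `metrics.csv` (AA/M10/L5/RA/IS/IV, sleep
duration and efficiency per participant), `results.csv` (one row per
exposure × comparison × adjustment with OR, 95% CI, p and FDR-adjusted p),
a readable `report.md`, and `manifest.json`. Under the default generator
parameters the UM group has the highest average acceleration and shortest
detected sleep, and the BD group the lowest activity, longest sleep and
lowest efficiency.

The same stages are available from the shell:

```bash
actimood simulate  --outdir runs/demo --seed 7
actimood phenotype --cohort runs/demo/cohort.csv --out runs/demo/phenotyped.csv
actimood run-all   --outdir runs/demo --seed 7
```

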