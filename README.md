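# rctaugment

Phase III trials exclude large parts of the real-world patient population —
in schizophrenia, typical criteria (illness duration < 3 years, suicide-
attempt history, alcohol or drug abuse, non-compliance, private-practice
management) leave only about a quarter of routine-care patients eligible.
That protects effect detection but hurts generalizability: models trained on
trial data must extrapolate to subgroups they never saw.

`rctaugment` implements *trial-population augmentation*: before running a
trial, simulate — on real-world cohort data, or on the package's synthetic
cohort with known ground truth — what happens when selected exclusion
criteria are relaxed and a controlled number of re-includable patients
replace randomly chosen trial patients at constant sample size. For every
augmentation scenario it quantifies both sides of the trade-off:

- **Effectiveness prediction.** A proportional-odds model of the 7-point
  CGI-S severity score at 3 months, `P(Y ≤ k | x) = logistic(c_k − x·β)`
  with 24 covariates and no interactions, is fitted on each (augmented)
  trial population and scored on the full cohort by bias
  `mean(ŷ − y)` and MSE `mean((ŷ − y)²)`, averaged over replicated random
  re-inclusions along an augmentation grid from 0 to "natural augmentation"
  (every re-includable patient admitted).
- **Trial results.** Virtual two-arm trials (250 patients per arm by
  default) are drawn from each source population — one arm sampled at
  random, the other selected by 1:1 greedy nearest-neighbor propensity
  matching — and bootstrapped to give the comparative-efficacy distribution
  `mean ΔCGI-S(D1) − mean ΔCGI-S(D2)`, its SD, and the trial's power
  (Welch-test rejection fraction at α = 0.05).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
import rctaugment as ra

cohort = ra.generate_cohort(ra.CohortGenParams(n_patients=8000, seed=303))
criteria = ra.default_criterion_set()

frac = criteria.eligible_mask(cohort.df).mean()
print(f"trial-eligible: {100*frac:.1f}% of the cohort")

pi = ra.pool_increase(cohort.treatment_group("D1"), criteria, ["illness_duration"])
print(f"re-admitting illness duration 1-3y grows the D1 pool by "
      f"{100*pi.point:.1f}% (95% CI {100*pi.lo:.1f}-{100*pi.hi:.1f}%)")

grp = cohort.treatment_group("D1")
rct, pool = ra.build_reinclusion_pool(
    cohort, criteria, ["illness_duration", "suicide_attempt"], "D1")
curve = ra.augmentation_curve(grp, rct, pool, n_points=6, n_resamples=20, seed=7)
print(curve[["n_replace", "mean_bias", "mean_mse"]].round(3).to_string(index=False))

trial = ra.bootstrap_trials(
    ra.apply_criteria(cohort, criteria), n_per_arm=250, n_replicates=200, seed=11)
print(f"RCT population: comparative efficacy {trial.mean:+.3f} "
      f"(SD {trial.sd:.3f}), power {trial.power:.2f}")
```

prints

```
trial-eligible: 25.5% of the cohort
re-admitting illness duration 1-3y grows the D1 pool by 32.8% (95% CI 29.5-36.3%)
 n_replace  mean_bias  mean_mse
         0      0.209     1.482
       154      0.014     1.405
       307      0.016     1.399
       461      0.018     1.395
       614      0.020     1.395
       768      0.015     1.396
RCT population: comparative efficacy -0.061 (SD 0.070), power 0.03
```

Reading it: a model trained on the bare trial population over-predicts the
full cohort's 3-month severity (bias +0.21 — the excluded subgroups respond
better than the trial population suggests) with MSE 1.48; re-including the
first ~20% of the naturally re-includable patients already removes most of
the bias and most of the achievable MSE improvement. The bare-trial virtual
RCT estimates a comparative efficacy of −0.06 points in favor of D1,
smaller in magnitude than the full cohort's comparative effectiveness, with
the tightest bootstrap SD of all source populations.

A full study (eligibility tables, all eight standard relaxation scenarios,
virtual trials) runs from one config:

```
rctaugment run --demo --outdir out/          # bundled desk-scale demo
rctaugment generate --n-patients 8000 --seed 1 --out cohort.csv
rctaugment virtual-trial --cohort cohort.csv --relax illness_duration --seed 2
```

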