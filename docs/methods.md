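# Methods

`rctaugment` simulates, before a phase III trial is run, what happens when a
trial's eligibility criteria are selectively relaxed so that typically
excluded real-world patients can be enrolled. Two quantities are traded off:

1. **External validity** — how well a model trained on (augmented) trial data
   predicts the drug's effectiveness in the full real-world population,
   scored by bias and mean squared error (MSE) of the predictions; and
2. **Internal validity** — the distribution of the trial's comparative-
   efficacy estimate (and hence its power), which widens as the enrolled
   population becomes more heterogeneous.

The implementation follows the method end to end on a synthetic real-world
cohort with known ground truth, so every stage is testable without access to
any proprietary registry data.

## The simulated cohort

`generate_cohort` draws an observational cohort of schizophrenia-like
outpatients starting one of two drugs, D1 or D2:

- **Covariates.** Illness duration is log-normal (log-mean 1.6, log-SD 1.0
  years), so the <1y, 1–3y and ≥3y strata are all populated (~5%, ~25%,
  ~69%). Suicide-attempt history, alcohol abuse, drug abuse, physician-rated
  non-compliance and private-practice management are Bernoulli flags with
  default prevalences 0.20/0.15/0.12/0.20/0.25, calibrated jointly so the six
  standard exclusion criteria leave ≈25% of patients trial-eligible — the
  regime reported for real-world schizophrenia cohorts, where more than three
  quarters of patients fail typical phase III criteria.
  `calibrate_eligible_fraction` can re-scale the flag prevalences by common-
  random-number bisection to hit any attainable eligible fraction (±0.03).
- **24 regression variables.** The six criterion covariates, an
  `early_course` indicator (illness < 3 years), baseline CGI-S, dose in
  defined-daily-dose equivalents, the treatment indicator, and a generic
  block of 8 standard-normal plus 6 Bernoulli(0.35) covariates — 24 in
  total, the number of variables the outcome and propensity regressions use.
- **Treatment assignment** is logistic in covariates (default: intercept 0.9
  for a ~72/28 D1/D2 split, with small |log-odds| ≤ 0.3 dependence on
  baseline severity, alcohol abuse, private practice and one generic
  covariate), so the cohort is confounded and propensity matching downstream
  is non-trivial.
- **Outcome.** The 3-month CGI-S (7-point ordinal) is drawn from a
  proportional-odds process: latent = x·β + s·ε with standard-logistic ε,
  cut into 7 categories by six fixed cutpoints. Baseline severity dominates
  (β = 0.9); D1 carries a small overall advantage (β = −0.08 on the latent
  scale). ΔCGI-S = 3-month − baseline; negative means improvement.

Two ground-truth knobs create the phenomena the method is designed to
quantify, and both are deliberately *outside* what the prediction model can
represent (it has no interactions and no heteroscedasticity):

- **Subgroup offsets and effect modification.** Each relaxable subgroup
  carries a net latent offset — early-course −0.65, suicide-attempt history
  −0.35 per attempt, private practice −0.65 (better outcomes), alcohol +0.65
  and drug abuse +0.55 (worse) — plus an extra −0.30 under D1 (favorable
  effect modification). These magnitudes are calibrated so that the
  structural part of the prediction error a trial-only model makes on the
  full cohort is 6–10% of total MSE, the relative size of the improvement
  the method is meant to resolve; with much smaller offsets the improvement
  drowns in single-fit Monte-Carlo noise at the package's default study size.
- **Subgroup noise inflation.** Patients in any relaxable subgroup get
  latent noise scale s = 1.5 instead of 1, making excluded subpopulations
  noisier: this is what drives the SD of comparative efficacy upward as
  populations are augmented toward the full cohort.

Cutpoints (−1.288, 1.164, 3.306, 5.254, 7.019, 8.877) were frozen once from
a 400k-draw quantile calibration so the marginal 3-month distribution has
mean ≈3.47 and the mean ΔCGI-S is ≈−0.80.

What the generator does **not** emulate: real joint covariate structure
(covariates are independent given the stated links), country/site effects,
visit schedules beyond baseline + 3 months, dropout/missingness, and any
drug-specific safety profile. Passing tests therefore demonstrate that the
*machinery* behaves as specified under a known data-generating process, not
that any particular real cohort shows effects of this size.

## Eligibility

The six standard exclusion criteria are data (`EligibilityCriterion`:
covariate, comparator, threshold): illness duration < 3 years; ≥1 past
suicide attempt; alcohol abuse; drug abuse; non-compliance; private-practice
management. Relaxed variants are *re-admission* rules: illness duration in
[1, 3) years; exactly one past attempt; alcohol, drug and private-practice
patients admitted outright. Non-compliance is never relaxed. Range
predicates are half-open [lo, hi) so a threshold value is never counted on
both sides.

Pool-increase statistics use the exact Clopper-Pearson binomial interval.
The binomial pair is k = newly eligible, n = base-eligible + newly eligible
(the share of re-included patients in the widened pool, which keeps k ≤ n);
the interval is then mapped through p ↦ p/(1−p) onto the increase-ratio
scale k/base. The convention behind the reference tables is not published;
this one is a documented choice. Mean ΔCGI-S intervals use the normal
approximation, matching the reference tables' footnote.

## Augmentation

Augmented trial populations are built by replacement at constant size:
`n_replace` patients are removed uniformly at random from the trial-eligible
population and replaced by the same number drawn uniformly from the
re-includable pool (patients meeting the relaxed criterion plus all
remaining criteria). *Natural augmentation* is the pool's share of the
naturally widened population — the level reached without enrollment
stratification. A grid of replacement counts from 0 to the natural count
(default 10 near-evenly spaced points) with `n_resamples` independently
seeded replicates per point supports the prediction curves. Both the removal
and the addition are re-randomized in every replicate; each (grid point,
replicate) has a deterministic child seed `(seed, i, j)` so any single
replicate is reproducible in isolation. At `n_replace = 0` the population is
the unaugmented trial population itself, so a single replicate is evaluated
there.

## Effectiveness prediction

A proportional-odds (ordinal logistic) model of the 3-month CGI-S on all 24
regression variables — no interactions — is fitted by maximum likelihood
(statsmodels `OrderedModel`, L-BFGS with a BFGS fallback; replicate fits are
warm-started from the unaugmented fit). The model structure is identical for
every training population; each population gets its own cutpoints and
coefficients. A covariate that is constant in a training set (an exclusion
flag absent from the trial population) is dropped from that fit with
coefficient zero — exactly the extrapolation a trial-only model is forced to
make. Cutpoints for categories unobserved in training give those categories
probability zero at prediction time; a fit on a single observed category is
a domain error.

The point prediction is the probability-weighted expected category (a real
number in [1, 7]); the modal category is available via `point="modal"`. The
predicted change is the predicted 3-month score minus the observed baseline.
Bias = mean(predicted − observed) and MSE = mean((predicted − observed)²)
are computed per patient over the full real-world cohort, on the 3-month
score scale by default (`on="delta_cgis"` switches to the change scale; a
distribution-level difference-of-means variant exists behind
`distribution_metrics`). Relative versions divide |bias| by the mean
observed score and MSE by the mean squared observed score, in percent.
Replicate fit failures are retried once with a fresh replacement draw; a
grid point fails if more than 5% of its replicates fail.

## Virtual trials

A virtual two-arm trial of 2 × `n_per_arm` (default 250) patients is built
from any source population by sampling the D2 arm uniformly at random and
selecting the D1 arm by 1:1 greedy nearest-neighbor matching on the logit of
the propensity score, without replacement and without caliper (a caliper in
logit-SD units can be added in config); D2 patients are processed in
descending score order, ties broken by lowest patient id for determinism.
The propensity model is a maximum-likelihood logistic regression of
treatment on the 23 non-treatment regression variables, fitted once per
source population; exactly collinear columns are dropped and flagged, and an
L2-regularized fallback (flagged) covers separation.

Comparative efficacy is the difference in mean ΔCGI-S, D1 arm minus D2 arm.
Sampling and matching are repeated `n_replicates` times (default 1000;
both stages re-randomized) to give the bootstrap distribution, its mean and
SD. Power is the fraction of replicates whose two-sample Welch test on the
per-arm changes rejects at two-sided α = 0.05; a closed-form normal
approximation from the replicate mean and SD is available as
`power_method="normal"`. Applying the identical sample-and-match procedure
to the full cohort yields the comparative-*effectiveness* benchmark.

## Study runner

`run_study` executes the whole pipeline from one config: generate or load
the cohort, emit the eligibility tables, run benchmark virtual trials on the
trial-eligible population and the full cohort, then for every scenario the
augmentation curve (per treatment group) and the virtual trials on the
naturally widened population. Scenario failures are recorded and the study
continues. All child seeds derive hierarchically from the global seed via
`SeedSequence`, and no output file contains wall-clock information, so a
rerun with the same config is byte-identical. The bundled demo config covers
the eight standard scenarios (five single relaxations, three pairs) at desk
scale: 6000 patients, 4 grid points × 3 resamples, 100 per arm × 25 trial
replicates.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script were chosen as the
smallest sizes at which each phenomenon is resolved well above Monte-Carlo
noise: cohorts of 8000 patients for headline checks (≈25% trial-eligible),
6-point augmentation grids with 50 resamples per point, and 250-per-arm
trials with 300 bootstrap replicates. Monte-Carlo standard errors are
reported alongside every replicate-averaged quantity (SE of an SD is
approximated by sd/√(2(B−1))). Optimizer non-convergence raises rather than
returning silently; degenerate inputs (single-category outcomes, empty
pools, single-treatment sources) are domain errors with explicit messages.

## Known limitations

- The prediction model and the generator share the proportional-odds family
  by design (to allow parameter-recovery tests); misspecification beyond
  dropped covariates, effect modification and noise inflation is not
  explored.
- Greedy nearest-neighbor matching is order-dependent; optimal matching and
  calipers are config extensions, not defaults.
- Power is estimated for the two-sided Welch test on raw arm means only; no
  covariate-adjusted analysis of the virtual trials is implemented.
- Effect sizes in the default ground truth are at the upper end of what
  observational severity scales show, chosen so that desk-scale runs resolve
  the phenomena; absolute bias/MSE/SD values are not comparable to any real
  cohort's.
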