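import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from rctaugment import (
    CohortGenParams,
    calibrate_eligible_fraction,
    default_criterion_set,
    default_outcome_model,
    generate_cohort,
    subgroup_masks,
)
from rctaugment.eligibility import CriterionSet, EligibilityCriterion
from rctaugment.exceptions import CalibrationError, ConfigurationError
from rctaugment.ordinal import OrdinalOutcomeModel


def test_generation_is_deterministic_under_fixed_seed():
    params = CohortGenParams(n_patients=1000, seed=42)
    a = generate_cohort(params)
    b = generate_cohort(params)
    assert a.to_csv_bytes() == b.to_csv_bytes()


def test_different_seeds_differ():
    a = generate_cohort(CohortGenParams(n_patients=500, seed=1))
    b = generate_cohort(CohortGenParams(n_patients=500, seed=2))
    assert a.to_csv_bytes() != b.to_csv_bytes()


def test_zero_prevalence_flag_never_set():
    params = CohortGenParams(n_patients=2000, seed=3)
    params.prevalences["alcohol_abuse"] = 0.0
    cohort = generate_cohort(params)
    assert cohort.df["alcohol_abuse"].sum() == 0


def test_empirical_prevalence_within_binomial_bounds():
    params = CohortGenParams(n_patients=20_000, seed=4)
    params.prevalences["alcohol_abuse"] = 0.25
    cohort = generate_cohort(params)
    p_hat = cohort.df["alcohol_abuse"].mean()
    sd = np.sqrt(0.25 * 0.75 / 20_000)
    assert abs(p_hat - 0.25) < 3 * sd


def test_score_invariants_hold(small_cohort):
    df = small_cohort.df
    assert df["cgis_baseline"].between(1, 7).all()
    assert df["cgis_3mo"].between(1, 7).all()
    assert (df["delta_cgis"] == df["cgis_3mo"] - df["cgis_baseline"]).all()
    assert (df["dose_dddeq"] >= 0).all()
    assert df["id"].is_unique


@pytest.mark.parametrize(
    "corrupt",
    [
        lambda p: p.prevalences.__setitem__("alcohol_abuse", 1.5),
        lambda p: setattr(p, "n_patients", 0),
        lambda p: setattr(p, "subgroup_noise_scale", -1.0),
        lambda p: setattr(
            p, "outcome_model", OrdinalOutcomeModel.__new__(OrdinalOutcomeModel)
        ),
    ],
)
def test_invalid_params_raise_configuration_error(corrupt):
    params = CohortGenParams(n_patients=100, seed=0)
    try:
        corrupt(params)
    except ConfigurationError:
        return  # rejected at construction already
    with pytest.raises((ConfigurationError, AttributeError)):
        generate_cohort(params)


def test_non_increasing_cutpoints_rejected():
    with pytest.raises(ConfigurationError, match="strictly increasing"):
        OrdinalOutcomeModel({"x": 1.0}, [0.0, 1.0, 0.5, 2.0, 3.0, 4.0])


def test_outcome_law_conformity_chi_square():
    """Sampled categories follow the proportional-odds probabilities
    (goodness of fit at alpha=0.01) in a pure-model configuration."""
    params = CohortGenParams(
        n_patients=30_000,
        seed=5,
        effect_modification={},
        subgroup_noise_scale=1.0,
    )
    cohort = generate_cohort(params)
    model = params.outcome_model
    probs = model.category_probs(cohort.df)
    # stratify by treatment x baseline score; expected counts are summed
    # per-patient probabilities within each cell
    df = cohort.df
    pvals = []
    for (_, _), idx in df.groupby(["treatment", "cgis_baseline"]).groups.items():
        if len(idx) < 500:
            continue
        sub = df.loc[idx]
        expected = probs[df.index.get_indexer(idx)].sum(axis=0)
        observed = np.array([(sub["cgis_3mo"] == k).sum() for k in range(1, 8)])
        keep = expected > 5
        stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pvals.append(1 - stats.chi2.cdf(stat, keep.sum() - 1))
    assert pvals, "no cells large enough"
    assert min(pvals) > 0.01 / len(pvals)  # Bonferroni across cells


def test_effect_modification_knob_shifts_subgroup_outcome():
    """A favorable latent shift for (subgroup, D1) strictly improves the mean
    outcome of subgroup patients on D1 relative to the zero-shift draw."""
    base = CohortGenParams(
        n_patients=15_000, seed=6, effect_modification={}, subgroup_noise_scale=1.0
    )
    shifted = replace(base, effect_modification={("alcohol_abuse", "D1"): -0.8})
    c0 = generate_cohort(base)
    c1 = generate_cohort(shifted)

    def subgroup_mean(c):
        df = c.df
        m = subgroup_masks(df)["alcohol_abuse"] & (df["treatment"] == "D1")
        return df.loc[m, "cgis_3mo"].mean()

    assert subgroup_mean(c1) < subgroup_mean(c0)


def test_calibrate_reaches_paper_like_eligibility_target(criteria):
    params = CohortGenParams(n_patients=4000, seed=7)
    out = calibrate_eligible_fraction(params, criteria, 0.23)
    cohort = generate_cohort(replace(out, n_patients=50_000))
    frac = criteria.eligible_mask(cohort.df).mean()
    assert 0.20 <= frac <= 0.26


def test_calibration_is_idempotent(criteria):
    params = CohortGenParams(n_patients=4000, seed=8)
    once = calibrate_eligible_fraction(params, criteria, 0.25)
    twice = calibrate_eligible_fraction(once, criteria, 0.25)
    for key in once.prevalences:
        assert twice.prevalences[key] == pytest.approx(once.prevalences[key], abs=0.05)


def test_calibration_noop_when_target_already_met():
    flag_only = CriterionSet(
        [EligibilityCriterion("alcohol_abuse", "alcohol_abuse", "is_true")]
    )
    params = CohortGenParams(n_patients=2000, seed=9)
    params.prevalences = {k: 0.0 for k in params.prevalences}
    out = calibrate_eligible_fraction(params, flag_only, 1.0)
    assert out.prevalences == params.prevalences


def test_calibration_unattainable_target_raises(criteria):
    params = CohortGenParams(n_patients=2000, seed=10)
    with pytest.raises(CalibrationError, match="unattainable"):
        # illness-duration distribution alone caps the eligible fraction
        calibrate_eligible_fraction(params, criteria, 0.95)


def test_csv_and_json_round_trip(tmp_path, small_cohort):
    from rctaugment import Cohort

    p_csv = tmp_path / "cohort.csv"
    small_cohort.to_csv(p_csv)
    back = Cohort.from_csv(p_csv)
    assert len(back) == len(small_cohort)
    assert list(back.df.columns) == list(small_cohort.df.columns)

    p_json = tmp_path / "cohort.json"
    small_cohort.to_json(p_json)
    back_j = Cohort.from_json(p_json)
    assert back_j.df["id"].tolist() == small_cohort.df["id"].tolist()
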