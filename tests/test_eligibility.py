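import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rctaugment import (
    CriterionSet,
    EligibilityCriterion,
    apply_criteria,
    clopper_pearson,
    mean_outcome_ci,
    newly_eligible_mask,
    pool_increase,
)

from conftest import make_patients


# ---------------------------------------------------------------- filtering


def test_base_filter_excludes_exactly_the_violators(ten_patient_cohort, criteria):
    eligible = apply_criteria(ten_patient_cohort, criteria)
    assert len(eligible) == 7


def test_fully_permissive_relaxation_returns_whole_cohort(ten_patient_cohort):
    base = [
        EligibilityCriterion("illness_duration", "illness_duration", "lt", 3.0),
        EligibilityCriterion("suicide_attempt", "suicide_attempts", "ge", 1),
        EligibilityCriterion("alcohol_abuse", "alcohol_abuse", "is_true"),
        EligibilityCriterion("drug_abuse", "drug_abuse", "is_true"),
        EligibilityCriterion("noncompliance", "compliant", "is_false"),
        EligibilityCriterion("private_practice", "private_practice", "is_true"),
    ]
    permissive = {
        c.name: EligibilityCriterion(f"{c.name}_ok", "illness_duration", "ge", 0.0)
        for c in base
    }
    cs = CriterionSet(base, permissive)
    out = apply_criteria(ten_patient_cohort, cs, relax=[c.name for c in base])
    assert len(out) == len(ten_patient_cohort)


def test_short_illness_patient_readmitted_only_under_relaxation(criteria):
    cohort = make_patients([{"illness_duration": 2.0}, {}])
    assert apply_criteria(cohort, criteria).df["id"].tolist() == ["F001"]
    relaxed = apply_criteria(cohort, criteria, relax=["illness_duration"])
    assert sorted(relaxed.df["id"]) == ["F000", "F001"]


def test_subyear_illness_patient_stays_excluded_under_relaxation(criteria):
    cohort = make_patients([{"illness_duration": 0.5}, {}])
    relaxed = apply_criteria(cohort, criteria, relax=["illness_duration"])
    assert relaxed.df["id"].tolist() == ["F001"]


def test_only_single_attempt_patients_readmitted(criteria):
    cohort = make_patients([{"suicide_attempts": 1}, {"suicide_attempts": 3}, {}])
    relaxed = apply_criteria(cohort, criteria, relax=["suicide_attempt"])
    assert sorted(relaxed.df["id"]) == ["F000", "F002"]


def test_noncompliance_has_no_relaxed_variant(criteria):
    with pytest.raises(KeyError, match="no relaxed variant"):
        criteria.eligible_mask(make_patients([{}]).df, relax=["noncompliance"])


def test_unknown_criterion_name_rejected(criteria, ten_patient_cohort):
    with pytest.raises(KeyError, match="unknown criterion"):
        apply_criteria(ten_patient_cohort, criteria, relax=["bmi"])


def test_filter_is_pure_and_preserves_records(ten_patient_cohort, criteria):
    before = ten_patient_cohort.df.copy()
    out = apply_criteria(ten_patient_cohort, criteria)
    assert ten_patient_cohort.df.equals(before)
    merged = out.df.merge(before, how="left", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_relaxation_monotonicity_on_generated_cohort(medium_cohort, criteria):
    df = medium_cohort.df
    base = criteria.eligible_mask(df)
    one = criteria.eligible_mask(df, ["illness_duration"])
    two = criteria.eligible_mask(df, ["illness_duration", "suicide_attempt"])
    assert not (base & ~one).any()
    assert not (one & ~two).any()
    assert base.sum() < one.sum() < two.sum()


def test_criterion_set_yaml_round_trip(tmp_path, criteria, medium_cohort):
    path = tmp_path / "criteria.yaml"
    criteria.to_yaml(path)
    back = CriterionSet.from_yaml(path)
    assert back.names == criteria.names
    np.testing.assert_array_equal(
        back.eligible_mask(medium_cohort.df, ["illness_duration"]),
        criteria.eligible_mask(medium_cohort.df, ["illness_duration"]),
    )


# ------------------------------------------------------------ Clopper-Pearson


def test_clopper_pearson_boundaries():
    assert clopper_pearson(0, 50).lo == 0.0
    assert clopper_pearson(50, 50).hi == 1.0
    ci = clopper_pearson(0, 50)
    assert ci.point == 0.0 and ci.hi < 0.1


def test_clopper_pearson_domain_errors():
    with pytest.raises(ValueError):
        clopper_pearson(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson(7, 5)


def test_clopper_pearson_matches_tail_inversion_spot_check():
    """k=20, n=100: endpoints invert the exact binomial tail sums."""
    ci = clopper_pearson(20, 100, 0.05)
    # P(X >= 20 | p = lo) = alpha/2 and P(X <= 20 | p = hi) = alpha/2
    assert stats.binom.sf(19, 100, ci.lo) == pytest.approx(0.025, abs=1e-9)
    assert stats.binom.cdf(20, 100, ci.hi) == pytest.approx(0.025, abs=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(n=st.integers(1, 200), data=st.data())
def test_clopper_pearson_nesting_and_ordering(n, data):
    k = data.draw(st.integers(0, n))
    wide = clopper_pearson(k, n, 0.01)
    narrow = clopper_pearson(k, n, 0.05)
    assert wide.lo <= narrow.lo <= narrow.point <= narrow.hi <= wide.hi
    assert 0.0 <= wide.lo and wide.hi <= 1.0


# ------------------------------------------------------------- pool increase


def test_pool_increase_hand_count(criteria):
    rows = [{} for _ in range(100)] + [{"illness_duration": 2.0} for _ in range(15)]
    cohort = make_patients(rows)
    ci = pool_increase(cohort, criteria, ["illness_duration"])
    assert ci.point == pytest.approx(0.15)
    assert ci.k == 15 and ci.n == 115
    assert ci.lo < 0.15 < ci.hi


def test_pool_increase_zero_when_nobody_readmitted(criteria):
    cohort = make_patients([{} for _ in range(20)])
    ci = pool_increase(cohort, criteria, ["alcohol_abuse"])
    assert ci.point == 0.0 and ci.lo == 0.0


def test_pool_increase_empty_base_pool_errors(criteria):
    cohort = make_patients([{"alcohol_abuse": 1, "drug_abuse": 1}])
    with pytest.raises(ZeroDivisionError):
        pool_increase(cohort, criteria, ["alcohol_abuse"])


def test_joint_relaxation_increase_dominates_singles(medium_cohort, criteria):
    single_a = pool_increase(medium_cohort, criteria, ["illness_duration"]).point
    single_b = pool_increase(medium_cohort, criteria, ["suicide_attempt"]).point
    joint = pool_increase(
        medium_cohort, criteria, ["illness_duration", "suicide_attempt"]
    ).point
    assert joint >= max(single_a, single_b)


def test_newly_eligible_disjoint_from_base(medium_cohort, criteria):
    df = medium_cohort.df
    new = newly_eligible_mask(df, criteria, ["private_practice"])
    assert not (new & criteria.eligible_mask(df)).any()


# ------------------------------------------------------------- mean outcome


def test_mean_outcome_ci_hand_computation():
    mean, lo, hi = mean_outcome_ci([-2, -1, 0, -1], alpha=0.05)
    # sd = sqrt(2/3); half-width = 1.959964 * sd / 2
    half = 1.959964 * np.sqrt(2 / 3) / 2
    assert mean == pytest.approx(-1.0)
    assert lo == pytest.approx(-1.0 - half, abs=1e-5)
    assert hi == pytest.approx(-1.0 + half, abs=1e-5)


def test_mean_outcome_ci_degenerate_and_antisymmetric():
    mean, lo, hi = mean_outcome_ci([2.0, 2.0, 2.0])
    assert (mean, lo, hi) == (2.0, 2.0, 2.0)
    m1, l1, h1 = mean_outcome_ci([-2, -1, 0, -1])
    m2, l2, h2 = mean_outcome_ci([2, 1, 0, 1])
    assert (m2, l2, h2) == pytest.approx((-m1, -h1, -l1))
    with pytest.raises(ValueError):
        mean_outcome_ci([1.0])
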