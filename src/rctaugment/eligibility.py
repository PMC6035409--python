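"""Eligibility criteria as data, applied to cohorts, plus the descriptive
statistics of the population-comparison table: pool-increase percentages with
exact (Clopper-Pearson) binomial confidence intervals and mean-outcome
normal-approximation intervals.

A criterion is an *exclusion* rule: a patient matching its predicate is
excluded. A relaxed variant is a *re-admission* rule: an otherwise-excluded
patient matching it becomes eligible again (e.g. base rule "illness duration
< 3 years excludes", relaxed rule "duration in [1, 3) is re-admitted").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import Cohort, TREATMENTS

_OPS = ("lt", "le", "eq", "ge", "gt", "in_range", "is_true", "is_false")


@dataclass(frozen=True)
class EligibilityCriterion:
    """Declarative predicate over one covariate.

    ``in_range`` uses a half-open interval ``[lo, hi)`` so that exact
    threshold values are never double-counted between base and relaxed rules.
    """

    name: str
    field: str
    op: str
    value: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")
        if self.op == "in_range":
            lo, hi = self.value  # type: ignore[misc]
            if not lo < hi:
                raise ValueError(f"in_range thresholds must be ordered, got {self.value}")

    def matches(self, df: pd.DataFrame) -> np.ndarray:
        if self.field not in df.columns:
            raise KeyError(f"criterion {self.name!r}: covariate {self.field!r} not in schema")
        x = df[self.field].to_numpy()
        if self.op == "lt":
            return x < self.value
        if self.op == "le":
            return x <= self.value
        if self.op == "eq":
            return x == self.value
        if self.op == "ge":
            return x >= self.value
        if self.op == "gt":
            return x > self.value
        if self.op == "in_range":
            lo, hi = self.value  # type: ignore[misc]
            return (x >= lo) & (x < hi)
        if self.op == "is_true":
            return x.astype(bool)
        return ~x.astype(bool)  # is_false

    def to_dict(self) -> dict:
        return {"name": self.name, "field": self.field, "op": self.op, "value": self.value}


@dataclass
class CriterionSet:
    """A base set of exclusion criteria plus optional re-admission rules."""

    criteria: list[EligibilityCriterion]
    relaxed: dict[str, EligibilityCriterion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValueError("duplicate criterion names")
        unknown = set(self.relaxed) - set(names)
        if unknown:
            raise ValueError(f"relaxed rules for unknown criteria: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.criteria]

    def check_relax(self, relax: Iterable[str]) -> tuple[str, ...]:
        relax = tuple(relax)
        for name in relax:
            if name not in self.names:
                raise KeyError(f"unknown criterion {name!r}")
            if name not in self.relaxed:
                raise KeyError(f"criterion {name!r} has no relaxed variant")
        return relax

    def eligible_mask(self, df: pd.DataFrame, relax: Iterable[str] = ()) -> np.ndarray:
        """Patients passing every criterion, with the named ones relaxed."""
        relax = self.check_relax(relax)
        ok = np.ones(len(df), dtype=bool)
        for crit in self.criteria:
            passes = ~crit.matches(df)
            if crit.name in relax:
                passes |= self.relaxed[crit.name].matches(df)
            ok &= passes
        return ok

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "criteria": [c.to_dict() for c in self.criteria],
            "relaxed": {k: v.to_dict() for k, v in self.relaxed.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CriterionSet":
        with open(path) as fh:
            payload = yaml.safe_load(fh)

        def mk(d: dict) -> EligibilityCriterion:
            value = d.get("value")
            if isinstance(value, list):
                value = tuple(value)
            return EligibilityCriterion(d["name"], d["field"], d["op"], value)

        return cls(
            [mk(d) for d in payload["criteria"]],
            {k: mk(d) for k, d in payload.get("relaxed", {}).items()},
        )


def default_criterion_set() -> CriterionSet:
    """The six standard schizophrenia phase III exclusion criteria.

    Relaxed variants re-admit: illness duration in [1, 3) years; exactly one
    past suicide attempt; any alcohol abuse; any drug abuse; private-practice
    patients. Non-compliance is never relaxed.
    """
    base = [
        EligibilityCriterion("illness_duration", "illness_duration", "lt", 3.0),
        EligibilityCriterion("suicide_attempt", "suicide_attempts", "ge", 1),
        EligibilityCriterion("alcohol_abuse", "alcohol_abuse", "is_true"),
        EligibilityCriterion("drug_abuse", "drug_abuse", "is_true"),
        EligibilityCriterion("noncompliance", "compliant", "is_false"),
        EligibilityCriterion("private_practice", "private_practice", "is_true"),
    ]
    relaxed = {
        "illness_duration": EligibilityCriterion(
            "illness_duration_1_3", "illness_duration", "in_range", (1.0, 3.0)
        ),
        "suicide_attempt": EligibilityCriterion("one_attempt", "suicide_attempts", "eq", 1),
        "alcohol_abuse": EligibilityCriterion("alcohol_ok", "alcohol_abuse", "is_true"),
        "drug_abuse": EligibilityCriterion("drug_ok", "drug_abuse", "is_true"),
        "private_practice": EligibilityCriterion(
            "private_ok", "private_practice", "is_true"
        ),
    }
    return CriterionSet(base, relaxed)


def apply_criteria(
    cohort: Cohort, criteria: CriterionSet, relax: Iterable[str] = ()
) -> Cohort:
    """Pure filter: the sub-cohort passing all (possibly relaxed) criteria."""
    mask = criteria.eligible_mask(cohort.df, relax)
    suffix = "+".join(relax) if relax else "base"
    return cohort.subset(mask, f"{cohort.name}/eligible[{suffix}]")


def newly_eligible_mask(
    df: pd.DataFrame, criteria: CriterionSet, relax: Iterable[str]
) -> np.ndarray:
    """Eligible under the relaxed rules but not under the base rules."""
    relax = criteria.check_relax(relax)
    if not relax:
        raise ValueError("no criterion relaxed")
    return criteria.eligible_mask(df, relax) & ~criteria.eligible_mask(df)


@dataclass(frozen=True)
class PrevalenceCI:
    """Point estimate with confidence bounds for a proportion or ratio."""

    point: float
    lo: float
    hi: float
    k: int
    n: int
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo <= self.point <= self.hi:
            raise ValueError(f"bounds not ordered: {self.lo}, {self.point}, {self.hi}")


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> PrevalenceCI:
    """Exact binomial confidence interval by beta-quantile inversion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return PrevalenceCI(k / n, lo, hi, k, n, alpha)


def pool_increase(
    cohort: Cohort,
    criteria: CriterionSet,
    relax: Iterable[str],
    alpha: float = 0.05,
) -> PrevalenceCI:
    """Relative growth of the trial-eligible pool under relaxation.

    With ``k`` newly eligible and ``b`` base-eligible patients, the point
    estimate is the increase ratio ``k / b``. The binomial interval is
    computed exactly for the *share* ``k / (b + k)`` of re-included patients
    in the widened pool, then mapped through ``p -> p / (1 - p)`` onto the
    ratio scale (a monotone transform, so coverage is preserved).
    """
    df = cohort.df
    base = int(criteria.eligible_mask(df).sum())
    if base == 0:
        raise ZeroDivisionError("no base-eligible patients: pool increase undefined")
    k = int(newly_eligible_mask(df, criteria, relax).sum())
    n = base + k
    share = clopper_pearson(k, n, alpha)

    def ratio(p: float) -> float:
        return np.inf if p >= 1.0 else p / (1.0 - p)

    return PrevalenceCI(k / base, ratio(share.lo), ratio(share.hi), k, n, alpha)


def mean_outcome_ci(
    values: Sequence[float] | np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Mean with a normal-approximation confidence interval."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    m = float(x.mean())
    half = float(stats.norm.ppf(1 - alpha / 2) * x.std(ddof=1) / np.sqrt(len(x)))
    return m, m - half, m + half


def eligibility_table(
    cohort: Cohort,
    criteria: CriterionSet,
    scenarios: Sequence[tuple[str, ...]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Population-comparison table: per treatment group, the real-world
    population, the base trial-eligible population and each relaxation
    scenario, with pool increase (%, exact CI) and mean change in CGI-S
    (normal CI)."""
    rows = []
    for treatment in TREATMENTS:
        grp = cohort.treatment_group(treatment)
        full_mean = mean_outcome_ci(grp.df["delta_cgis"], alpha)
        rows.append(
            {
                "treatment": treatment,
                "population": "real-world",
                "pool_increase_pct": np.nan,
                "pool_increase_lo_pct": np.nan,
                "pool_increase_hi_pct": np.nan,
                "n": len(grp),
                "mean_delta_cgis": full_mean[0],
                "mean_delta_lo": full_mean[1],
                "mean_delta_hi": full_mean[2],
            }
        )
        base = apply_criteria(grp, criteria)
        base_mean = mean_outcome_ci(base.df["delta_cgis"], alpha)
        rows.append(
            {
                "treatment": treatment,
                "population": "rct",
                "pool_increase_pct": 0.0,
                "pool_increase_lo_pct": np.nan,
                "pool_increase_hi_pct": np.nan,
                "n": len(base),
                "mean_delta_cgis": base_mean[0],
                "mean_delta_lo": base_mean[1],
                "mean_delta_hi": base_mean[2],
            }
        )
        for relax in scenarios:
            ci = pool_increase(grp, criteria, relax, alpha)
            new = grp.df.loc[newly_eligible_mask(grp.df, criteria, relax)]
            if len(new) >= 2:
                nm = mean_outcome_ci(new["delta_cgis"], alpha)
            else:
                nm = (np.nan, np.nan, np.nan)
            rows.append(
                {
                    "treatment": treatment,
                    "population": "augmented:" + "+".join(relax),
                    "pool_increase_pct": 100 * ci.point,
                    "pool_increase_lo_pct": 100 * ci.lo,
                    "pool_increase_hi_pct": 100 * ci.hi,
                    "n": ci.k,
                    "mean_delta_cgis": nm[0],
                    "mean_delta_lo": nm[1],
                    "mean_delta_hi": nm[2],
                }
            )
    return pd.DataFrame(rows)
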