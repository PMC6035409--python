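"""Synthetic real-world cohort generator.

Emulates an observational antipsychotic-outcomes cohort: two active drugs
(D1/D2) assigned non-randomly, a 7-point ordinal severity score (CGI-S) at
baseline and at 3 months, and the covariates that typical phase III
eligibility criteria act on (illness duration, suicide-attempt history,
alcohol/drug abuse, compliance, private-practice management, dose in defined
daily-dose equivalents), padded with a generic covariate block so the outcome
regression uses 24 variables.

The 3-month score is drawn from a known proportional-odds model on a latent
scale, so every downstream stage (eligibility filtering, augmentation,
model fitting, virtual trials) can be tested against ground truth.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ConfigurationError
from .ordinal import OrdinalOutcomeModel

TREATMENTS = ("D1", "D2")

#: Columns every patient table must carry.
CORE_COLUMNS = [
    "id",
    "treatment",
    "treat_d1",
    "cgis_baseline",
    "cgis_3mo",
    "delta_cgis",
    "illness_duration",
    "early_course",
    "suicide_attempts",
    "alcohol_abuse",
    "drug_abuse",
    "compliant",
    "private_practice",
    "dose_dddeq",
]

#: The 24 regression variables used by the outcome and propensity models
#: (criterion covariates plus the early-course indicator, baseline severity,
#: dose, treatment indicator and a generic block g01..g14).
GENERIC_CONTINUOUS = [f"g{i:02d}" for i in range(1, 9)]
GENERIC_BINARY = [f"g{i:02d}" for i in range(9, 15)]
REGRESSION_COVARIATES = [
    "illness_duration",
    "early_course",
    "suicide_attempts",
    "alcohol_abuse",
    "drug_abuse",
    "compliant",
    "private_practice",
    "cgis_baseline",
    "dose_dddeq",
    "treat_d1",
    *GENERIC_CONTINUOUS,
    *GENERIC_BINARY,
]

#: Covariates entering the propensity (treatment-assignment) model.
PROPENSITY_COVARIATES = [c for c in REGRESSION_COVARIATES if c != "treat_d1"]

#: Patient subgroups that effect modification and noise inflation act on.
SUBGROUP_NAMES = (
    "short_illness",
    "suicide_history",
    "alcohol_abuse",
    "drug_abuse",
    "private_practice",
    "noncompliance",
)


def subgroup_masks(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Boolean membership of each typically-excluded subgroup."""
    return {
        "short_illness": df["illness_duration"] < 3.0,
        "suicide_history": df["suicide_attempts"] > 0,
        "alcohol_abuse": df["alcohol_abuse"].astype(bool),
        "drug_abuse": df["drug_abuse"].astype(bool),
        "private_practice": df["private_practice"].astype(bool),
        "noncompliance": ~df["compliant"].astype(bool),
    }


@dataclass
class Cohort:
    """A named patient-level table (one row per patient)."""

    df: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ConfigurationError(f"cohort {self.name!r} is empty")
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"cohort {self.name!r} missing columns {missing}")
        if df["id"].duplicated().any():
            raise ConfigurationError(f"cohort {self.name!r} has duplicate patient ids")
        for col in ("cgis_baseline", "cgis_3mo"):
            v = df[col]
            if not ((v >= 1) & (v <= 7)).all():
                raise ConfigurationError(f"{col} outside 1..7")
        if not (df["delta_cgis"] == df["cgis_3mo"] - df["cgis_baseline"]).all():
            raise ConfigurationError("delta_cgis != cgis_3mo - cgis_baseline")
        if (df["dose_dddeq"] < 0).any():
            raise ConfigurationError("negative dose_dddeq")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask: pd.Series | np.ndarray, name: str | None = None) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask, dtype=bool)].copy(), name or self.name)

    def treatment_group(self, treatment: str) -> "Cohort":
        if treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {treatment!r}")
        return self.subset(self.df["treatment"] == treatment, f"{self.name}[{treatment}]")

    # -- serialization -----------------------------------------------------

    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode()

    @classmethod
    def from_csv(cls, path_or_buf, name: str = "cohort") -> "Cohort":
        return cls(pd.read_csv(path_or_buf), name)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "patients": self.df.to_dict(orient="records")},
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "Cohort":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(pd.DataFrame(payload["patients"]), payload.get("name", "cohort"))


def default_outcome_model() -> OrdinalOutcomeModel:
    """Ground-truth proportional-odds model for the 3-month CGI-S.

    Baseline severity dominates; D1 carries a small advantage (negative shift
    on the 3-month score). The typically-excluded subgroups carry net outcome
    offsets in the direction real-world cohorts show: early-course patients
    (illness < 3 years, a true step effect through the ``early_course``
    indicator), suicide-attempt history and private-practice patients respond
    better; alcohol and drug abusers respond worse; non-compliance worsens
    outcome through the ``compliant`` coefficient. Cutpoints were calibrated
    once by large-sample simulation so that the marginal 3-month distribution
    has mean ~3.5 and the mean change from baseline is ~-0.8 points.
    """
    coeffs = {
        "cgis_baseline": 0.9,
        "treat_d1": -0.08,
        "illness_duration": 0.005,
        "early_course": -0.65,
        "suicide_attempts": -0.35,
        "alcohol_abuse": 0.65,
        "drug_abuse": 0.55,
        "compliant": -0.45,
        "private_practice": -0.65,
        "dose_dddeq": 0.05,
        "g01": 0.2,
        "g02": -0.2,
        "g03": 0.15,
        "g09": 0.2,
    }
    for name in REGRESSION_COVARIATES:
        coeffs.setdefault(name, 0.0)
    cutpoints = [-1.288, 1.164, 3.306, 5.254, 7.019, 8.877]
    return OrdinalOutcomeModel(coeffs, cutpoints)


def default_effect_modification() -> dict[tuple[str, str], float]:
    """Favorable D1 response in the typically-excluded relaxable subgroups."""
    return {
        (s, "D1"): -0.30
        for s in (
            "short_illness",
            "suicide_history",
            "alcohol_abuse",
            "drug_abuse",
            "private_practice",
        )
    }


@dataclass
class CohortGenParams:
    """Configuration of the synthetic cohort generator.

    ``prevalences`` hold the marginal probability of each criterion-relevant
    flag (``suicide_attempt`` is the probability of any past attempt;
    ``noncompliance`` the probability of being flagged non-compliant). The
    defaults are calibrated so that the six standard exclusion criteria leave
    roughly a quarter of patients trial-eligible, the regime reported for
    real-world schizophrenia cohorts.

    ``effect_modification`` maps (subgroup, treatment) to an additive shift on
    the latent outcome scale; ``subgroup_noise_scale`` inflates the latent
    logistic noise of patients in any relaxable subgroup, making excluded
    subpopulations noisier than the trial-eligible core.
    """

    n_patients: int = 8000
    seed: int = 0
    prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "suicide_attempt": 0.20,
            "alcohol_abuse": 0.15,
            "drug_abuse": 0.12,
            "noncompliance": 0.20,
            "private_practice": 0.25,
        }
    )
    illness_duration_lognorm: tuple[float, float] = (1.6, 1.0)  # mean/sd of log-years
    cgis_baseline_probs: tuple[float, ...] = (0.01, 0.04, 0.20, 0.35, 0.25, 0.12, 0.03)
    dose_lognorm: tuple[float, float] = (0.0, 0.4)
    mean_attempts_given_any: float = 0.5  # extra attempts ~ Poisson(this) + 1
    generic_binary_p: float = 0.35
    treatment_assignment_coeffs: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.9,
            "cgis_baseline_centered": 0.15,
            "alcohol_abuse": -0.2,
            "private_practice": 0.3,
            "g01": 0.2,
        }
    )
    outcome_model: OrdinalOutcomeModel = field(default_factory=default_outcome_model)
    effect_modification: dict[tuple[str, str], float] = field(
        default_factory=default_effect_modification
    )
    subgroup_noise_scale: float = 1.5
    name: str = "synthetic-cohort"

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for key, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence {key}={p} outside [0, 1]")
        probs = np.asarray(self.cgis_baseline_probs)
        if len(probs) != 7 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cgis_baseline_probs must be 7 probabilities summing to 1")
        if not 0.0 <= self.generic_binary_p <= 1.0:
            raise ConfigurationError("generic_binary_p outside [0, 1]")
        if self.subgroup_noise_scale <= 0:
            raise ConfigurationError("subgroup_noise_scale must be positive")
        for (sub, treat) in self.effect_modification:
            if sub not in SUBGROUP_NAMES:
                raise ConfigurationError(f"unknown subgroup {sub!r} in effect_modification")
            if treat not in TREATMENTS:
                raise ConfigurationError(f"unknown treatment {treat!r} in effect_modification")
        # a ConfigurationError from non-increasing cutpoints surfaces here
        self.outcome_model.__post_init__()


def generate_cohort(params: CohortGenParams) -> Cohort:
    """Draw a fully synthetic cohort; reproducible for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    prev = params.prevalences

    mu_d, sd_d = params.illness_duration_lognorm
    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "illness_duration": rng.lognormal(mu_d, sd_d, n),
            "cgis_baseline": rng.choice(
                np.arange(1, 8), size=n, p=np.asarray(params.cgis_baseline_probs)
            ),
        }
    )
    df["early_course"] = (df["illness_duration"] < 3.0).astype(int)
    any_attempt = rng.random(n) < prev.get("suicide_attempt", 0.0)
    df["suicide_attempts"] = np.where(
        any_attempt, 1 + rng.poisson(params.mean_attempts_given_any, n), 0
    )
    df["alcohol_abuse"] = (rng.random(n) < prev.get("alcohol_abuse", 0.0)).astype(int)
    df["drug_abuse"] = (rng.random(n) < prev.get("drug_abuse", 0.0)).astype(int)
    df["compliant"] = (rng.random(n) >= prev.get("noncompliance", 0.0)).astype(int)
    df["private_practice"] = (rng.random(n) < prev.get("private_practice", 0.0)).astype(int)
    mu_dose, sd_dose = params.dose_lognorm
    df["dose_dddeq"] = rng.lognormal(mu_dose, sd_dose, n)
    for col in GENERIC_CONTINUOUS:
        df[col] = rng.normal(size=n)
    for col in GENERIC_BINARY:
        df[col] = (rng.random(n) < params.generic_binary_p).astype(int)

    # non-randomized treatment assignment (observational cohort)
    tc = params.treatment_assignment_coeffs
    lp = np.full(n, tc.get("intercept", 0.0))
    for name, b in tc.items():
        if name == "intercept" or b == 0.0:
            continue
        if name == "cgis_baseline_centered":
            lp = lp + b * (df["cgis_baseline"].to_numpy(float) - 4.0)
        else:
            lp = lp + b * df[name].to_numpy(float)
    d1 = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    df["treatment"] = np.where(d1, "D1", "D2")
    df["treat_d1"] = d1.astype(int)

    # ground-truth outcome process
    masks = subgroup_masks(df)
    shift = np.zeros(n)
    for (sub, treat), delta in params.effect_modification.items():
        shift = shift + np.where(
            masks[sub].to_numpy() & (df["treatment"] == treat).to_numpy(), delta, 0.0
        )
    in_relaxable = np.zeros(n, dtype=bool)
    for sub in SUBGROUP_NAMES:
        if sub == "noncompliance":
            continue
        in_relaxable |= masks[sub].to_numpy()
    noise_scale = np.where(in_relaxable, params.subgroup_noise_scale, 1.0)
    df["cgis_3mo"] = params.outcome_model.sample(
        df, rng, latent_shift=shift, noise_scale=noise_scale
    )
    df["delta_cgis"] = df["cgis_3mo"] - df["cgis_baseline"]
    return Cohort(df[CORE_COLUMNS + GENERIC_CONTINUOUS + GENERIC_BINARY], params.name)


def _scaled(params: CohortGenParams, m: float) -> CohortGenParams:
    return replace(params, prevalences={k: v * m for k, v in params.prevalences.items()})


def calibrate_eligible_fraction(
    params: CohortGenParams,
    criteria,
    target_fraction: float,
    n_sim: int = 50_000,
    tol: float = 0.03,
    max_iter: int = 40,
) -> CohortGenParams:
    """Rescale flag prevalences so the criteria leave ``target_fraction`` eligible.

    ``criteria`` is any object exposing ``eligible_mask(df) -> bool array``
    (a :class:`~rctaugment.eligibility.CriterionSet`). A common multiplier on
    all flag prevalences is found by bisection against cohorts of ``n_sim``
    patients drawn with common random numbers, so the measured fraction is
    monotone in the multiplier. Illness-duration parameters are left fixed.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise CalibrationError(f"target_fraction {target_fraction} outside (0, 1]")
    sim = replace(params, n_patients=n_sim, seed=params.seed)

    def fraction(m: float) -> float:
        cohort = generate_cohort(_scaled(sim, m))
        return float(np.asarray(criteria.eligible_mask(cohort.df)).mean())

    current = fraction(1.0)
    if abs(current - target_fraction) <= tol:
        return replace(params)

    max_prev = max(params.prevalences.values(), default=0.0)
    hi_mult = 1.0 / max_prev if max_prev > 0 else 1.0
    f_lo_mult = fraction(0.0)  # largest achievable fraction (all flags off)
    f_hi_mult = fraction(hi_mult)
    if target_fraction > f_lo_mult + tol or target_fraction < f_hi_mult - tol:
        raise CalibrationError(
            f"target {target_fraction:.3f} unattainable: achievable eligible "
            f"fraction range is [{f_hi_mult:.3f}, {f_lo_mult:.3f}] "
            "(illness-duration distribution is fixed)"
        )
    lo, hi = 0.0, hi_mult
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = fraction(mid)
        if abs(f - target_fraction) <= tol / 2:
            return _scaled(params, mid)
        if f > target_fraction:
            lo = mid  # fraction decreases as prevalences grow
        else:
            hi = mid
    achieved = fraction(0.5 * (lo + hi))
    if abs(achieved - target_fraction) <= tol:
        return _scaled(params, 0.5 * (lo + hi))
    raise CalibrationError(
        f"bisection did not reach target {target_fraction:.3f} "
        f"(best {achieved:.3f} after {max_iter} iterations)"
    )
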