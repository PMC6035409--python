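import numpy as np
import pandas as pd
import pytest

from rctaugment import Cohort, CohortGenParams, default_criterion_set, generate_cohort


def make_patients(rows: list[dict], name: str = "fixture") -> Cohort:
    """Build a small cohort by hand; unspecified fields get innocuous values
    that violate no eligibility criterion."""
    defaults = {
        "treatment": "D1",
        "cgis_baseline": 4,
        "cgis_3mo": 4,
        "illness_duration": 10.0,
        "suicide_attempts": 0,
        "alcohol_abuse": 0,
        "drug_abuse": 0,
        "compliant": 1,
        "private_practice": 0,
        "dose_dddeq": 1.0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"id": f"F{i:03d}", **defaults, **row}
        rec["treat_d1"] = int(rec["treatment"] == "D1")
        rec["early_course"] = int(rec["illness_duration"] < 3.0)
        rec["delta_cgis"] = rec["cgis_3mo"] - rec["cgis_baseline"]
        records.append(rec)
    return Cohort(pd.DataFrame(records), name)


@pytest.fixture(scope="session")
def criteria():
    return default_criterion_set()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-patient default cohort shared across fast tests."""
    return generate_cohort(CohortGenParams(n_patients=2000, seed=123))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 6000-patient default cohort for matching/curve tests."""
    return generate_cohort(CohortGenParams(n_patients=6000, seed=456))


@pytest.fixture
def ten_patient_cohort():
    """10 patients, exactly 3 violating one criterion each (7 eligible)."""
    return make_patients(
        [
            {},
            {"illness_duration": 2.0},  # excluded: short illness
            {},
            {"suicide_attempts": 1},  # excluded: past attempt
            {},
            {"alcohol_abuse": 1},  # excluded: alcohol abuse
            {},
            {},
            {},
            {},
        ]
    )


def simulate_ordinal(beta, cutpoints, n, seed, binary_cols=()):
    """Independent data simulator for proportional-odds recovery tests:
    draws covariates, forms the latent variable with standard logistic noise,
    and bins it by the cutpoints. Deliberately separate from the package's
    cohort generator."""
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(len(beta))]
    cols = {}
    for i, name in enumerate(names):
        if i in binary_cols:
            cols[name] = (rng.random(n) < 0.4).astype(float)
        else:
            cols[name] = rng.normal(size=n)
    df = pd.DataFrame(cols)
    eta = df.to_numpy() @ np.asarray(beta, dtype=float)
    latent = eta + rng.logistic(size=n)
    cutpoints = np.asarray(cutpoints, dtype=float)
    df["cgis_3mo"] = 1 + (latent[:, None] > cutpoints[None, :]).sum(axis=1)
    return df, names
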