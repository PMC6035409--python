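"""Virtual two-arm trials: sample one arm at random, build the other by
propensity-score matching, and bootstrap the comparative-efficacy
distribution (mean change under D1 minus mean change under D2), its
standard deviation, and the trial's statistical power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, PROPENSITY_COVARIATES
from .exceptions import FitError


@dataclass
class PropensityModel:
    """Logistic model of P(treatment = D1 | covariates)."""

    coefficients: dict[str, float]
    intercept: float
    dropped: tuple[str, ...] = ()
    method: str = "mle"  # "ridge" when the MLE was rank-deficient/separated

    def logit_score(self, df: pd.DataFrame) -> np.ndarray:
        z = np.full(len(df), self.intercept)
        for name, b in self.coefficients.items():
            if b != 0.0:
                z = z + b * df[name].to_numpy(dtype=float)
        return z

    def score(self, df: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logit_score(df)))


def fit_propensity(
    source: Cohort, covariate_names: Sequence[str] = PROPENSITY_COVARIATES
) -> PropensityModel:
    """ML logistic fit of treatment assignment on covariates.

    Exactly collinear columns are dropped (flagged in ``dropped``); if the
    MLE fails to converge or separates, an L2-regularized fit is used and
    flagged in ``method``.
    """
    df = source.df
    y = (df["treatment"] == "D1").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both treatments must be present to fit a propensity model")
    X = df[list(covariate_names)].astype(float)
    X = X.loc[:, X.nunique() > 1]
    dropped = [c for c in covariate_names if c not in X.columns]
    # drop exact linear duplicates via QR rank inspection
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    r = np.linalg.qr(arr, mode="r")
    keep_idx = []
    for j in range(1, arr.shape[1]):
        if abs(r[j, j]) > 1e-8 * max(1.0, abs(r[0, 0])):
            keep_idx.append(j - 1)
        else:
            dropped.append(X.columns[j - 1])
    X = X.iloc[:, keep_idx]

    method = "mle"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", False) or not np.all(
            np.isfinite(res.params)
        ):
            raise FitError("logistic MLE did not converge")
        params = np.asarray(res.params)
    except (FitError, np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        method = "ridge"
    coeffs = dict.fromkeys(covariate_names, 0.0)
    coeffs.update(dict(zip(X.columns, params[1:])))
    return PropensityModel(coeffs, float(params[0]), tuple(dropped), method)


@dataclass
class MatchedArms:
    """Explicitly paired arms of a virtual trial."""

    d1: pd.DataFrame
    d2: pd.DataFrame
    pairs: list[tuple[str, str]] = field(repr=False)  # (d2_id, d1_id)


def match_arms(
    source: Cohort,
    propensity: PropensityModel,
    n_per_arm: int,
    seed: int | Sequence[int] | np.random.Generator = 0,
) -> MatchedArms:
    """Draw the D2 arm uniformly, then build the D1 arm by greedy 1:1
    nearest-neighbor matching on the logit propensity score, without
    replacement and without caliper. D2 patients are processed in descending
    score order; ties go to the lowest patient id.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = source.df
    d2_all = df[df["treatment"] == "D2"].sort_values("id", kind="mergesort")
    d1_all = df[df["treatment"] == "D1"].sort_values("id", kind="mergesort")
    for arm, n_avail in (("D2", len(d2_all)), ("D1", len(d1_all))):
        if n_avail < n_per_arm:
            raise ValueError(f"arm {arm} has only {n_avail} patients, need {n_per_arm}")
    idx2 = rng.choice(len(d2_all), size=n_per_arm, replace=False)
    d2 = d2_all.iloc[np.sort(idx2)]
    z2 = propensity.logit_score(d2)
    z1 = propensity.logit_score(d1_all)
    order = np.argsort(-z2, kind="mergesort")
    available = np.ones(len(d1_all), dtype=bool)
    chosen = np.empty(n_per_arm, dtype=int)
    pairs: list[tuple[str, str]] = []
    d2_ids = d2["id"].to_numpy()
    d1_ids = d1_all["id"].to_numpy()
    for k in order:
        dist = np.abs(z1 - z2[k])
        dist[~available] = np.inf
        best = dist.min()
        # ties resolved by lowest patient id: candidates are in id order
        j = int(np.flatnonzero(dist == best)[0])
        available[j] = False
        chosen[k] = j
        pairs.append((str(d2_ids[k]), str(d1_ids[j])))
    d1 = d1_all.iloc[chosen]
    pairs.sort()
    return MatchedArms(d1.reset_index(drop=True), d2.reset_index(drop=True), pairs)


def comparative_efficacy(matched: MatchedArms) -> float:
    """Mean change in CGI-S in the D1 arm minus that in the D2 arm."""
    if len(matched.d1) == 0 or len(matched.d2) == 0:
        raise ValueError("empty arm")
    return float(
        matched.d1["delta_cgis"].mean() - matched.d2["delta_cgis"].mean()
    )


def standardized_mean_difference(
    x1: np.ndarray, x2: np.ndarray
) -> float:
    """Absolute standardized mean difference (balance diagnostic)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    pooled = np.sqrt(0.5 * (x1.var(ddof=1) + x2.var(ddof=1)))
    if pooled == 0:
        return 0.0
    return float(abs(x1.mean() - x2.mean()) / pooled)


def normal_approx_power(mean: float, sd: float, alpha: float = 0.05) -> float:
    """Closed-form power from the replicate mean and SD of the trial
    statistic: P(|Z| > z_{1-alpha/2}) with Z ~ N(mean/sd, 1)."""
    if sd <= 0:
        return float(abs(mean) > 0)
    z = stats.norm.ppf(1 - alpha / 2)
    mu = mean / sd
    return float(stats.norm.cdf(-z - mu) + stats.norm.cdf(-z + mu))


@dataclass
class VirtualTrialResult:
    """Bootstrap distribution of comparative efficacy for one population."""

    replicates: np.ndarray
    n_per_arm: int
    n_replicates: int
    power: float
    alpha: float
    power_method: str = "welch"
    source_name: str = ""

    def __post_init__(self) -> None:
        self.replicates = np.asarray(self.replicates, dtype=float)
        if len(self.replicates) != self.n_replicates:
            raise ValueError("replicate count mismatch")

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def sd(self) -> float:
        return float(self.replicates.std(ddof=1)) if len(self.replicates) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "source": self.source_name,
            "mean": self.mean,
            "sd": self.sd,
            "power": self.power,
            "n_per_arm": self.n_per_arm,
            "n_replicates": self.n_replicates,
            "alpha": self.alpha,
        }


def bootstrap_trials(
    source: Cohort,
    covariate_names: Sequence[str] = PROPENSITY_COVARIATES,
    n_per_arm: int = 250,
    n_replicates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    power_method: str = "welch",
) -> VirtualTrialResult:
    """Repeat sample-and-match ``n_replicates`` times on ``source``.

    Both stages (D2 sampling and D1 matching) are re-randomized in every
    replicate. Power is the fraction of replicates whose two-sample Welch
    test on per-arm changes rejects at two-sided ``alpha``
    (``power_method='normal'`` instead applies the closed-form
    normal approximation to the replicate mean and SD).
    """
    propensity = fit_propensity(source, covariate_names)
    values = np.empty(n_replicates)
    rejections = 0
    failures = 0
    for b in range(n_replicates):
        try:
            matched = match_arms(source, propensity, n_per_arm, seed=(seed, b))
            values[b] = comparative_efficacy(matched)
            t = stats.ttest_ind(
                matched.d1["delta_cgis"], matched.d2["delta_cgis"], equal_var=False
            )
            rejections += int(t.pvalue < alpha)
        except ValueError:
            failures += 1
            values[b] = np.nan
            if failures > max(1, 0.01 * n_replicates):
                raise FitError(
                    f"{failures} replicate failures in {b + 1} virtual trials"
                )
    values = values[~np.isnan(values)]
    n_ok = len(values)
    if power_method == "welch":
        power = rejections / n_ok if n_ok else float("nan")
    elif power_method == "normal":
        power = normal_approx_power(values.mean(), values.std(ddof=1), alpha)
    else:
        raise ValueError(f"unknown power_method {power_method!r}")
    return VirtualTrialResult(
        values, n_per_arm, n_ok, power, alpha, power_method, source.name
    )
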