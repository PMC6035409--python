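"""Proportional-odds (ordinal logistic) model shared by the cohort generator
and the prediction module.

The model places a latent variable ``y* = x·beta + s·eps`` with standard
logistic noise ``eps`` on the real line and maps it to an ordered category
through strictly increasing cutpoints ``c_1 < ... < c_{K-1}``::

    P(Y <= k | x) = logistic((c_k - x·beta) / s)

With noise scale ``s = 1`` this is the standard proportional-odds model; the
generator optionally inflates ``s`` for selected patients to emulate
subpopulations with noisier outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

DEFAULT_CATEGORIES: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class OrdinalOutcomeModel:
    """Proportional-odds model with named coefficients.

    Parameters
    ----------
    coefficients
        Map covariate name -> slope on the latent scale. Covariates are read
        from patient tables by column name.
    cutpoints
        Strictly increasing thresholds, one fewer than ``categories``.
    categories
        Ordered category values (default the 7-point CGI-S scale 1..7).
    fit_info
        Optional diagnostics attached by the fitting routine.
    """

    coefficients: Mapping[str, float]
    cutpoints: Sequence[float]
    categories: Sequence[int] = DEFAULT_CATEGORIES
    link: str = "logistic"
    fit_info: Any = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coefficients = dict(self.coefficients)
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        self.categories = np.asarray(self.categories)
        if self.link != "logistic":
            raise ConfigurationError(f"unsupported link {self.link!r}")
        if len(self.cutpoints) != len(self.categories) - 1:
            raise ConfigurationError(
                f"{len(self.categories)} categories require "
                f"{len(self.categories) - 1} cutpoints, got {len(self.cutpoints)}"
            )
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ConfigurationError(
                f"cutpoints must be strictly increasing, got {self.cutpoints}"
            )

    # -- latent scale ------------------------------------------------------

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        eta = np.zeros(len(data))
        for name, beta in self.coefficients.items():
            if beta == 0.0:
                continue
            if name not in data.columns:
                raise KeyError(f"covariate {name!r} missing from patient table")
            eta = eta + beta * data[name].to_numpy(dtype=float)
        return eta

    # -- category scale ----------------------------------------------------

    def cumulative_probs(
        self, data: pd.DataFrame, noise_scale: float | np.ndarray = 1.0
    ) -> np.ndarray:
        """P(Y <= k | x) for every non-terminal category, shape (n, K-1)."""
        eta = self.linear_predictor(data)
        s = np.broadcast_to(np.asarray(noise_scale, dtype=float), eta.shape)
        z = (self.cutpoints[None, :] - eta[:, None]) / s[:, None]
        return _logistic(z)

    def category_probs(
        self, data: pd.DataFrame, noise_scale: float | np.ndarray = 1.0
    ) -> np.ndarray:
        """Per-category probabilities, shape (n, K); rows sum to 1."""
        cum = self.cumulative_probs(data, noise_scale)
        full = np.concatenate(
            [np.zeros((len(cum), 1)), cum, np.ones((len(cum), 1))], axis=1
        )
        return np.diff(full, axis=1)

    def expected_score(
        self, data: pd.DataFrame, noise_scale: float | np.ndarray = 1.0
    ) -> np.ndarray:
        probs = self.category_probs(data, noise_scale)
        return probs @ np.asarray(self.categories, dtype=float)

    def sample(
        self,
        data: pd.DataFrame,
        rng: np.random.Generator,
        latent_shift: float | np.ndarray = 0.0,
        noise_scale: float | np.ndarray = 1.0,
    ) -> np.ndarray:
        """Draw outcome categories from the latent-variable process."""
        eta = self.linear_predictor(data) + latent_shift
        latent = eta + noise_scale * rng.logistic(size=len(data))
        return np.asarray(self.categories)[
            (latent[:, None] > self.cutpoints[None, :]).sum(axis=1)
        ]
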