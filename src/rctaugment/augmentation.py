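"""Population augmentation by replacement at constant trial size.

An augmented trial population is built from the base trial-eligible
population by removing ``n_replace`` randomly chosen patients and adding the
same number of randomly chosen re-included patients (patients meeting a
relaxed criterion plus all remaining exclusion criteria), so every scenario
keeps an identical target sample size. "Natural augmentation" is the level
reached when the whole re-includable pool is admitted without enrollment
stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .eligibility import CriterionSet, apply_criteria, newly_eligible_mask


@dataclass(frozen=True)
class AugmentationScenario:
    """One relaxation scenario: which criteria, how much replacement."""

    relaxed_names: tuple[str, ...]
    n_replace: int
    n_resamples: int = 500
    seed: int = 0
    treatment_group: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.relaxed_names):
            raise ValueError("at least one relaxed criterion required")
        if self.n_replace < 0:
            raise ValueError("n_replace must be >= 0")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


@dataclass
class AugmentedPopulation:
    """A constant-size replicate population plus its provenance."""

    cohort: Cohort
    n_replace: int
    replicate_index: int
    seed_key: tuple[int, ...]
    removed_ids: tuple[str, ...] = field(default=(), repr=False)
    added_ids: tuple[str, ...] = field(default=(), repr=False)


def natural_augmentation(
    cohort: Cohort,
    criteria: CriterionSet,
    relaxed_names: Iterable[str],
    treatment_group: str | None = None,
) -> tuple[int, float]:
    """Count and proportion of re-includable patients.

    Count: patients meeting the relaxed criterion (or criteria) and all
    remaining base criteria. Proportion: count / (base-eligible + count) —
    the share such patients would hold in the naturally widened pool.
    """
    grp = cohort.treatment_group(treatment_group) if treatment_group else cohort
    base = int(criteria.eligible_mask(grp.df).sum())
    count = int(newly_eligible_mask(grp.df, criteria, relaxed_names).sum())
    if count == 0:
        warnings.warn(
            f"relaxing {tuple(relaxed_names)} admits no new patients", stacklevel=2
        )
        return 0, 0.0
    return count, count / (base + count)


def augment_by_replacement(
    rct_pop: Cohort,
    reinclusion_pool: Cohort,
    n_replace: int,
    seed: int | Sequence[int] | np.random.Generator = 0,
    replicate_index: int = 0,
) -> AugmentedPopulation:
    """Replace ``n_replace`` uniformly chosen trial patients with uniformly
    chosen pool patients; the output size equals the input trial size."""
    if n_replace < 0 or n_replace > min(len(rct_pop), len(reinclusion_pool)):
        raise ValueError(
            f"n_replace={n_replace} outside 0..min(|rct|={len(rct_pop)}, "
            f"|pool|={len(reinclusion_pool)})"
        )
    overlap = set(rct_pop.df["id"]) & set(reinclusion_pool.df["id"])
    if overlap:
        raise ValueError(f"pools not disjoint: {sorted(overlap)[:5]} ...")
    if isinstance(seed, np.random.Generator):
        rng, seed_key = seed, (-1,)
    else:
        seed_key = (seed,) if isinstance(seed, int) else tuple(seed)
        rng = np.random.default_rng(seed_key)

    # sort by id before drawing so replicate identity depends only on ids
    base = rct_pop.df.sort_values("id", kind="mergesort").reset_index(drop=True)
    pool = reinclusion_pool.df.sort_values("id", kind="mergesort").reset_index(drop=True)
    removed = rng.choice(len(base), size=n_replace, replace=False)
    added = rng.choice(len(pool), size=n_replace, replace=False)
    kept = base.drop(index=removed)
    out = pd.concat([kept, pool.iloc[np.sort(added)]], ignore_index=True)
    cohort = Cohort(out, f"{rct_pop.name}+{n_replace}")
    return AugmentedPopulation(
        cohort,
        n_replace,
        replicate_index,
        seed_key,
        removed_ids=tuple(base["id"].iloc[np.sort(removed)]),
        added_ids=tuple(pool["id"].iloc[np.sort(added)]),
    )


def replacement_grid(natural_count: int, n_points: int = 10) -> np.ndarray:
    """Near-evenly spaced replacement counts from 0 to the natural count."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.unique(np.round(np.linspace(0, natural_count, n_points)).astype(int))
    return grid


def augmentation_grid(
    rct_pop: Cohort,
    reinclusion_pool: Cohort,
    n_points: int = 10,
    n_resamples: int = 500,
    seed: int = 0,
    natural_count: int | None = None,
) -> list[tuple[int, list[AugmentedPopulation]]]:
    """Replicated augmented populations over a grid of replacement counts.

    Each (grid point ``i``, replicate ``j``) draws from an independent child
    stream keyed ``(seed, i, j)``, so any single replicate can be rebuilt in
    isolation. Grid point 0 is the unaugmented trial population.
    """
    if natural_count is None:
        natural_count = len(reinclusion_pool)
    grid = replacement_grid(natural_count, n_points)
    out: list[tuple[int, list[AugmentedPopulation]]] = []
    for i, n_replace in enumerate(grid):
        reps = [
            augment_by_replacement(
                rct_pop, reinclusion_pool, int(n_replace), seed=(seed, i, j),
                replicate_index=j,
            )
            for j in range(n_resamples)
        ]
        out.append((int(n_replace), reps))
    return out


def grid_manifest(
    grid: list[tuple[int, list[AugmentedPopulation]]],
    rct_pop: Cohort,
    natural_count: int,
    seed: int,
) -> dict:
    """Per-scenario provenance record (JSON-serializable)."""
    return {
        "rct_population_size": len(rct_pop),
        "natural_augmentation_count": natural_count,
        "seed": seed,
        "grid": [
            {
                "n_replace": n_replace,
                "n_resamples": len(reps),
                "population_sizes": sorted({len(r.cohort) for r in reps}),
            }
            for n_replace, reps in grid
        ],
    }


def build_reinclusion_pool(
    cohort: Cohort,
    criteria: CriterionSet,
    relaxed_names: Iterable[str],
    treatment_group: str | None = None,
) -> tuple[Cohort, Cohort]:
    """(base trial population, re-includable pool) for a relaxation scenario."""
    grp = cohort.treatment_group(treatment_group) if treatment_group else cohort
    rct_pop = apply_criteria(grp, criteria)
    mask = newly_eligible_mask(grp.df, criteria, relaxed_names)
    pool = grp.subset(mask, f"{grp.name}/pool[{'+'.join(relaxed_names)}]")
    return rct_pop, pool
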