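"""End-to-end scenario runs and parameter-grid sweeps.

Four canonical scenarios combine two axes: whether female pre-adult
mortality tracks male mortality or stays fixed at 10%, and whether the
mating trait is held at a fixed proportion or a fixed number of surviving
adult males.

    Scenario 1 — equal mortality,     fixed proportion (1/3, 2/3, 8/9)
    Scenario 2 — female fixed at 10%, fixed proportion (1/3, 2/3, 8/9)
    Scenario 3 — equal mortality,     fixed number     (3, 6, 9)
    Scenario 4 — female fixed at 10%, fixed number     (3, 6, 9)

Each sweeps male mortality over {10%, 40%, 70%} from a cohort of 30
pre-adult males and 30 pre-adult females, yielding 9 grid points per
scenario.  ``run_sweep`` returns the sexual-selection table (one row per
grid point) and ``bounds_sweep`` the companion viability-selection bounds
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .allocation import allocate_mates
from .bounds import snat_bounds, standardize_snat
from .cohort import AdultPopulation, ScenarioConfig, sex_ratios
from .selection import (
    SelectionResult,
    selection_differential,
    standardized_differential,
)

__all__ = [
    "SweepSpec",
    "scenario_spec",
    "run_scenario",
    "run_sweep",
    "bounds_sweep",
    "SWEEP_COLUMNS",
    "BOUNDS_COLUMNS",
]

#: Exact column order of the sexual-selection sweep table.
SWEEP_COLUMNS = [
    "scenario_label",
    "male_mortality",
    "female_mortality",
    "trait_mode",
    "trait_level",
    "n_males_adult",
    "n_females_adult",
    "k_carriers",
    "ASR",
    "OSR",
    "s_sex",
    "s_sex_std",
]

#: Exact column order of the viability-selection bounds table.
BOUNDS_COLUMNS = [
    "scenario_label",
    "male_mortality",
    "trait_mode",
    "trait_level",
    "n0",
    "m",
    "k_surv",
    "t_min_feasible",
    "t_max_feasible",
    "s_nat_min",
    "s_nat_max",
    "s_nat_min_std",
    "s_nat_max_std",
]

MORTALITY_GRID = (0.1, 0.4, 0.7)
PROPORTION_GRID = (Fraction(1, 3), Fraction(2, 3), Fraction(8, 9))
NUMBER_GRID = (3, 6, 9)


@dataclass(frozen=True)
class SweepSpec:
    """A grid of model runs: mortality levels crossed with trait levels."""

    scenario_label: str
    male_mortalities: Sequence[float]
    trait_mode: str
    trait_levels: Sequence[Union[int, float, Fraction]]
    female_mortality: Optional[float] = None  # None -> track male mortality
    n_males0: int = 30
    n_females0: int = 30

    def configs(self) -> list[ScenarioConfig]:
        """One config per (mortality, trait level) pair, mortality-major."""
        out = []
        for mort in self.male_mortalities:
            fem = mort if self.female_mortality is None else self.female_mortality
            for level in self.trait_levels:
                out.append(
                    ScenarioConfig(
                        n_males0=self.n_males0,
                        n_females0=self.n_females0,
                        male_mortality=mort,
                        female_mortality=fem,
                        trait_mode=self.trait_mode,
                        trait_level=level,
                        scenario_label=self.scenario_label,
                    )
                )
        return out


_CANONICAL = {
    1: SweepSpec("scenario_1", MORTALITY_GRID, "fixed_proportion", PROPORTION_GRID),
    2: SweepSpec(
        "scenario_2", MORTALITY_GRID, "fixed_proportion", PROPORTION_GRID,
        female_mortality=0.1,
    ),
    3: SweepSpec("scenario_3", MORTALITY_GRID, "fixed_number", NUMBER_GRID),
    4: SweepSpec(
        "scenario_4", MORTALITY_GRID, "fixed_number", NUMBER_GRID,
        female_mortality=0.1,
    ),
}


def scenario_spec(scenario: int) -> SweepSpec:
    """The canonical :class:`SweepSpec` for scenario 1-4."""
    try:
        return _CANONICAL[scenario]
    except KeyError:
        raise ValueError(f"scenario must be 1-4, got {scenario!r}") from None


def run_scenario(
    config: ScenarioConfig,
    *,
    strict: bool = False,
    rng: Optional[np.random.Generator] = None,
    ddof: int = 0,
) -> SelectionResult:
    """One full model run: mortality -> trait -> mating -> selection.

    Deterministic unless ``rng`` is supplied, in which case the remainder
    mates are assigned to a random subset of carriers (the statistics are
    invariant to that choice).
    """
    adults = AdultPopulation.from_config(config, strict=strict)
    outcome = allocate_mates(adults.n_females_adult, adults.trait_vector, rng=rng)
    asr, osr = sex_ratios(adults.n_males_adult, adults.n_females_adult)
    k = adults.k_carriers
    s_sex = selection_differential(adults.trait_vector, outcome.mates, ddof=ddof)
    if k == adults.n_males_adult or k == 0:
        s_sex_std = math.nan  # zero trait variance
    else:
        s_sex_std = standardized_differential(
            adults.trait_vector, outcome.mates, ddof=ddof
        )
    return SelectionResult(
        s_sex=s_sex,
        s_sex_std=s_sex_std,
        asr=asr,
        osr=osr,
        n_males_adult=adults.n_males_adult,
        n_females_adult=adults.n_females_adult,
        k_carriers=k,
        mates=outcome.mates,
        config=config,
    )


def _level_repr(level) -> str:
    return str(level) if isinstance(level, Fraction) else str(level)


def run_sweep(
    spec: SweepSpec,
    *,
    strict: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Run every grid point of ``spec``; one row per point."""
    rows = []
    for config in spec.configs():
        res = run_scenario(config, strict=strict, rng=rng)
        rows.append(
            {
                "scenario_label": config.scenario_label,
                "male_mortality": config.male_mortality,
                "female_mortality": config.female_mortality,
                "trait_mode": config.trait_mode,
                "trait_level": _level_repr(config.trait_level),
                "n_males_adult": res.n_males_adult,
                "n_females_adult": res.n_females_adult,
                "k_carriers": res.k_carriers,
                "ASR": res.asr,
                "OSR": res.osr,
                "s_sex": res.s_sex,
                "s_sex_std": res.s_sex_std,
            }
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def bounds_sweep(
    spec: SweepSpec,
    *,
    strict: bool = False,
    std_population: str = "adult",
) -> pd.DataFrame:
    """Viability-selection bounds at every grid point of ``spec``.

    For each (mortality, trait level) point the surviving-carrier count is
    fixed by the scenario and the trait status of the males that died
    pre-adult is swept over its feasible range; the extremes of
    cov(x_male, W_surv) are reported raw and standardized.
    """
    import warnings as _warnings

    rows = []
    for config in spec.configs():
        adults = AdultPopulation.from_config(config, strict=strict)
        rng_ = snat_bounds(config.n_males0, adults.n_males_adult, adults.k_carriers)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            s_min_std = standardize_snat(
                rng_.s_nat_min, n0=rng_.n0, m=rng_.m, k_surv=rng_.k_surv,
                t=rng_.t_at_min, std_population=std_population,
            )
            s_max_std = standardize_snat(
                rng_.s_nat_max, n0=rng_.n0, m=rng_.m, k_surv=rng_.k_surv,
                t=rng_.t_at_max, std_population=std_population,
            )
        rows.append(
            {
                "scenario_label": config.scenario_label,
                "male_mortality": config.male_mortality,
                "trait_mode": config.trait_mode,
                "trait_level": _level_repr(config.trait_level),
                "n0": rng_.n0,
                "m": rng_.m,
                "k_surv": rng_.k_surv,
                "t_min_feasible": rng_.t_feasible[0],
                "t_max_feasible": rng_.t_feasible[1],
                "s_nat_min": rng_.s_nat_min,
                "s_nat_max": rng_.s_nat_max,
                "s_nat_min_std": s_min_std,
                "s_nat_max_std": s_max_std,
            }
        )
    return pd.DataFrame(rows, columns=BOUNDS_COLUMNS)
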