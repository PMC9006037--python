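"""Cohort construction: pre-adult survival, trait assignment and sex ratios.

The model follows a single cohort of pre-adult males and females through a
pre-adult stage with sex-specific mortality.  Survivors mature into the
adult mating pool.  A binary mate-acquisition trait (``x_male`` in {0, 1})
is then fixed among surviving males, either as a *proportion* of survivors
or as an absolute *number* of carriers.  Everything downstream — mate
allocation, selection differentials, sex ratios — is computed from the
resulting :class:`AdultPopulation`.

The model is fully deterministic: survival is a deterministic thinning
(``round(n0 * (1 - mortality))``), and trait carriers are placed at the
first ``k`` indices.  Carrier placement is irrelevant — every statistic in
the package is invariant to permutations of the trait vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Union

import numpy as np

__all__ = [
    "TRAIT_MODES",
    "NonIntegralCountError",
    "ScenarioConfig",
    "AdultPopulation",
    "apply_mortality",
    "assign_trait",
    "sex_ratios",
]

#: Valid trait-assignment modes: a fixed proportion of surviving males
#: carries the trait, or a fixed absolute number does.
TRAIT_MODES = ("fixed_proportion", "fixed_number")

#: Tolerance used by strict mode to decide whether an expected count is an
#: integer.  The canonical parameter grid (cohorts of 30; mortalities
#: 10/40/70%; proportions 1/3, 2/3, 8/9) is always exactly integral, so on
#: that grid rounding never fires.
INTEGRALITY_TOL = 1e-9


class NonIntegralCountError(ValueError):
    """Raised in strict mode when a survivor/carrier count is not integral."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_mortality(n0: int, mortality: float, *, strict: bool = False) -> int:
    """Number of individuals surviving the pre-adult stage.

    Parameters
    ----------
    n0
        Initial (pre-adult) cohort size; positive integer.
    mortality
        Fraction of the cohort dying before maturation, in [0, 1].
    strict
        If True, raise :class:`NonIntegralCountError` when
        ``n0 * (1 - mortality)`` is not an integer (to within 1e-9)
        instead of rounding.

    Returns
    -------
    int
        ``round(n0 * (1 - mortality))``, halves away from zero.
    """
    if int(n0) != n0 or n0 < 1:
        raise ValueError(f"n0 must be a positive integer, got {n0!r}")
    if not 0.0 <= mortality <= 1.0:
        raise ValueError(f"mortality must lie in [0, 1], got {mortality!r}")
    expected = n0 * (1.0 - float(mortality))
    survivors = _round_half_away(expected)
    if strict and abs(expected - survivors) > INTEGRALITY_TOL:
        raise NonIntegralCountError(
            f"survivor count {expected} for n0={n0}, mortality={mortality} "
            "is not integral (strict mode)"
        )
    return survivors


def assign_trait(
    n_adult: int,
    mode: str,
    level: Union[int, float, Fraction],
    *,
    strict: bool = False,
) -> np.ndarray:
    """Binary mating-trait vector over surviving adult males.

    Carriers (value 1) occupy the first ``k`` positions; ordering never
    affects any downstream statistic.

    Parameters
    ----------
    n_adult
        Number of surviving adult males.
    mode
        ``"fixed_proportion"`` — ``k = round(level * n_adult)`` males carry
        the trait; ``"fixed_number"`` — exactly ``level`` males carry it.
    level
        Proportion in [0, 1] (``fixed_proportion``) or a non-negative
        integer count no larger than ``n_adult`` (``fixed_number``).
    strict
        For ``fixed_proportion``: raise if ``level * n_adult`` is not
        integral instead of rounding.
    """
    if int(n_adult) != n_adult or n_adult < 0:
        raise ValueError(f"n_adult must be a non-negative integer, got {n_adult!r}")
    if mode not in TRAIT_MODES:
        raise ValueError(f"mode must be one of {TRAIT_MODES}, got {mode!r}")

    if mode == "fixed_proportion":
        if not 0 <= level <= 1:
            raise ValueError(f"proportion level must lie in [0, 1], got {level!r}")
        if isinstance(level, Fraction):
            expected = level * n_adult
            k = _round_half_away(float(expected))
            exact = expected.denominator == 1
        else:
            expected = float(level) * n_adult
            k = _round_half_away(expected)
            exact = abs(expected - k) <= INTEGRALITY_TOL
        if strict and not exact:
            raise NonIntegralCountError(
                f"carrier count {expected} for n_adult={n_adult}, "
                f"level={level} is not integral (strict mode)"
            )
    else:  # fixed_number
        if int(level) != level or level < 0:
            raise ValueError(f"carrier count must be a non-negative integer, got {level!r}")
        k = int(level)
        if k > n_adult:
            raise ValueError(
                f"carrier count {k} exceeds surviving males {n_adult}"
            )

    trait = np.zeros(n_adult, dtype=np.int64)
    trait[:k] = 1
    return trait


def sex_ratios(n_males_adult: int, n_females_adult: int) -> tuple[float, float]:
    """Adult sex ratio (ASR) and operational sex ratio (OSR).

    ASR is the ratio of surviving adult males to surviving adult females.
    OSR is the ratio of males to females prepared to mate; here every
    surviving adult male counts as prepared to mate (not only trait
    carriers) and every surviving female is receptive exactly once, so the
    two ratios coincide.  A trait-restricted OSR would be biased even under
    equal male and female survival, which would contradict the model's
    attribution of sex-ratio bias solely to sex-differential mortality;
    see the methods note.

    Raises
    ------
    ZeroDivisionError
        If no females survive (the ratio is undefined).
    """
    if n_females_adult < 1:
        raise ZeroDivisionError(
            "sex ratio undefined: no surviving adult females"
        )
    asr = n_males_adult / n_females_adult
    osr = asr  # all adult males are prepared to mate; females mate once
    return asr, osr


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one model run.

    Attributes
    ----------
    n_males0, n_females0
        Pre-adult cohort sizes (positive integers).
    male_mortality, female_mortality
        Sex-specific pre-adult mortality fractions in [0, 1].
    trait_mode
        ``"fixed_proportion"`` or ``"fixed_number"``.
    trait_level
        Proportion of surviving males carrying the trait
        (``fixed_proportion``) or the absolute carrier count
        (``fixed_number``).  :class:`fractions.Fraction` values are kept
        exact so strict mode can verify integrality without float slop.
    scenario_label
        Free-text label echoed into every output for provenance.
    """

    n_males0: int
    n_females0: int
    male_mortality: float
    female_mortality: float
    trait_mode: str
    trait_level: Union[int, float, Fraction]
    scenario_label: str = ""

    def __post_init__(self) -> None:
        for name in ("n_males0", "n_females0"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("male_mortality", "female_mortality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.trait_mode not in TRAIT_MODES:
            raise ValueError(
                f"trait_mode must be one of {TRAIT_MODES}, got {self.trait_mode!r}"
            )
        if self.trait_mode == "fixed_proportion":
            if not 0 <= self.trait_level <= 1:
                raise ValueError(
                    f"trait_level must lie in [0, 1] for fixed_proportion, "
                    f"got {self.trait_level!r}"
                )
        else:
            if int(self.trait_level) != self.trait_level or self.trait_level < 0:
                raise ValueError(
                    f"trait_level must be a non-negative integer for "
                    f"fixed_number, got {self.trait_level!r}"
                )

    def to_dict(self) -> dict:
        """Plain-JSON-serializable echo of the configuration."""
        return {
            "n_males0": self.n_males0,
            "n_females0": self.n_females0,
            "male_mortality": self.male_mortality,
            "female_mortality": self.female_mortality,
            "trait_mode": self.trait_mode,
            "trait_level": (
                (int(self.trait_level)
                 if self.trait_level.denominator == 1
                 else str(self.trait_level))
                if isinstance(self.trait_level, Fraction)
                else self.trait_level
            ),
            "scenario_label": self.scenario_label,
        }


@dataclass(frozen=True)
class AdultPopulation:
    """Post-mortality state: surviving counts and the male trait vector."""

    n_males_adult: int
    n_females_adult: int
    trait_vector: np.ndarray

    def __post_init__(self) -> None:
        tv = np.asarray(self.trait_vector, dtype=np.int64)
        object.__setattr__(self, "trait_vector", tv)
        if tv.ndim != 1 or len(tv) != self.n_males_adult:
            raise ValueError(
                f"trait_vector length {len(tv)} != n_males_adult "
                f"{self.n_males_adult}"
            )
        if not np.isin(tv, (0, 1)).all():
            raise ValueError("trait_vector entries must be 0 or 1")

    @property
    def k_carriers(self) -> int:
        """Number of surviving adult males carrying the mating trait."""
        return int(self.trait_vector.sum())

    @classmethod
    def from_config(cls, config: ScenarioConfig, *, strict: bool = False) -> "AdultPopulation":
        """Apply mortality to both sexes and assign the trait."""
        n_m = apply_mortality(config.n_males0, config.male_mortality, strict=strict)
        n_f = apply_mortality(config.n_females0, config.female_mortality, strict=strict)
        trait = assign_trait(n_m, config.trait_mode, config.trait_level, strict=strict)
        return cls(n_males_adult=n_m, n_females_adult=n_f, trait_vector=trait)
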