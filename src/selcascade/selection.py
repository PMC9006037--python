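"""Selection differentials on the binary mating trait.

The strength of selection on the trait is measured by the selection
differential: the covariance between individual trait values and relative
fitness,

    s_sex = cov(x_male, W_mat)      (sexual selection, adults only)
    s_nat = cov(x_male, W_surv)     (viability selection, whole cohort)

where W is the fitness component (mating success, or pre-adult survival)
divided by its population mean.  With population moments (divide by n) the
differential equals the within-generation change in the trait mean caused
by selection, which is why the population covariance is the default; a
sample-covariance option (``ddof=1``) is provided for comparison with
conventions that divide by n - 1.

Standardized differentials (selection intensities) divide by the trait's
population standard deviation, sqrt(p(1-p)) for a binary trait at
frequency p, making values comparable across traits.  When the trait has
zero variance (no carriers, or all males carriers) the standardized value
is undefined and is returned as NaN with a warning rather than raised, so
that grid sweeps run to completion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import ScenarioConfig

__all__ = [
    "SelectionResult",
    "relative_fitness",
    "selection_differential",
    "standardized_differential",
    "survival_selection_differential",
]


def relative_fitness(values) -> np.ndarray:
    """Fitness component divided by its mean; output mean is exactly 1.

    Raises
    ------
    ValueError
        If the mean is not positive (e.g. all-zero mating success), in
        which case relative fitness is undefined.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if (v < 0).any():
        raise ValueError("fitness components must be non-negative")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean fitness is zero: relative fitness undefined")
    return v / mean


def selection_differential(trait, fitness, *, ddof: int = 0) -> float:
    """Covariance of the trait with relative fitness.

    Parameters
    ----------
    trait
        {0, 1} trait values, one per individual.
    fitness
        Raw (absolute) fitness components, same length; normalized to
        relative fitness internally.
    ddof
        0 (default) for the population covariance — the differential then
        equals the selection-induced change in trait mean — or 1 for the
        sample convention.
    """
    x = np.asarray(trait, dtype=np.float64)
    w = np.asarray(fitness, dtype=np.float64)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("trait and fitness must be 1-D sequences of equal length")
    rel = relative_fitness(w)
    if len(x) == 1:
        return 0.0
    return float(np.cov(x, rel, ddof=ddof)[0, 1])


def _trait_sd(trait, ddof: int = 0) -> float:
    x = np.asarray(trait, dtype=np.float64)
    return float(x.std(ddof=ddof))


def standardized_differential(trait, fitness, *, ddof: int = 0) -> float:
    """Selection differential divided by the trait standard deviation.

    For a binary trait at carrier frequency p the divisor is
    sqrt(p(1-p)); the result is the selection intensity.  Returns NaN
    (with a warning) when the trait has zero variance — k = 0 or k = n —
    since no within-population selection on the trait is then observable.
    """
    s = selection_differential(trait, fitness, ddof=ddof)
    sd = _trait_sd(trait, ddof=ddof)
    if sd == 0.0:
        warnings.warn(
            "trait variance is zero: standardized differential undefined, "
            "returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return s / sd


def survival_selection_differential(trait, survival, *, ddof: int = 0) -> float:
    """Viability selection differential cov(trait, relative survival).

    Computed over the whole pre-adult cohort: ``trait`` marks carriers
    among pre-adults and ``survival`` is the {0, 1} indicator of surviving
    to adulthood.  Serves both the mating-trait bounds analysis and any
    generic binary survival trait.

    Raises
    ------
    ValueError
        If no individual survives (mean survival zero).
    """
    x = np.asarray(trait, dtype=np.float64)
    s = np.asarray(survival, dtype=np.float64)
    if x.shape != s.shape or x.ndim != 1:
        raise ValueError("trait and survival must be 1-D sequences of equal length")
    if s.sum() <= 0:
        raise ValueError("no survivors: relative survival undefined")
    return selection_differential(x, s, ddof=ddof)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one full model run.

    Attributes
    ----------
    s_sex
        Sexual selection differential cov(x_male, W_mat) over surviving
        adult males.
    s_sex_std
        ``s_sex`` divided by the adult trait SD sqrt(p(1-p)); NaN when
        the trait variance is zero.
    asr, osr
        Adult and operational sex ratios (males / females).
    n_males_adult, n_females_adult, k_carriers
        Surviving counts and number of trait carriers.
    mates
        Per-male integer mate counts (the realized numerator of W_mat).
    config
        Echo of the :class:`~selcascade.cohort.ScenarioConfig` that
        produced the run.
    """

    s_sex: float
    s_sex_std: float
    asr: float
    osr: float
    n_males_adult: int
    n_females_adult: int
    k_carriers: int
    mates: np.ndarray = field(repr=False)
    config: Optional[ScenarioConfig] = None

    def to_dict(self, *, verbose: bool = False) -> dict:
        """JSON-serializable summary; ``verbose`` adds per-male mates."""
        out = dict(self.config.to_dict()) if self.config is not None else {}
        out.update(
            n_males_adult=self.n_males_adult,
            n_females_adult=self.n_females_adult,
            k_carriers=self.k_carriers,
            ASR=self.asr,
            OSR=self.osr,
            s_sex=self.s_sex,
            s_sex_std=None if math.isnan(self.s_sex_std) else self.s_sex_std,
        )
        if verbose:
            out["mates"] = [int(m) for m in self.mates]
        return out
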