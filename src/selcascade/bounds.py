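"""Feasible range of viability selection on the mating trait.

A scenario fixes the number of surviving adult carriers ``k_surv`` but not
how many of the males that died before adulthood carried the trait.  With
``n0`` pre-adult males, ``m`` survivors and ``k_surv`` surviving carriers,
the number ``t`` of pre-adult carriers can be anything in

    t in [k_surv, k_surv + (n0 - m)]

(dead males may all lack the trait, all carry it, or anything between).
For each feasible t the viability selection differential on the trait,
cov(x_male, W_surv) over the n0 pre-adult males, has the closed form

    s_nat(t) = k_surv / m - t / n0,

which is linear and strictly decreasing in t, so the maximum is attained
when no dead male carried the trait (t = k_surv) and the minimum when all
dead males carried it (t = k_surv + n0 - m).  ``snat_bounds`` nevertheless
enumerates every feasible t — the enumeration and the closed form are
cross-checked against an explicit vector-covariance oracle in the tests.

Standardized bounds divide by a binary-trait standard deviation
sqrt(p(1-p)).  Two populations can define p: the surviving adult males
(p = k_surv / m, the frequency the scenario actually fixes; the default)
or the pre-adult cohort at the achieving t (p = t / n0).  Only the adult
convention preserves the qualitative ordering of the raw bounds across
the mortality grid; see the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NaturalSelectionRange",
    "snat_at",
    "snat_bounds",
    "trait_survival_vectors",
    "standardize_snat",
]


def _check_feasible(n0: int, m: int, k_surv: int) -> None:
    for name, v in (("n0", n0), ("m", m), ("k_surv", k_surv)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if m < 1:
        raise ValueError("m must be >= 1: at least one male must survive")
    if not k_surv <= m <= n0:
        raise ValueError(
            f"infeasible configuration: need k_surv <= m <= n0, "
            f"got k_surv={k_surv}, m={m}, n0={n0}"
        )


def snat_at(n0: int, m: int, k_surv: int, t: int) -> float:
    """Viability selection differential at pre-adult carrier count ``t``.

    Closed form ``k_surv/m - t/n0``: the population covariance of the
    trait with relative survival over all ``n0`` pre-adult males, given
    ``m`` survivors of whom ``k_surv`` carry the trait and ``t`` carriers
    among the pre-adults.
    """
    _check_feasible(n0, m, k_surv)
    t_lo, t_hi = k_surv, k_surv + (n0 - m)
    if int(t) != t or not t_lo <= t <= t_hi:
        raise ValueError(
            f"t={t!r} outside feasible interval [{t_lo}, {t_hi}] "
            f"for n0={n0}, m={m}, k_surv={k_surv}"
        )
    return k_surv / m - t / n0


def trait_survival_vectors(
    n0: int, m: int, k_surv: int, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit pre-adult (trait, survival) vectors realizing a configuration.

    Builds one concrete cohort: ``k_surv`` surviving carriers, then
    ``m - k_surv`` surviving non-carriers, then ``t - k_surv`` dead
    carriers, then dead non-carriers.  Used to cross-check the closed
    form of :func:`snat_at` against a direct vector covariance; any other
    arrangement gives identical statistics.
    """
    _check_feasible(n0, m, k_surv)
    if not k_surv <= t <= k_surv + (n0 - m):
        raise ValueError(f"t={t} infeasible for n0={n0}, m={m}, k_surv={k_surv}")
    trait = np.zeros(n0, dtype=np.int64)
    survival = np.zeros(n0, dtype=np.int64)
    survival[:m] = 1
    trait[:k_surv] = 1               # surviving carriers
    trait[m : m + (t - k_surv)] = 1  # dead carriers
    return trait, survival


@dataclass(frozen=True)
class NaturalSelectionRange:
    """Feasible extremes of viability selection on the mating trait.

    ``t_at_max``/``t_at_min`` are the pre-adult carrier counts achieving
    the extremes; ``t_feasible`` is the full integer interval
    ``[k_surv, k_surv + (n0 - m)]``.
    """

    s_nat_min: float
    s_nat_max: float
    t_at_min: int
    t_at_max: int
    t_feasible: tuple[int, int]
    n0: int
    m: int
    k_surv: int


def snat_bounds(n0: int, m: int, k_surv: int) -> NaturalSelectionRange:
    """Enumerate every feasible pre-adult carrier count and return extremes.

    The maximum is always at ``t = k_surv`` (no dead carriers) and the
    minimum at ``t = k_surv + (n0 - m)`` (every dead male a carrier),
    because :func:`snat_at` is strictly decreasing in t; the enumeration
    keeps the production path honest for any future non-linear variant.
    """
    _check_feasible(n0, m, k_surv)
    t_lo, t_hi = k_surv, k_surv + (n0 - m)
    values = {t: snat_at(n0, m, k_surv, t) for t in range(t_lo, t_hi + 1)}
    t_at_max = min(values, key=lambda t: (-values[t], t))
    t_at_min = max(values, key=lambda t: (-values[t], -t))
    return NaturalSelectionRange(
        s_nat_min=values[t_at_min],
        s_nat_max=values[t_at_max],
        t_at_min=t_at_min,
        t_at_max=t_at_max,
        t_feasible=(t_lo, t_hi),
        n0=n0,
        m=m,
        k_surv=k_surv,
    )


def standardize_snat(
    s_nat: float,
    *,
    n0: int,
    m: int,
    k_surv: int,
    t: int,
    std_population: str = "adult",
) -> float:
    """Divide a viability differential by a binary-trait SD sqrt(p(1-p)).

    ``std_population="adult"`` uses the adult carrier frequency
    ``p = k_surv / m`` (default; the frequency the scenario fixes);
    ``"preadult_at_t"`` uses ``p = t / n0``, the pre-adult frequency at
    the achieving carrier count.  Returns NaN with a warning when the
    chosen population has zero trait variance.
    """
    if std_population == "adult":
        p = k_surv / m
    elif std_population == "preadult_at_t":
        p = t / n0
    else:
        raise ValueError(
            f"std_population must be 'adult' or 'preadult_at_t', "
            f"got {std_population!r}"
        )
    sd = math.sqrt(p * (1.0 - p))
    if sd == 0.0:
        warnings.warn(
            "trait variance is zero in the standardization population: "
            "returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return s_nat / sd
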