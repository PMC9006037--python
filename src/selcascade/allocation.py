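"""Integer-equitable allocation of female mates among trait-bearing males.

Only males carrying the binary mating trait can acquire mates.  Females
each mate exactly once, males may mate multiply, and the ``F`` receptive
females are distributed as equitably as possible among the ``k`` carriers
while keeping every male's mate count an integer: each carrier receives
``F // k`` mates and the remainder ``F mod k`` carriers receive one extra.
The resulting integer constraint is the model's only source of variation
in mating success among carriers ("stochasticity" only in the sense that
*which* carriers get the extra mate is arbitrary — no reported statistic
depends on it, which the test suite asserts exhaustively).

Remainder mates go to the lowest-index carriers by default, making every
output bit-reproducible.  A seeded random assignment of the remainder is
available for demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["MatingOutcome", "allocate_mates"]


@dataclass(frozen=True)
class MatingOutcome:
    """Integer mate counts per surviving adult male.

    ``mates`` is the numerator of relative mating success W_mat: entry i is
    the number of females mated by male i.  Non-carriers always have 0;
    the counts sum to the number of surviving females; and among carriers
    the spread between the largest and smallest count is at most 1.
    """

    mates: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mates, dtype=np.int64)
        object.__setattr__(self, "mates", m)
        if m.ndim != 1 or (m < 0).any():
            raise ValueError("mates must be a 1-D sequence of non-negative integers")

    @property
    def n_females(self) -> int:
        """Total matings = number of females (each female mates once)."""
        return int(self.mates.sum())


def allocate_mates(
    n_females: int,
    trait_vector: np.ndarray,
    *,
    rng: Optional[np.random.Generator] = None,
) -> MatingOutcome:
    """Distribute ``n_females`` mates equitably among trait carriers.

    Parameters
    ----------
    n_females
        Number of receptive females (each mates exactly once); >= 1.
    trait_vector
        {0, 1} vector over surviving adult males; must contain at least
        one carrier, otherwise mean mating success is zero and relative
        fitness is undefined downstream.
    rng
        If given, the ``n_females mod k`` extra mates are assigned to a
        random subset of carriers instead of the lowest-index ones.  All
        selection statistics are invariant to this choice; the option
        exists purely to demonstrate that invariance.

    Returns
    -------
    MatingOutcome
        Carriers receive ``n_females // k`` or ``n_females // k + 1``
        mates; non-carriers receive 0.
    """
    trait = np.asarray(trait_vector, dtype=np.int64)
    if not np.isin(trait, (0, 1)).all():
        raise ValueError("trait_vector entries must be 0 or 1")
    carriers = np.flatnonzero(trait)
    k = len(carriers)
    if k == 0:
        raise ValueError("no trait carriers: no male can mate")
    if int(n_females) != n_females or n_females < 1:
        raise ValueError(f"n_females must be a positive integer, got {n_females!r}")

    base, remainder = divmod(int(n_females), k)
    mates = np.zeros(len(trait), dtype=np.int64)
    mates[carriers] = base
    if remainder:
        if rng is None:
            extra = carriers[:remainder]
        else:
            extra = rng.choice(carriers, size=remainder, replace=False)
        mates[extra] += 1
    return MatingOutcome(mates=mates)
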