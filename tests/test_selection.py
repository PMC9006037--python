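"""Selection differentials checked against exact brute-force covariance."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from selcascade import (
    allocate_mates,
    relative_fitness,
    selection_differential,
    standardized_differential,
    survival_selection_differential,
    trait_survival_vectors,
)

from _oracles import selection_differential_oracle


def _trait(n, k):
    t = np.zeros(n, dtype=int)
    t[:k] = 1
    return t


class TestRelativeFitness:
    def test_constant_input_maps_to_ones(self):
        assert relative_fitness([3, 3, 3]).tolist() == [1.0, 1.0, 1.0]

    def test_single_winner(self):
        assert relative_fitness([9, 0, 0]).tolist() == [3.0, 0.0, 0.0]

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            relative_fitness([0, 0, 0])

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=40).filter(lambda v: sum(v) > 0))
    def test_mean_is_always_one(self, values):
        assert relative_fitness(values).mean() == pytest.approx(1.0, abs=1e-12)


class TestSelectionDifferential:
    @pytest.mark.parametrize(
        "n, k, mates_per_carrier, expected",
        [
            # frozen from the exact-rational oracle; equals 1 - k/n
            (27, 3, 9, 8 / 9),   # 0.888...
            (9, 3, 9, 2 / 3),    # 27 females over 3 of 9 males: 0.666...
        ],
    )
    def test_full_monopolization_examples(self, n, k, mates_per_carrier, expected):
        trait = _trait(n, k)
        mates = trait * mates_per_carrier
        s = selection_differential(trait, mates)
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(float(selection_differential_oracle(trait, mates)), abs=1e-12)

    def test_zero_trait_variance_gives_zero(self):
        trait = _trait(9, 9)
        mates = allocate_mates(27, trait).mates
        assert selection_differential(trait, mates) == pytest.approx(0.0, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            selection_differential([1, 0], [1, 2, 3])

    def test_sample_covariance_option(self):
        trait = _trait(4, 2)
        mates = np.array([3, 1, 0, 0])
        pop = selection_differential(trait, mates, ddof=0)
        samp = selection_differential(trait, mates, ddof=1)
        assert samp == pytest.approx(pop * 4 / 3, abs=1e-12)

    @given(
        n=st.integers(2, 25),
        data=st.data(),
    )
    def test_permutation_invariance(self, n, data):
        """Statistics depend only on the trait/fitness pairing, not order."""
        k = data.draw(st.integers(1, n))
        n_f = data.draw(st.integers(1, 60))
        trait = _trait(n, k)
        mates = allocate_mates(n_f, trait).mates
        perm = data.draw(st.permutations(range(n)))
        perm = np.asarray(perm)
        s0 = selection_differential(trait, mates)
        s1 = selection_differential(trait[perm], mates[perm])
        assert s1 == pytest.approx(s0, abs=1e-12)


class TestStandardizedDifferential:
    def test_full_monopolization_intensity(self):
        # k = 3 of 27, all mates to carriers: (1 - p)/sqrt(p(1-p)) = sqrt(8)
        trait = _trait(27, 3)
        mates = trait * 9
        assert standardized_differential(trait, mates) == pytest.approx(
            math.sqrt(8), abs=1e-12
        )

    def test_constant_fitness_gives_zero(self):
        trait = _trait(10, 5)
        assert standardized_differential(trait, np.ones(10)) == pytest.approx(0.0, abs=1e-15)

    def test_zero_variance_returns_nan_with_warning(self):
        trait = _trait(9, 9)
        with pytest.warns(RuntimeWarning):
            out = standardized_differential(trait, allocate_mates(5, trait).mates)
        assert math.isnan(out)


class TestSurvivalSelectionDifferential:
    @pytest.mark.parametrize(
        "n0, m, k_surv, t, expected",
        [
            # frozen from the exact-rational oracle: k/m - t/n0
            (30, 27, 9, 12, -1 / 15),  # 3 dead carriers: -0.0667
            (30, 9, 9, 9, 0.7),        # survival == trait
        ],
    )
    def test_cohort_examples(self, n0, m, k_surv, t, expected):
        trait, survival = trait_survival_vectors(n0, m, k_surv, t)
        s = survival_selection_differential(trait, survival)
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(
            float(selection_differential_oracle(trait, survival)), abs=1e-12
        )

    def test_uniform_survival_gives_zero(self):
        assert survival_selection_differential(
            _trait(10, 4), np.ones(10)
        ) == pytest.approx(0.0, abs=1e-15)

    def test_no_survivors_rejected(self):
        with pytest.raises(ValueError):
            survival_selection_differential(_trait(10, 4), np.zeros(10))
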