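"""Cohort construction: survival counts, trait assignment, sex ratios."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from selcascade import (
    AdultPopulation,
    NonIntegralCountError,
    ScenarioConfig,
    apply_mortality,
    assign_trait,
    sex_ratios,
)


class TestApplyMortality:
    @pytest.mark.parametrize(
        "n0, mortality, survivors",
        [(30, 0.10, 27), (30, 0.40, 18), (30, 0.70, 9), (30, 0.0, 30), (30, 1.0, 0)],
    )
    def test_exact_grid(self, n0, mortality, survivors):
        assert apply_mortality(n0, mortality) == survivors
        assert apply_mortality(n0, mortality, strict=True) == survivors

    def test_rounding_half_away_from_zero(self):
        # 5 * 0.5 = 2.5 rounds away from zero to 3 (banker's would give 2)
        assert apply_mortality(5, 0.5) == 3

    def test_strict_mode_rejects_non_integral(self):
        with pytest.raises(NonIntegralCountError):
            apply_mortality(10, 0.25, strict=True)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_mortality_out_of_range(self, bad):
        with pytest.raises(ValueError):
            apply_mortality(30, bad)

    @given(
        n0=st.integers(1, 100),
        m1=st.floats(0, 1, allow_nan=False),
        m2=st.floats(0, 1, allow_nan=False),
    )
    def test_survivors_monotone_in_mortality(self, n0, m1, m2):
        lo, hi = sorted((m1, m2))
        assert apply_mortality(n0, hi) <= apply_mortality(n0, lo)


class TestAssignTrait:
    @pytest.mark.parametrize(
        "n_adult, mode, level, k",
        [
            (27, "fixed_proportion", 1 / 3, 9),
            (9, "fixed_proportion", 8 / 9, 8),
            (18, "fixed_proportion", Fraction(2, 3), 12),
            (18, "fixed_number", 6, 6),
            (9, "fixed_number", 9, 9),
            (10, "fixed_number", 0, 0),
        ],
    )
    def test_carrier_counts(self, n_adult, mode, level, k):
        trait = assign_trait(n_adult, mode, level)
        assert len(trait) == n_adult
        assert set(np.unique(trait)) <= {0, 1}
        assert trait.sum() == k

    def test_more_carriers_than_survivors_rejected(self):
        with pytest.raises(ValueError):
            assign_trait(9, "fixed_number", 12)

    def test_strict_mode_rejects_non_integral_proportion(self):
        with pytest.raises(NonIntegralCountError):
            assign_trait(10, "fixed_proportion", 1 / 3, strict=True)

    def test_strict_mode_accepts_float_thirds_on_grid(self):
        # 27 * (1/3 as a float) deviates from 9 only by float rounding
        assert assign_trait(27, "fixed_proportion", 1 / 3, strict=True).sum() == 9

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            assign_trait(10, "fixed_number", -1)


class TestSexRatios:
    @pytest.mark.parametrize("n", [27, 18, 9])
    def test_equal_survival_gives_unit_ratios(self, n):
        asr, osr = sex_ratios(n, n)
        assert asr == 1.0 and osr == 1.0

    def test_biased_survival(self):
        asr, osr = sex_ratios(9, 27)
        assert asr == pytest.approx(1 / 3)
        assert osr == asr

    def test_no_females_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            sex_ratios(10, 0)


class TestScenarioConfig:
    def test_grid_is_exactly_integral(self):
        """Every canonical grid point survives strict mode untouched."""
        for mort in (0.1, 0.4, 0.7):
            for level in (Fraction(1, 3), Fraction(2, 3), Fraction(8, 9)):
                cfg = ScenarioConfig(30, 30, mort, mort, "fixed_proportion", level)
                adults = AdultPopulation.from_config(cfg, strict=True)
                assert adults.n_males_adult == round(30 * (1 - mort))
                assert adults.k_carriers == level * adults.n_males_adult

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_males0=0),
            dict(male_mortality=1.2),
            dict(trait_mode="random"),
            dict(trait_mode="fixed_proportion", trait_level=1.5),
            dict(trait_mode="fixed_number", trait_level=2.5),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(
            n_males0=30, n_females0=30, male_mortality=0.1,
            female_mortality=0.1, trait_mode="fixed_number", trait_level=3,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            ScenarioConfig(**base)

    def test_trait_vector_length_checked(self):
        with pytest.raises(ValueError):
            AdultPopulation(5, 5, np.array([1, 0, 1]))
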