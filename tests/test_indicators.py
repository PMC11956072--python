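"""Indicator scoring: worked examples, invariants, vectorized equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dqqkit.indicators import (
    Respondent,
    all5,
    fgds,
    gdr,
    mddw,
    ncd_protect,
    ncd_risk,
    score_respondent,
    score_table,
    sweet_beverage,
    unhealthy_upf,
    zero_fruit_veg,
)
from dqqkit.taxonomy import FoodGroupVector, food_group_codes

ALL_CODES = food_group_codes()

vectors = st.sets(st.sampled_from(ALL_CODES)).map(FoodGroupVector.from_groups)


def vec(*groups: str) -> FoodGroupVector:
    return FoodGroupVector.from_groups(groups)


class TestWorkedExamples:
    def test_fgds_hand_count(self):
        # grains + DGLV + eggs + meat(fish) + other fruits + other vegetables
        v = vec(
            "grain_based_staple_foods",
            "dark_green_leafy_vegetables",
            "eggs",
            "fish_and_seafood",
            "other_fruits",
            "other_vegetables",
        )
        assert fgds(v) == 6

    def test_fgds_saturates_at_10(self, full_vector, empty_vector):
        assert fgds(full_vector) == 10
        assert fgds(empty_vector) == 0

    def test_all5_minimal_witness(self):
        v = vec(
            "grain_based_staple_foods",
            "other_vegetables",
            "citrus_fruits",
            "pulses_legumes",
            "eggs",
        )
        result = all5(v)
        assert result.flag and all(result.components.values())

    def test_all5_fails_without_fruit(self):
        v = vec(
            "grain_based_staple_foods",
            "other_vegetables",
            "pulses_legumes",
            "eggs",
        )
        result = all5(v)
        assert not result.flag
        assert result.components["fruit"] is False

    def test_ncd_protect_additivity(self, empty_vector):
        assert ncd_protect(empty_vector) == 0
        assert ncd_protect(vec("whole_grains", "citrus_fruits")) == 2

    def test_processed_meat_scores_two_risk_points(self):
        assert ncd_risk(vec("processed_meats")) == 2

    def test_fast_food_and_instant_noodles_share_one_point(self):
        assert ncd_risk(vec("fast_foods", "instant_noodles")) == 1

    def test_red_meats_share_one_point(self):
        assert (
            ncd_risk(vec("unprocessed_red_meat_ruminants", "unprocessed_red_meat_non_ruminants"))
            == 1
        )

    def test_gdr_extremes(self, empty_vector):
        assert gdr(empty_vector) == 9
        protect_only = vec(
            "whole_grains", "pulses_legumes", "nuts_and_seeds",
            "vitamin_a_rich_orange_vegetables", "dark_green_leafy_vegetables",
            "other_vegetables", "vitamin_a_rich_fruits", "citrus_fruits", "other_fruits",
        )
        assert gdr(protect_only) == 18
        risk_only = vec(
            "soft_drinks_and_energy_sports_drinks", "baked_grain_based_sweets",
            "other_sweets", "processed_meats", "unprocessed_red_meat_ruminants",
            "deep_fried_foods", "fast_foods", "salty_snacks",
        )
        assert gdr(risk_only) == 0

    def test_juice_counts_as_sweet_beverage_not_fruit(self):
        v = vec("fruit_juice_fruit_flavoured_drinks")
        assert zero_fruit_veg(v) is True
        assert sweet_beverage(v) is True

    def test_salty_snacks_alone_trigger_upf(self):
        assert unhealthy_upf(vec("salty_snacks")) is True
        assert unhealthy_upf(vec("milk")) is False


class TestMddw:
    def test_threshold_at_five_groups(self):
        v5 = vec(
            "grain_based_staple_foods", "pulses_legumes", "nuts_and_seeds", "milk", "eggs"
        )
        assert fgds(v5) == 5
        assert mddw(v5, 17, "female") is True
        v4 = vec("grain_based_staple_foods", "pulses_legumes", "nuts_and_seeds", "milk")
        assert mddw(v4, 17, "female") is False

    @pytest.mark.parametrize(
        "age, gender, applicable",
        [(17, "male", False), (15, "female", True), (49, "female", True),
         (50, "female", False), (14, "female", False)],
    )
    def test_applicability_window(self, full_vector, age, gender, applicable):
        result = mddw(full_vector, age, gender)
        assert (result is not None) == applicable

    def test_age_window_is_configurable(self, full_vector):
        assert mddw(full_vector, 55, "female", age_range=(15, 60)) is True


class TestInvariants:
    @given(vectors)
    def test_gdr_identity(self, v):
        assert gdr(v) == ncd_protect(v) - ncd_risk(v) + 9

    @given(vectors, st.sampled_from(ALL_CODES))
    def test_monotonicity_under_added_consumption(self, v, extra):
        """Consuming one more group never lowers scores or unsets any-flags."""
        grown = FoodGroupVector({**dict(v.consumed), extra: True})
        assert fgds(grown) >= fgds(v)
        assert ncd_protect(grown) >= ncd_protect(v)
        assert ncd_risk(grown) >= ncd_risk(v)
        if all5(v).flag:
            assert all5(grown).flag
        if sweet_beverage(v):
            assert sweet_beverage(grown)
        if unhealthy_upf(v):
            assert unhealthy_upf(grown)
        if not zero_fruit_veg(v):
            assert not zero_fruit_veg(grown)

    @given(vectors)
    def test_zero_fruit_veg_caps_fgds_at_six(self, v):
        if zero_fruit_veg(v):
            assert fgds(v) <= 6

    @given(vectors)
    def test_all5_flag_is_conjunction_of_components(self, v):
        result = all5(v)
        assert result.flag == all(result.components.values())


class TestScoreRespondent:
    def _respondent(self, v, **kw):
        defaults = dict(
            respondent_id="r1", country="Laos", cluster_id="c1", age_years=17,
            gender="female", education="more_than_primary", residence="rural",
            wealth_quintile=3, diet=v,
        )
        defaults.update(kw)
        return Respondent(**defaults)

    def test_empty_diet(self, empty_vector):
        res = score_respondent(self._respondent(empty_vector))
        assert res.fgds == 0 and res.gdr == 9 and res.zero_fruit_veg

    def test_saturated_diet(self, full_vector):
        res = score_respondent(self._respondent(full_vector))
        assert res.fgds == 10 and res.all5 and res.ncd_risk == 9

    def test_male_respondent_mddw_not_applicable(self, full_vector):
        res = score_respondent(self._respondent(full_vector, gender="male"))
        assert res.mddw is None

    def test_underage_respondent_rejected(self, empty_vector):
        with pytest.raises(ValueError, match="15"):
            self._respondent(empty_vector, age_years=14)


class TestScoreTable:
    def test_matches_per_respondent_scoring(self, default_dataset):
        """Vectorized scoring equals the pure per-respondent route."""
        sample = default_dataset.sample(n=250, random_state=5)
        table = score_table(sample)
        for (idx, row), (_, scored) in zip(sample.iterrows(), table.iterrows()):
            v = FoodGroupVector({c: bool(row[c]) for c in ALL_CODES})
            r = Respondent(
                respondent_id=row["respondent_id"], country=row["country"],
                cluster_id=row["cluster_id"], age_years=int(row["age_years"]),
                gender=row["gender"], education=row["education"],
                residence=row["residence"], wealth_quintile=int(row["wealth_quintile"]),
                diet=v,
            )
            expected = score_respondent(r)
            assert scored["fgds"] == expected.fgds
            assert scored["ncd_protect"] == expected.ncd_protect
            assert scored["ncd_risk"] == expected.ncd_risk
            assert scored["gdr"] == expected.gdr
            assert scored["all5"] == expected.all5
            assert scored["zero_fruit_veg"] == expected.zero_fruit_veg
            assert scored["sweet_beverage"] == expected.sweet_beverage
            assert scored["unhealthy_upf"] == expected.unhealthy_upf
            if expected.mddw is None:
                assert pd.isna(scored["mddw"])
            else:
                assert scored["mddw"] == expected.mddw

    def test_missing_food_column_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="eggs"):
            score_table(default_dataset.drop(columns=["eggs"]))
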