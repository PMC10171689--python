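"""Wealth-score computation, score-to-income conversion and recoding."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wealthproxy import (
    EconomicConfig,
    HouseholdAssets,
    IwiIncomeModel,
    compute_iwi_score,
    iwi_income_daily_usd,
    recode_assets,
    score_to_monthly_inr,
    to_monthly_local,
)
from wealthproxy.iwi_scoring import IwiWeightTable, load_recode_rubric

MIN_ASSETS = HouseholdAssets(
    has_tv=False, has_refrigerator=False, has_phone=False, has_car=False,
    has_bicycle=False, has_cheap_utensils=False, has_expensive_utensils=False,
    has_electricity=False, floor_quality="low", toilet_quality="low",
    rooms_category="low", water_quality="low")

MAX_ASSETS = HouseholdAssets(
    has_tv=True, has_refrigerator=True, has_phone=True, has_car=True,
    has_bicycle=True, has_cheap_utensils=True, has_expensive_utensils=True,
    has_electricity=True, floor_quality="high", toilet_quality="high",
    rooms_category="high", water_quality="high")


class TestScore:
    def test_score_range_spans_zero_to_hundred(self, weight_table):
        # the shipped table's extreme configurations define the 0-100 range
        assert compute_iwi_score(MIN_ASSETS, weight_table) == \
            pytest.approx(0.0, abs=1e-4)
        assert compute_iwi_score(MAX_ASSETS, weight_table) == \
            pytest.approx(100.0, abs=1e-4)

    def test_missing_assets_give_missing_score(self, weight_table):
        assert compute_iwi_score(None, weight_table) is None

    @pytest.mark.parametrize("item", ["has_tv", "has_refrigerator",
                                      "has_phone", "has_car", "has_bicycle",
                                      "has_cheap_utensils",
                                      "has_expensive_utensils",
                                      "has_electricity"])
    def test_toggling_an_item_adds_exactly_its_weight(self, weight_table,
                                                      item):
        column = item.removeprefix("has_")
        base = compute_iwi_score(MIN_ASSETS, weight_table)
        toggled = compute_iwi_score(
            dataclasses.replace(MIN_ASSETS, **{item: True}), weight_table)
        assert toggled - base == pytest.approx(
            weight_table.boolean_weights[column], abs=1e-9)

    @given(upgrade=st.sampled_from(
        ["floor_quality", "toilet_quality", "rooms_category",
         "water_quality"]),
        level=st.sampled_from(["medium", "high"]))
    def test_upgrading_quality_never_decreases_score(self, weight_table,
                                                     upgrade, level):
        base = compute_iwi_score(MIN_ASSETS, weight_table)
        upgraded = compute_iwi_score(
            dataclasses.replace(MIN_ASSETS, **{upgrade: level}),
            weight_table)
        assert upgraded >= base

    def test_out_of_range_raw_sum_clamps_with_warning(self):
        inflated = IwiWeightTable(
            constant=120.0,
            boolean_weights={k: 1.0 for k in (
                "tv", "refrigerator", "phone", "car", "bicycle",
                "cheap_utensils", "expensive_utensils", "electricity")},
            categorical_weights={k: {"low": 0.0, "medium": 1.0, "high": 2.0}
                                 for k in ("floor_quality", "toilet_quality",
                                           "rooms_category",
                                           "water_quality")})
        with pytest.warns(UserWarning, match="clamped"):
            assert compute_iwi_score(MIN_ASSETS, inflated) == 100.0


class TestIncomeConversion:
    def test_score_zero_evaluates_to_printed_constant(self):
        assert iwi_income_daily_usd(0.0) == 1.489056

    def test_score_hundred_matches_high_precision_evaluation(self):
        assert iwi_income_daily_usd(100.0) == pytest.approx(
            1.489056 * math.exp(2.918), rel=1e-12)

    @pytest.mark.parametrize("score", [0.0, 10.0, 33.3, 50.0, 76.0])
    def test_doubling_identity(self, score):
        # income doubles every ln2/rate ~ 23.75 score points
        doubling = math.log(2) / 0.02918
        assert iwi_income_daily_usd(score + doubling) == pytest.approx(
            2 * iwi_income_daily_usd(score), rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=99.0))
    def test_income_strictly_increasing_in_score(self, score):
        assert iwi_income_daily_usd(score + 1.0) > iwi_income_daily_usd(score)

    @pytest.mark.parametrize("score", [-0.1, 100.5, float("nan")])
    def test_score_outside_range_rejected(self, score):
        with pytest.raises(ValueError):
            iwi_income_daily_usd(score)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            IwiIncomeModel(scale=-1.0)


class TestCurrencyPipeline:
    def test_identity_factors(self):
        econ = EconomicConfig(ppp_lcu_per_usd=1.0,
                              cpi_ratio_target_over_base=1.0)
        assert to_monthly_local(1.0, econ) == pytest.approx(30.44)
        assert to_monthly_local(0.0, econ) == 0.0

    def test_linear_in_ppp(self, econ):
        doubled = dataclasses.replace(
            econ, ppp_lcu_per_usd=2 * econ.ppp_lcu_per_usd)
        assert to_monthly_local(3.0, doubled) == \
            pytest.approx(2 * to_monthly_local(3.0, econ))

    def test_composition_strictly_increasing(self, econ):
        scores = np.linspace(0, 100, 101)
        incomes = score_to_monthly_inr(scores, econ)
        assert np.all(np.diff(incomes) > 0)


class TestRecode:
    RAW = {"tv": "yes", "refrigerator": "no", "phone": "yes", "car": "no",
           "bicycle": "yes", "cheap_utensils": "yes",
           "expensive_utensils": "no", "electricity": "yes",
           "floor_material": "cement", "toilet_facility": "flush to sewer",
           "water_source": "public tap", "rooms": 2}

    @pytest.mark.parametrize("rooms,expected", [
        (0, "low"), (1, "low"), (2, "medium"), (3, "high"), (7, "high")])
    def test_room_count_binning(self, rooms, expected):
        assets = recode_assets({**self.RAW, "rooms": rooms})
        assert assets.rooms_category == expected

    def test_vocabulary_mapping(self):
        assets = recode_assets(self.RAW)
        assert assets.floor_quality == "medium"
        assert assets.toilet_quality == "high"
        assert assets.water_quality == "medium"
        assert assets.has_tv and not assets.has_refrigerator

    def test_all_absent_is_missing_block(self):
        assert recode_assets({}) is None

    def test_unknown_floor_string_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="marble\\?"):
            assert recode_assets(
                {**self.RAW, "floor_material": "marble?"}) is None

    def test_rubric_rooms_validation(self):
        rubric = load_recode_rubric()
        with pytest.raises(ValueError):
            rubric.rooms_level(-1)
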