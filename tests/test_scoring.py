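"""Scoring-protocol arithmetic, invariants and cohort scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from newsy.scoring import (DENSITY_ITEMS, DIVERSITY_ITEMS, LIKERT_SUBSCALE_ITEMS,
                           RECREATION_ITEMS, ScoringError, ScoringProtocol,
                           reverse_code, score_cohort, score_destination_mix,
                           score_likert_subscale, score_residential_density)


class TestResidentialDensity:
    @pytest.mark.parametrize("responses, variant, expected", [
        ((0, 0, 0, 0, 0, 0), "standard", 0.0),
        ((4, 4, 4, 4, 4, 4), "standard", 1048.0),  # 4 * (1+11+25+50+75+100)
        ((1, 1, 0, 0, 0, 0), "standard", 12.0),
        ((4, 4, 4, 4, 4), "no_item6", 648.0),      # 4 * (1+11+25+50+75)
    ])
    def test_weighted_sum(self, responses, variant, expected):
        assert score_residential_density(responses, variant) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            score_residential_density((5, 0, 0, 0, 0, 0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ScoringError):
            score_residential_density((1, 1, 1))

    def test_missing_response_gives_missing_score(self):
        assert math.isnan(score_residential_density((1, math.nan, 0, 0, 0, 0)))

    @given(st.lists(st.integers(0, 4), min_size=6, max_size=6),
           st.integers(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_each_item(self, responses, idx):
        base = score_residential_density(responses)
        if responses[idx] < 4:
            bumped = list(responses)
            bumped[idx] += 1
            assert score_residential_density(bumped) > base


class TestDestinationMix:
    def test_constant_vectors(self):
        assert score_destination_mix([5] * 13, 13) == 5.0
        assert score_destination_mix([1] * 9, 9) == 1.0

    def test_mean(self):
        assert score_destination_mix([5, 4, 3, 2, 1, 5, 4, 3, 2], 9) == \
            pytest.approx(29 / 9)

    def test_shape_and_range_errors(self):
        with pytest.raises(ScoringError):
            score_destination_mix([3] * 12, 13)
        with pytest.raises(ScoringError):
            score_destination_mix([0] + [3] * 12, 13)

    @given(st.lists(st.integers(1, 5), min_size=9, max_size=9), st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, responses, rnd):
        shuffled = list(responses)
        rnd.shuffle(shuffled)
        assert score_destination_mix(shuffled, 9) == \
            pytest.approx(score_destination_mix(responses, 9))


class TestReverseCode:
    @pytest.mark.parametrize("x, expected", [(1, 4), (2, 3), (3, 2), (4, 1)])
    def test_four_point_scale(self, x, expected):
        assert reverse_code(x) == expected

    @given(st.integers(1, 4))
    def test_involution(self, x):
        assert reverse_code(reverse_code(x)) == x

    @given(st.integers(1, 3))
    def test_strictly_decreasing(self, x):
        assert reverse_code(x + 1) < reverse_code(x)

    def test_out_of_range(self):
        with pytest.raises(ScoringError):
            reverse_code(5)


class TestLikertSubscales:
    def test_traffic_safety_reversal(self):
        r = {"TS1": 1, "TS2": 4, "TS3": 1}
        assert score_likert_subscale(r, ["TS1", "TS2", "TS3"],
                                     {"TS1", "TS3"}) == 4.0

    def test_maximal_fear_gives_minimal_safety(self):
        r = {f"CR{i}": 4 for i in range(1, 5)}
        items = [f"CR{i}" for i in range(1, 5)]
        assert score_likert_subscale(r, items, set(items)) == 1.0

    def test_no_reversal_constant(self):
        r = {"AE1": 2, "AE2": 2, "AE3": 2}
        assert score_likert_subscale(r, ["AE1", "AE2", "AE3"]) == 2.0

    def test_missing_item_listwise(self):
        assert math.isnan(score_likert_subscale({"AE1": 2, "AE2": 3},
                                                ["AE1", "AE2", "AE3"]))

    @given(st.dictionaries(st.sampled_from(["AE1", "AE2", "AE3"]),
                           st.integers(1, 4), min_size=3))
    @settings(max_examples=40, deadline=None)
    def test_range(self, responses):
        s = score_likert_subscale(responses, ["AE1", "AE2", "AE3"])
        assert 1.0 <= s <= 4.0


def _one_row(values: dict) -> pd.DataFrame:
    return pd.DataFrame([values])


class TestCohortScoring:
    def test_minimum_respondent(self):
        row = {c: 0 for c in DENSITY_ITEMS}
        row |= {c: 1 for c in DIVERSITY_ITEMS + RECREATION_ITEMS}
        for items in LIKERT_SUBSCALE_ITEMS.values():
            row |= {c: 1 for c in items}
        out = score_cohort(_one_row(row))
        assert out.loc[0, "residential_density_score"] == 0.0
        assert out.loc[0, "land_use_mix_diversity_score"] == 1.0
        assert out.loc[0, "recreational_facilities_score"] == 1.0
        # all-1 responses: reversed items score 4, so AW = (4+1+1+1+1)/5
        assert out.loc[0, "accessibility_walking_score"] == pytest.approx(8 / 5)
        assert out.loc[0, "safety_from_crime_score"] == 4.0  # all reversed
        assert out.loc[0, "aesthetics_score"] == 1.0

    def test_country_variants(self):
        row_dk = {"country": "denmark"} | {c: 4 for c in DENSITY_ITEMS[:5]}
        row_ng = {"country": "nigeria"} | {c: 2 for c in RECREATION_ITEMS}
        out_dk = score_cohort(pd.DataFrame([row_dk]))
        assert out_dk.loc[0, "residential_density_score"] == 648.0
        out_ng = score_cohort(pd.DataFrame([row_ng]))
        # six-item variant still averages to 2 on constant responses
        assert out_ng.loc[0, "recreational_facilities_score"] == 2.0
        assert ScoringProtocol.for_country("nigeria").recreation_items == \
            [f"RF{i}" for i in range(1, 7)]

    def test_scores_within_theoretical_ranges(self, rng):
        n = 200
        data = {c: rng.integers(0, 5, n) for c in DENSITY_ITEMS}
        data |= {c: rng.integers(1, 6, n) for c in DIVERSITY_ITEMS + RECREATION_ITEMS}
        for items in LIKERT_SUBSCALE_ITEMS.values():
            data |= {c: rng.integers(1, 5, n) for c in items}
        out = score_cohort(pd.DataFrame(data))
        assert out["residential_density_score"].between(0, 1048).all()
        assert out["land_use_mix_diversity_score"].between(1, 5).all()
        for name in LIKERT_SUBSCALE_ITEMS:
            assert out[f"{name}_score"].between(1, 4).all()

    def test_min_answered_fraction_mode(self):
        row = {c: 3 for c in DIVERSITY_ITEMS}
        row["LU13"] = np.nan
        listwise = score_cohort(_one_row(row))
        assert math.isnan(listwise.loc[0, "land_use_mix_diversity_score"])
        relaxed = score_cohort(_one_row(row),
                               ScoringProtocol(min_answered_fraction=0.8),
                               per_country_variants=False)
        assert relaxed.loc[0, "land_use_mix_diversity_score"] == 3.0
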