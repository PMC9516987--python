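"""SDQ scoring, banding, exclusion filtering, aggregation and
descriptive-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdqmap.sdq import (ItemMap, aggregate_ward_year, apply_exclusions,
                        band_of, descriptive_table, pct_1dp, score_sdq)

ITEM_MAP = ItemMap.default()


def items_for_total(total: int) -> list[int]:
    """Raw responses whose scored total equals ``total`` (fills difficulty
    items greedily, 2 points each; reversed items get 2 - score)."""
    diff_ids = [i for d in ITEM_MAP.difficulty_domains
                for i in ITEM_MAP.domains[d]]
    scores = [0] * 25
    remaining = total
    for i in diff_ids:
        add = min(2, remaining)
        scores[i - 1] = add
        remaining -= add
    assert remaining == 0
    return [2 - s if (i + 1) in ITEM_MAP.reversed_items else s
            for i, s in enumerate(scores)]


def test_minimum_score_all_domains_zero():
    """All difficulty responses at their 'no difficulty' end score 0."""
    items = items_for_total(0)
    s = score_sdq(items, ITEM_MAP)
    assert s.total == 0
    assert s.band == "close_to_average"
    assert s.high_flag is False
    for dom in ITEM_MAP.difficulty_domains:
        assert s.domain_scores[dom] == 0


@pytest.mark.parametrize("total,band,high", [
    (10, "close_to_average", False),
    (11, "slightly_raised", False),
    (14, "slightly_raised", False),
    (15, "high", True),
    (17, "high", True),
    (18, "very_high", True),
    (40, "very_high", True),
])
def test_banding_thresholds(total, band, high):
    s = score_sdq(items_for_total(total), ITEM_MAP)
    assert s.total == total
    assert s.band == band
    assert s.high_flag is high


def test_banding_is_partition():
    """Every total 0-40 maps to exactly one band; high_flag agrees with
    band membership."""
    for total in range(41):
        band = band_of(total)
        assert band in ("close_to_average", "slightly_raised", "high",
                        "very_high")
        assert (total >= 15) == (band in ("high", "very_high"))


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sampled_from([0, 1, 2]), min_size=25, max_size=25))
def test_total_is_sum_of_difficulty_domains(items):
    s = score_sdq(items, ITEM_MAP)
    assert s.total == sum(s.domain_scores[d]
                          for d in ITEM_MAP.difficulty_domains)
    assert 0 <= s.total <= 40
    assert s.band == band_of(s.total)


def test_invalid_item_named_in_error():
    items = items_for_total(0)
    items[16] = 3
    with pytest.raises(ValueError, match="item 17"):
        score_sdq(items, ITEM_MAP)


def test_prorating_partial_domains():
    """A domain with >= 3 answered items is prorated (rounded mean x 5);
    fewer than 3 in a difficulty domain makes the total missing."""
    items = items_for_total(0)
    # emotional domain items are 3, 8, 13, 16, 24; set three of them to 2
    # and blank the other two -> mean 2, prorated domain score 10
    for i in (3, 8, 13):
        items[i - 1] = 2
    for i in (16, 24):
        items[i - 1] = None
    s = score_sdq(items, ITEM_MAP)
    assert s.prorated
    assert s.domain_scores["emotional"] == 10
    assert s.total == 10
    # blank 3 of 5 -> domain and total missing
    for i in (3, 8, 16):
        items[i - 1] = None
    s = score_sdq(items, ITEM_MAP)
    assert s.total is None and s.band is None


def _records(n, **overrides):
    base = dict(
        child_id=np.arange(n), preschool_id=0, ward_id=0, cohort=2010,
        sex="female", age_months=60.0, deprivation_quintile=5,
        total_score=5.0, postcode_valid=True, in_study_area=True,
        dob_known=True)
    base.update(overrides)
    return pd.DataFrame(base)


def test_exclusion_reasons_and_union():
    df = pd.concat([
        _records(4),                             # retained
        _records(2, in_study_area=False),        # out of area
        _records(1, dob_known=False),
        _records(2, age_months=6.3 * 12),        # out of age (over 6)
        _records(1, age_months=3.9 * 12),        # out of age (under 4)
        _records(1, postcode_valid=False),
        _records(2, total_score=np.nan),
        _records(1, in_study_area=False, total_score=np.nan),  # overlap
    ], ignore_index=True)
    retained, tally = apply_exclusions(df)
    assert len(retained) == 4
    assert tally["out_of_area"] == 3
    assert tally["out_of_age"] == 3
    assert tally["missing_dob"] == 1
    assert tally["invalid_postcode"] == 1
    assert tally["missing_score"] == 3
    # union is overlap-adjusted: 10 distinct failing records
    assert tally["excluded"] == 10
    assert tally["retained"] == 4


def test_exclusions_empty_input():
    retained, tally = apply_exclusions(_records(0))
    assert retained.empty and tally["excluded"] == 0


def test_aggregate_threshold_boundary():
    """Totals {14, 15, 20} in one ward-year: Y=2 of E=3, median 15."""
    df = _records(3)
    df["total_score"] = [14.0, 15.0, 20.0]
    df["sex"] = ["male", "male", "female"]
    out = aggregate_ward_year(df)
    assert len(out) == 1
    row = out.iloc[0]
    assert row.y_high == 2 and row.n_assessed == 3
    assert row.median_score == 15.0
    assert row.prop_boys == pytest.approx(2 / 3)


def test_aggregate_matches_naive_groupby(small_study):
    records, _ = small_study
    out = aggregate_ward_year(records)
    # independent double loop
    for _, row in out.sample(12, random_state=0).iterrows():
        sub = records[(records.ward_id == row.ward_id)
                      & (records.cohort == row.cohort)]
        assert row.n_assessed == len(sub)
        assert row.y_high == int((sub.total_score >= 15).sum())
        assert row.prop_boys == pytest.approx((sub.sex == "male").mean())
        assert row.prop_most_deprived == pytest.approx(
            (sub.deprivation_quintile == 1).mean())
    assert out.n_assessed.sum() == len(records)
    assert out.y_high.sum() == int((records.total_score >= 15).sum())


def test_unknown_ward_rejected():
    df = _records(3)
    df.loc[1, "ward_id"] = np.nan
    with pytest.raises(ValueError, match="unknown ward"):
        aggregate_ward_year(df)


@pytest.mark.parametrize("n_high,total,expected", [
    (3149, 35171, 9.0),
    (212, 2112, 10.0),
    (1541, 16456, 9.4),
    (1160, 15297, 7.6),
    (236, 1306, 18.1),
    (877, 17210, 5.1),
    (2272, 17961, 12.6),
])
def test_percentage_rounding_half_up(n_high, total, expected):
    assert pct_1dp(n_high, total) == expected


def test_descriptive_table_identical_scores():
    df = _records(10)
    df["total_score"] = 7.0
    t = descriptive_table(df, "sex")
    assert len(t) == 1
    assert t.iloc[0]["median"] == 7.0
    assert t.iloc[0]["q25"] == t.iloc[0]["q75"] == 7.0


def test_descriptive_groups_partition_total(small_study):
    records, _ = small_study
    for grouping in ("age_band", "sex", "deprivation", "cohort", "ward"):
        t = descriptive_table(records, grouping)
        assert t["N"].sum() == len(records)
        assert t["n_high"].sum() == int((records.total_score >= 15).sum())
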