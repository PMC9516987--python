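"""SDQ scoring, banding, exclusion filtering and descriptive summaries.

The Strengths and Difficulties Questionnaire (SDQ) has 25 items on a 0/1/2
scale across five domains (emotional symptoms, conduct problems,
hyperactivity/inattention, peer problems, prosocial behaviour). The four
difficulty domains sum to a total difficulties score out of 40. For UK
preschool children the total is banded 0-10 close to average, 11-14
slightly raised, 15-17 high and >= 18 very high; a score of 15 or more
("high or very high") flags a high likelihood of psychiatric disorder and
is the event counted by the disease-mapping model.

Child-level data are held as a pandas DataFrame with one row per child;
see :mod:`sdqmap.synthetic` for the column schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

BANDS = ("close_to_average", "slightly_raised", "high", "very_high")
#: band lower bounds on the total difficulties score
BAND_EDGES = {"close_to_average": 0, "slightly_raised": 11, "high": 15,
              "very_high": 18}
HIGH_THRESHOLD = 15

#: exclusion reasons, applied in this order for per-reason tallies
EXCLUSION_REASONS = ("out_of_area", "missing_dob", "out_of_age",
                     "invalid_postcode", "missing_score")

AGE_BAND_LABELS = ("4-4.5", "4.5-5", "5-5.5", "5.5-6")


@dataclass(frozen=True)
class ItemMap:
    """Item -> domain assignment and reverse-scored item set (1-based ids)."""

    domains: dict[str, list[int]]
    reversed_items: frozenset[int]
    difficulty_domains: tuple[str, ...]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemMap":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            domains={k: list(v) for k, v in cfg["domains"].items()},
            reversed_items=frozenset(cfg["reversed"]),
            difficulty_domains=tuple(cfg["difficulty_domains"]),
        )

    @classmethod
    def default(cls) -> "ItemMap":
        ref = resources.files("sdqmap") / "data" / "sdq_teacher_items.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass(frozen=True)
class SDQScore:
    total: int | None
    domain_scores: dict[str, int | None]
    band: str | None
    high_flag: bool | None
    prorated: bool = False


def band_of(total: int) -> str:
    if not 0 <= total <= 40:
        raise ValueError(f"total must be in [0, 40], got {total}")
    if total >= 18:
        return "very_high"
    if total >= 15:
        return "high"
    if total >= 11:
        return "slightly_raised"
    return "close_to_average"


def score_sdq(items, item_map: ItemMap | None = None) -> SDQScore:
    """Score a 25-item SDQ response vector.

    ``items`` is indexable 0..24 (item 1 at position 0) with values in
    {0, 1, 2} or None/NaN for unanswered items. Per SDQ convention a domain
    score is prorated (rounded mean x 5) when at least 3 of its 5 items are
    answered; if any difficulty domain has fewer, the total is missing.
    """
    if item_map is None:
        item_map = ItemMap.default()
    items = list(items)
    if len(items) != 25:
        raise ValueError(f"expected 25 items, got {len(items)}")
    vals: list[float | None] = []
    for idx, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            vals.append(None)
            continue
        if v not in (0, 1, 2):
            raise ValueError(f"item {idx} has invalid response {v!r}; "
                             "must be 0, 1 or 2")
        vals.append(2 - v if idx in item_map.reversed_items else v)

    domain_scores: dict[str, int | None] = {}
    prorated = False
    for dom, ids in item_map.domains.items():
        answered = [vals[i - 1] for i in ids if vals[i - 1] is not None]
        if len(answered) == len(ids):
            domain_scores[dom] = int(sum(answered))
        elif len(answered) >= 3:
            # rounded (half-up) mean response x 5
            mean5 = Decimal(sum(answered)) / Decimal(len(answered)) * 5
            domain_scores[dom] = int(mean5.quantize(0, rounding=ROUND_HALF_UP))
            prorated = True
        else:
            domain_scores[dom] = None

    diff = [domain_scores[d] for d in item_map.difficulty_domains]
    if any(d is None for d in diff):
        return SDQScore(None, domain_scores, None, None, prorated)
    total = int(sum(diff))
    return SDQScore(total, domain_scores, band_of(total),
                    total >= HIGH_THRESHOLD, prorated)


# ---------------------------------------------------------------------------
# exclusion filtering


def exclusion_mask(records: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask per exclusion reason (columns ordered as
    :data:`EXCLUSION_REASONS`)."""
    age_years = records["age_months"] / 12.0
    masks = pd.DataFrame(index=records.index)
    masks["out_of_area"] = ~records["in_study_area"].astype(bool)
    masks["missing_dob"] = ~records["dob_known"].astype(bool)
    # age is unknowable without a date of birth; out-of-age applies only
    # where a DOB exists
    masks["out_of_age"] = records["dob_known"].astype(bool) & (
        (age_years < 4.0) | (age_years > 6.0)
    )
    masks["invalid_postcode"] = ~records["postcode_valid"].astype(bool)
    masks["missing_score"] = records["total_score"].isna()
    return masks


def apply_exclusions(records: pd.DataFrame):
    """Drop ineligible children; return (retained, tally).

    Children are excluded if they lived outside the study area, were
    missing a date of birth, were under 4 or over 6 years old at school
    entry, had a missing/invalid postcode, or had no total difficulties
    score. The tally counts each reason separately plus the overlap-
    adjusted union ("excluded").
    """
    if records.empty:
        tally = {r: 0 for r in EXCLUSION_REASONS}
        tally.update(excluded=0, retained=0)
        return records.copy(), tally
    masks = exclusion_mask(records)
    any_fail = masks.any(axis=1)
    tally = {r: int(masks[r].sum()) for r in EXCLUSION_REASONS}
    tally["excluded"] = int(any_fail.sum())
    tally["retained"] = int((~any_fail).sum())
    return records.loc[~any_fail].copy(), tally


# ---------------------------------------------------------------------------
# aggregation and descriptives


def age_band(age_months: pd.Series) -> pd.Series:
    """Half-open age bands [4,4.5), [4.5,5), [5,5.5), [5.5,6] in years."""
    yrs = age_months / 12.0
    return pd.cut(yrs, bins=[4.0, 4.5, 5.0, 5.5, 6.0],
                  labels=AGE_BAND_LABELS, right=False,
                  include_lowest=True).astype(object).where(yrs <= 6.0)


def off_expected_age(age_months: pd.Series) -> pd.Series:
    """Outside the expected school-start age range (4.5-5.5 years)."""
    yrs = age_months / 12.0
    return (yrs < 4.5) | (yrs > 5.5)


def aggregate_ward_year(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate scored, filtered child records to ward x cohort rows.

    Returns one row per ward x cohort with the high-score count ``y_high``,
    exposure ``n_assessed`` (all assessed children), covariate proportions
    and the median total score.
    """
    if records["ward_id"].isna().any():
        raise ValueError("records with unknown ward cannot be aggregated")
    if records["total_score"].isna().any():
        raise ValueError("records must be scored and filtered first")
    df = records.assign(
        _high=(records["total_score"] >= HIGH_THRESHOLD).astype(int),
        _boy=(records["sex"] == "male").astype(int),
        _mostdep=(records["deprivation_quintile"] == 1).astype(int),
        _offage=off_expected_age(records["age_months"]).astype(int),
    )
    g = df.groupby(["ward_id", "cohort"], sort=True)
    out = g.agg(
        y_high=("_high", "sum"),
        n_assessed=("_high", "size"),
        prop_boys=("_boy", "mean"),
        prop_most_deprived=("_mostdep", "mean"),
        prop_off_age=("_offage", "mean"),
        median_score=("total_score", "median"),
    ).reset_index()
    return out


def pct_1dp(n: int, total: int) -> float:
    """Percentage rounded half-up to 1 decimal place (table presentation)."""
    if total == 0:
        return float("nan")
    q = Decimal(n) * 100 / Decimal(total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _quartiles(scores: np.ndarray) -> tuple[float, float]:
    """25th/75th percentiles with lower-nearest-rank interpolation, matching
    integer IQRs as conventionally printed."""
    lo = float(np.percentile(scores, 25, method="lower"))
    hi = float(np.percentile(scores, 75, method="lower"))
    return lo, hi


_GROUPERS = {
    "age_band": lambda df: age_band(df["age_months"]),
    "sex": lambda df: df["sex"],
    "deprivation": lambda df: df["deprivation_quintile"],
    "cohort": lambda df: df["cohort"],
    "ward": lambda df: df["ward_id"],
}


def descriptive_table(records: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-group N, high-score count and percentage, median and IQR.

    ``grouping`` is one of age_band, sex, deprivation, cohort, ward.
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"unknown grouping {grouping!r}; "
                         f"choose from {sorted(_GROUPERS)}")
    key = _GROUPERS[grouping](records)
    rows = []
    for level, idx in records.groupby(key, sort=True).groups.items():
        sub = records.loc[idx]
        scores = sub["total_score"].to_numpy()
        n_high = int((scores >= HIGH_THRESHOLD).sum())
        q25, q75 = _quartiles(scores)
        rows.append({
            "group": level,
            "N": len(sub),
            "n_high": n_high,
            "pct_high": pct_1dp(n_high, len(sub)),
            "median": float(np.median(scores)),
            "q25": q25,
            "q75": q75,
        })
    return pd.DataFrame(rows)


def descriptive_tables(records: pd.DataFrame,
                       groupings=("age_band", "sex", "deprivation",
                                  "cohort", "ward")) -> pd.DataFrame:
    """Stacked descriptive table over several grouping variables."""
    parts = []
    for g in groupings:
        t = descriptive_table(records, g)
        t.insert(0, "grouping", g)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def table_to_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown(index=False)
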