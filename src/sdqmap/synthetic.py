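"""Synthetic study generator: wards, preschool rosters and child SDQ data.

The real study data (routinely collected preschool SDQ assessments for a
whole UK city, 2010-2017) are not public, so this module generates data
with exactly the generative structure the two models assume: a child's
total difficulties score is zero-inflated negative binomial with

    log lambda_ijk = beta0 + (beta_cohort + v1_j) * t + beta_male * male_i
                     + beta_age_sq * (age_i - 59)^2 + beta_dep[q_i]
                     + alpha_k + v0_j

where ``t`` is the cohort index, ``alpha_k ~ N(0, sigma2_preschool)`` is a
preschool effect and ``v0_j ~ N(0, sigma2_ward)`` a ward effect. Preschools
draw children mostly from one home ward but with a small probability from
adjacent wards, so preschool and ward are cross-classified rather than
nested. Every random effect drawn is recorded in a ground-truth ledger for
parameter-recovery testing.

Default parameters emulate the study's scale and marginals: ~35,000
children over 8 cohorts, 21 wards, 180 preschools, 51% boys, ward-varying
deprivation composition and roughly 9% of children scoring >= 15.

Child records are a pandas DataFrame with columns::

    child_id, preschool_id, ward_id, cohort, sex, age_months,
    deprivation_quintile, total_score, postcode_valid, in_study_area,
    dob_known [, item_1 .. item_25]
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geography import Geography, GeographyConfig, generate_geography
from .sdq import ItemMap
from .zinb import zinb_rvs

logger = logging.getLogger(__name__)

#: age-band supports in months and default mixture weights (study marginals)
AGE_BANDS_MONTHS = ((48, 54), (54, 60), (60, 66), (66, 72))
DEFAULT_AGE_WEIGHTS = (0.0601, 0.4679, 0.4350, 0.0371)
#: city-wide deprivation-quintile marginals, most deprived (1) .. least (5)
DEFAULT_DEP_MARGINALS = (0.2734, 0.2326, 0.1904, 0.1595, 0.1442)
#: relative cohort sizes across the 8 study years
DEFAULT_COHORT_WEIGHTS = (3082, 3336, 3882, 3899, 5275, 5246, 5480, 4971)

RECORD_COLUMNS = [
    "child_id", "preschool_id", "ward_id", "cohort", "sex", "age_months",
    "deprivation_quintile", "total_score", "postcode_valid",
    "in_study_area", "dob_known",
]


@dataclass
class PopulationConfig:
    n_children: int = 35_171
    n_preschools: int = 180
    cohorts: tuple[int, ...] = tuple(range(2010, 2018))
    prob_male: float = 0.5107
    age_band_weights: tuple[float, ...] = DEFAULT_AGE_WEIGHTS
    #: per-ward quintile probability vectors (n_wards x 5, quintile 1 first);
    #: None -> Dirichlet draws centred on the city marginals
    deprivation_mixing: np.ndarray | None = None
    cohort_weights: tuple[float, ...] | None = None
    #: probability a child attends a preschool homed in an adjacent ward
    crossing_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_preschools > self.n_children:
            raise ValueError("n_preschools must not exceed n_children")
        w = np.asarray(self.age_band_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-3):
            raise ValueError("age_band_weights must sum to 1")
        self.age_band_weights = tuple(w / w.sum())
        if self.deprivation_mixing is not None:
            m = np.asarray(self.deprivation_mixing, dtype=float)
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("each deprivation mixing row must sum to 1")
            self.deprivation_mixing = m


@dataclass
class TruthParams:
    """Ground-truth generative parameters (log-scale fixed effects).

    ``beta_dep`` holds the four deprivation contrasts versus the
    least-deprived quintile (5), ordered [q4, q3, q2, q1]. Defaults are the
    adjusted posterior means the study reported, so the default simulation
    resembles the study; ``p_zero``/``r_overdisp`` are calibrated to its
    descriptive score distribution (median 4, IQR 1-9, ~9% scoring >= 15).
    """

    beta0: float = float(np.log(4.079))
    beta_cohort: float = float(np.log(1.008))
    beta_male: float = float(np.log(1.370))
    beta_age_sq: float = float(np.log(1.003))
    beta_dep: tuple[float, float, float, float] = (
        float(np.log(1.115)), float(np.log(1.174)),
        float(np.log(1.234)), float(np.log(1.243)))
    sigma2_ward: float = 0.013
    sigma2_preschool: float = 0.062
    sigma2_slope: float = 0.0
    slope_intercept_correlation: float = 0.0
    p_zero: float = 0.15
    r_overdisp: float = 1.4

    def __post_init__(self) -> None:
        if min(self.sigma2_ward, self.sigma2_preschool, self.sigma2_slope) < 0:
            raise ValueError("variances must be >= 0")
        if not self.r_overdisp > 0:
            raise ValueError("r_overdisp must be > 0")
        if not 0.0 <= self.p_zero < 1.0:
            raise ValueError("p_zero must be in [0, 1)")
        if not -1.0 <= self.slope_intercept_correlation <= 1.0:
            raise ValueError("slope_intercept_correlation must be in [-1, 1]")


def _dep_contrast(truth: TruthParams, quintile: np.ndarray) -> np.ndarray:
    """Deprivation contrast per child; quintile 5 is the reference."""
    table = np.array([truth.beta_dep[3], truth.beta_dep[2],
                      truth.beta_dep[1], truth.beta_dep[0], 0.0])
    return table[quintile - 1]


def assign_preschools(geo: Geography, n_preschools: int,
                      rng: np.random.Generator,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """Home ward of each preschool: one per ward first (coverage), the rest
    proportional to ward population weights."""
    n_wards = geo.n_wards
    if n_preschools < n_wards:
        homes = rng.choice(n_wards, size=n_preschools, replace=False)
    else:
        extra = rng.choice(n_wards, size=n_preschools - n_wards, p=weights)
        homes = np.concatenate([np.arange(n_wards), extra])
        rng.shuffle(homes)
    return homes


def generate_children(geo: Geography, pop: PopulationConfig,
                      truth: TruthParams | None = None,
                      emit_items: bool = False):
    """Simulate child records; returns ``(records, truth_ledger)``.

    The ledger is a JSON-serializable dict holding every parameter and
    random effect drawn (keyed by ward/preschool id) for recovery tests.
    """
    if truth is None:
        truth = TruthParams()
    rng = np.random.default_rng(pop.seed)
    n = pop.n_children
    n_wards = geo.n_wards

    ward_w = geo_population_weights(geo, pop)
    # ward membership by multinomial allocation
    ward = rng.choice(n_wards, size=n, p=ward_w)

    # preschools: home ward plus occasional crossing to an adjacent ward
    homes = assign_preschools(geo, pop.n_preschools, rng, ward_w)
    by_ward = [np.nonzero(homes == j)[0] for j in range(n_wards)]
    adj_lists = [np.nonzero(geo.adjacency[j] > 0)[0] for j in range(n_wards)]
    preschool = np.empty(n, dtype=int)
    cross = rng.random(n) < pop.crossing_prob
    for j in range(n_wards):
        idx = np.nonzero(ward == j)[0]
        if idx.size == 0:
            continue
        local = by_ward[j]
        neigh = np.concatenate([by_ward[a] for a in adj_lists[j]]) \
            if adj_lists[j].size else np.empty(0, dtype=int)
        if local.size == 0:
            # no preschool homed here: fall back to neighbours, then city
            local = neigh if neigh.size else np.arange(len(homes))
        pool_cross = neigh if neigh.size else local
        take_cross = cross[idx]
        preschool[idx[~take_cross]] = rng.choice(local,
                                                 size=(~take_cross).sum())
        preschool[idx[take_cross]] = rng.choice(pool_cross,
                                                size=take_cross.sum())

    # demographics
    cw = np.asarray(pop.cohort_weights if pop.cohort_weights is not None
                    else DEFAULT_COHORT_WEIGHTS[: len(pop.cohorts)],
                    dtype=float)
    cw = cw / cw.sum()
    t = rng.choice(len(pop.cohorts), size=n, p=cw)
    male = rng.random(n) < pop.prob_male
    band = rng.choice(len(AGE_BANDS_MONTHS), size=n,
                      p=np.asarray(pop.age_band_weights))
    lo = np.array([b[0] for b in AGE_BANDS_MONTHS])[band]
    hi = np.array([b[1] for b in AGE_BANDS_MONTHS])[band]
    age_months = rng.uniform(lo, hi)

    if pop.deprivation_mixing is None:
        base = np.asarray(DEFAULT_DEP_MARGINALS)
        mixing = rng.dirichlet(base * 8.0, size=n_wards)
    else:
        mixing = pop.deprivation_mixing
    # vectorized per-ward categorical draw via inverse cdf
    cum = np.cumsum(mixing, axis=1)
    u = rng.random(n)
    quintile = 1 + (u[:, None] > cum[ward]).sum(axis=1).astype(int)
    quintile = np.clip(quintile, 1, 5)

    # random effects
    v0 = rng.normal(0.0, np.sqrt(truth.sigma2_ward), size=n_wards)
    alpha = rng.normal(0.0, np.sqrt(truth.sigma2_preschool),
                       size=pop.n_preschools)
    if truth.sigma2_slope > 0:
        rho = truth.slope_intercept_correlation
        cond_sd = np.sqrt(truth.sigma2_slope * (1 - rho ** 2))
        cond_mean = (rho * np.sqrt(truth.sigma2_slope / truth.sigma2_ward)
                     * v0) if truth.sigma2_ward > 0 else 0.0
        v1 = cond_mean + rng.normal(0.0, cond_sd, size=n_wards)
    else:
        v1 = np.zeros(n_wards)

    eta = (truth.beta0
           + (truth.beta_cohort + v1[ward]) * t
           + truth.beta_male * male
           + truth.beta_age_sq * (age_months - 59.0) ** 2
           + _dep_contrast(truth, quintile)
           + alpha[preschool] + v0[ward])
    lam = np.exp(eta)

    score = zinb_rvs(lam, truth.p_zero, truth.r_overdisp, rng)
    # scores above the SDQ support are rejected and redrawn
    over = np.nonzero(score > 40)[0]
    if over.size / n > 0.01:
        logger.warning(
            "ZINB mass beyond the SDQ support is heavy (%.1f%% of draws "
            "exceed 40); truncation materially distorts the generative "
            "model", 100.0 * over.size / n)
    while over.size:
        score[over] = zinb_rvs(lam[over], truth.p_zero, truth.r_overdisp, rng)
        over = over[score[over] > 40]

    records = pd.DataFrame({
        "child_id": np.arange(n),
        "preschool_id": preschool,
        "ward_id": ward,
        "cohort": np.asarray(pop.cohorts)[t],
        "sex": np.where(male, "male", "female"),
        "age_months": age_months,
        "deprivation_quintile": quintile,
        "total_score": score.astype(float),
        "postcode_valid": True,
        "in_study_area": True,
        "dob_known": True,
    })
    if emit_items:
        items = items_from_totals(score, rng)
        for i in range(25):
            records[f"item_{i + 1}"] = items[:, i]

    ledger = {
        "truth": {
            "beta0": truth.beta0, "beta_cohort": truth.beta_cohort,
            "beta_male": truth.beta_male, "beta_age_sq": truth.beta_age_sq,
            "beta_dep": list(truth.beta_dep),
            "sigma2_ward": truth.sigma2_ward,
            "sigma2_preschool": truth.sigma2_preschool,
            "sigma2_slope": truth.sigma2_slope,
            "slope_intercept_correlation": truth.slope_intercept_correlation,
            "p_zero": truth.p_zero, "r_overdisp": truth.r_overdisp,
        },
        "ward_effects": {int(geo.ward_ids[j]): float(v0[j])
                         for j in range(n_wards)},
        "ward_slopes": {int(geo.ward_ids[j]): float(v1[j])
                        for j in range(n_wards)},
        "preschool_effects": {int(k): float(alpha[k])
                              for k in range(pop.n_preschools)},
        "preschool_home_ward": {int(k): int(geo.ward_ids[homes[k]])
                                for k in range(pop.n_preschools)},
        "deprivation_mixing": mixing.tolist(),
        "seed": pop.seed,
    }
    return records, ledger


def geo_population_weights(geo: Geography,
                           pop: PopulationConfig) -> np.ndarray:
    """Ward population weights from the geography config (area-proportional
    when unspecified)."""
    areas = np.array([p.area for p in geo.polygons])
    return areas / areas.sum()


def items_from_totals(totals: np.ndarray, rng: np.random.Generator,
                      item_map: ItemMap | None = None) -> np.ndarray:
    """Raw 25-item response vectors whose scored total equals ``totals``.

    The total is spread over the 20 difficulty items by repeatedly
    incrementing a random item that is below its cap of 2; prosocial items
    are drawn independently. Reverse-scored items are emitted as raw
    responses (2 - score).
    """
    if item_map is None:
        item_map = ItemMap.default()
    n = len(totals)
    diff_ids = [i for d in item_map.difficulty_domains
                for i in item_map.domains[d]]
    pro_ids = item_map.domains["prosocial"]
    scores = np.zeros((n, 25), dtype=int)
    for row, tot in enumerate(np.asarray(totals, dtype=int)):
        remaining = tot
        while remaining > 0:
            i = diff_ids[rng.integers(len(diff_ids))]
            if scores[row, i - 1] < 2:
                scores[row, i - 1] += 1
                remaining -= 1
        for i in pro_ids:
            scores[row, i - 1] = rng.integers(0, 3)
    raw = scores.copy()
    for i in item_map.reversed_items:
        raw[:, i - 1] = 2 - scores[:, i - 1]
    return raw


# ---------------------------------------------------------------------------
# exclusion-noise injection


@dataclass(frozen=True)
class ExclusionRates:
    """Contamination rates, each in [0, 1)."""

    missing_dob: float = 0.0
    invalid_postcode: float = 0.0
    out_of_area: float = 0.0
    out_of_age: float = 0.0
    missing_score: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1]")


def inject_exclusion_noise(records: pd.DataFrame, rates: ExclusionRates,
                           seed: int):
    """Contaminate records so the exclusion filter removes a known subset.

    Each contamination is drawn independently per record, so a record may
    fail several criteria. Returns ``(contaminated, n_contaminated)`` where
    the count is the number of records failing at least one criterion.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    n = len(out)
    hit = np.zeros(n, dtype=bool)

    m = rng.random(n) < rates.missing_dob
    out.loc[m, "dob_known"] = False
    hit |= m
    m = rng.random(n) < rates.invalid_postcode
    out.loc[m, "postcode_valid"] = False
    hit |= m
    m = rng.random(n) < rates.out_of_area
    out.loc[m, "in_study_area"] = False
    hit |= m
    m = rng.random(n) < rates.out_of_age
    # push age outside [4, 6] years, below or above at random
    low = rng.random(n) < 0.5
    out.loc[m & low, "age_months"] = rng.uniform(36, 47.9, (m & low).sum())
    out.loc[m & ~low, "age_months"] = rng.uniform(72.1, 84, (m & ~low).sum())
    hit |= m
    m = rng.random(n) < rates.missing_score
    out.loc[m, "total_score"] = np.nan
    hit |= m
    return out, int(hit.sum())


def contaminate_exact(records: pd.DataFrame, n_excluded: int, seed: int
                      ) -> pd.DataFrame:
    """Make exactly ``n_excluded`` records fail one randomly chosen
    exclusion criterion each (records chosen without replacement)."""
    rng = np.random.default_rng(seed)
    out = records.copy()
    idx = rng.choice(len(out), size=n_excluded, replace=False)
    reason = rng.integers(0, 5, size=n_excluded)
    rows = out.index[idx]
    out.loc[rows[reason == 0], "dob_known"] = False
    out.loc[rows[reason == 1], "postcode_valid"] = False
    out.loc[rows[reason == 2], "in_study_area"] = False
    out.loc[rows[reason == 3], "age_months"] = 80.0
    out.loc[rows[reason == 4], "total_score"] = np.nan
    return out


# ---------------------------------------------------------------------------
# dataset I/O


def simulate_study(geo_cfg: GeographyConfig | None = None,
                   pop: PopulationConfig | None = None,
                   truth: TruthParams | None = None,
                   rates: ExclusionRates | None = None,
                   emit_items: bool = False):
    """Full synthetic study: geography + children (+ optional noise).

    Returns ``(geo, records, ledger)``.
    """
    geo_cfg = geo_cfg or GeographyConfig()
    pop = pop or PopulationConfig()
    geo = generate_geography(geo_cfg)
    records, ledger = generate_children(geo, pop, truth, emit_items)
    if rates is not None:
        records, n_bad = inject_exclusion_noise(records, rates,
                                                seed=pop.seed + 1)
        ledger["n_contaminated"] = n_bad
    return geo, records, ledger


def write_study(out_dir: str | Path, geo: Geography, records: pd.DataFrame,
                ledger: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    geo.write_geojson(out / "wards.geojson")
    geo.write_adjacency_csv(out / "adjacency.csv")
    (out / "truth.json").write_text(json.dumps(ledger, indent=1))


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df
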