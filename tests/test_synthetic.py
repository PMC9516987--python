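"""Synthetic study generator: determinism, cross-classification, moment
checks and exclusion-noise contamination."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from sdqmap.geography import GeographyConfig, generate_geography
from sdqmap.sdq import ItemMap, apply_exclusions, score_sdq
from sdqmap.synthetic import (ExclusionRates, PopulationConfig, TruthParams,
                              contaminate_exact, generate_children,
                              inject_exclusion_noise, items_from_totals)


def test_seeded_determinism_byte_identical(geo21, tmp_path):
    pop = PopulationConfig(n_children=2000, n_preschools=30, seed=5)
    a, _ = generate_children(geo21, pop)
    b, _ = generate_children(geo21, pop)
    a.to_csv(tmp_path / "a.csv", index=False)
    b.to_csv(tmp_path / "b.csv", index=False)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_cross_classification(small_study):
    """Preschool and ward overlap without nesting."""
    records, _ = small_study
    pre_wards = records.groupby("preschool_id")["ward_id"].nunique()
    ward_pres = records.groupby("ward_id")["preschool_id"].nunique()
    assert (pre_wards >= 2).any()
    assert (ward_pres >= 2).any()


def test_homogeneous_truth_matches_zinb_moments(geo21):
    """With all variances and covariate effects at zero the scores are iid
    ZINB; sample moments at n = 50,000 match the closed forms."""
    truth = TruthParams(beta0=np.log(5.0), beta_cohort=0.0, beta_male=0.0,
                        beta_age_sq=0.0, beta_dep=(0.0, 0.0, 0.0, 0.0),
                        sigma2_ward=0.0, sigma2_preschool=0.0,
                        p_zero=0.15, r_overdisp=2.0)
    pop = PopulationConfig(n_children=50_000, n_preschools=60, seed=21)
    records, _ = generate_children(geo21, pop, truth)
    lam, p, r = 5.0, 0.15, 2.0
    mean = (1 - p) * lam
    var = (1 - p) * lam * (1 + lam / r + p * lam)
    y = records.total_score.to_numpy()
    assert y.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / len(y)))
    assert y.var() == pytest.approx(var, rel=0.06)
    # per-ward means all near the common mean (no heterogeneity case)
    g = records.groupby("ward_id")["total_score"].agg(["mean", "size"])
    se = np.sqrt(var / g["size"])
    assert (np.abs(g["mean"] - mean) < 3.5 * se).all()


def test_zero_fraction_against_independent_pmf(geo21):
    """Observed zero fraction within the binomial 99% CI of
    p + (1-p) NB(0; lam, r), NB zero mass from scipy."""
    truth = TruthParams(beta0=1.0, beta_cohort=0.0, beta_male=0.0,
                        beta_age_sq=0.0, beta_dep=(0.0, 0.0, 0.0, 0.0),
                        sigma2_ward=0.0, sigma2_preschool=0.0,
                        p_zero=0.25, r_overdisp=1.4)
    pop = PopulationConfig(n_children=30_000, n_preschools=60, seed=8)
    records, _ = generate_children(geo21, pop, truth)
    lam = np.exp(1.0)
    p0 = 0.25 + 0.75 * nbinom.pmf(0, 1.4, 1.4 / (1.4 + lam))
    obs = (records.total_score == 0).mean()
    half = 2.576 * np.sqrt(p0 * (1 - p0) / len(records))
    assert abs(obs - p0) < half


def test_truth_ledger_roundtrip(small_study, geo21):
    records, ledger = small_study
    assert set(ledger["ward_effects"]) == set(geo21.ward_ids)
    assert len(ledger["preschool_effects"]) == 40
    # every preschool in the data has a retrievable effect and home ward
    for k in records.preschool_id.unique():
        assert int(k) in ledger["preschool_effects"]
        assert int(k) in ledger["preschool_home_ward"]
    v = np.array(list(ledger["ward_effects"].values()))
    assert v.std() == pytest.approx(np.sqrt(0.013), rel=0.8)


def test_scores_within_sdq_support(small_study):
    records, _ = small_study
    assert records.total_score.between(0, 40).all()


def test_items_consistent_with_scoring(geo21):
    """Emitted 25-item vectors score back to the recorded total."""
    pop = PopulationConfig(n_children=200, n_preschools=10, seed=3)
    records, _ = generate_children(geo21, pop, emit_items=True)
    item_map = ItemMap.default()
    cols = [f"item_{i}" for i in range(1, 26)]
    for _, row in records.head(50).iterrows():
        s = score_sdq([int(row[c]) for c in cols], item_map)
        assert s.total == int(row.total_score)


def test_exclusion_noise_identity_and_total():
    df = pd.DataFrame(dict(
        child_id=range(100), preschool_id=0, ward_id=0, cohort=2010,
        sex="female", age_months=60.0, deprivation_quintile=3,
        total_score=4.0, postcode_valid=True, in_study_area=True,
        dob_known=True))
    out, n_bad = inject_exclusion_noise(df, ExclusionRates(), seed=1)
    pd.testing.assert_frame_equal(out, df)
    assert n_bad == 0
    out, n_bad = inject_exclusion_noise(
        df, ExclusionRates(missing_score=1.0), seed=1)
    retained, _ = apply_exclusions(out)
    assert len(retained) == 0 and n_bad == 100


def test_exclusion_noise_union_matches_bruteforce(geo21):
    """Retained count equals n minus the union of flagged records,
    recomputed by an independent per-criterion set-union pass."""
    pop = PopulationConfig(n_children=10_000, n_preschools=60, seed=3)
    records, _ = generate_children(geo21, pop)
    rates = ExclusionRates(missing_dob=0.02, invalid_postcode=0.02,
                           out_of_area=0.01, out_of_age=0.01,
                           missing_score=0.05)
    out, n_bad = inject_exclusion_noise(records, rates, seed=3)
    bad = set()
    bad |= set(out.index[~out.dob_known])
    bad |= set(out.index[~out.postcode_valid])
    bad |= set(out.index[~out.in_study_area])
    bad |= set(out.index[(out.age_months < 48) | (out.age_months > 72)])
    bad |= set(out.index[out.total_score.isna()])
    retained, tally = apply_exclusions(out)
    assert len(retained) == len(out) - len(bad)
    assert n_bad == len(bad)
    assert tally["excluded"] == len(bad)


def test_contaminate_exact_count(geo21):
    pop = PopulationConfig(n_children=5000, n_preschools=40, seed=9)
    records, _ = generate_children(geo21, pop)
    out = contaminate_exact(records, n_excluded=700, seed=1)
    retained, tally = apply_exclusions(out)
    assert tally["excluded"] == 700
    assert len(retained) == 4300


def test_config_validation():
    with pytest.raises(ValueError):
        PopulationConfig(n_children=10, n_preschools=20)
    with pytest.raises(ValueError):
        TruthParams(r_overdisp=-1.0)
    with pytest.raises(ValueError):
        TruthParams(p_zero=1.0)
    with pytest.raises(ValueError):
        ExclusionRates(missing_dob=1.5)


def test_items_from_totals_caps():
    rng = np.random.default_rng(0)
    totals = np.array([0, 1, 20, 40])
    raw = items_from_totals(totals, rng)
    assert raw.shape == (4, 25)
    assert ((raw >= 0) & (raw <= 2)).all()
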