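"""Poisson disease-mapping model: oracle equivalence, recovery and
forward building."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma, poisson

from sdqmap.disease_mapping import (DMSpec, _PoissonKernel, dm_rr_summaries,
                                    fit_dm, fit_dm_median_variant,
                                    forward_build_dm)
from sdqmap.mcmc import InferenceConfig

from conftest import simulate_dm_counts


def test_poisson_kernel_matches_scipy_logpmf():
    """Likelihood code agrees with an independent log-pmf on 100 random
    (y, mu) pairs to 1e-10."""
    rng = np.random.default_rng(0)
    y = rng.integers(0, 60, 100).astype(float)
    E = rng.uniform(50, 300, 100)
    eta = rng.normal(-2.5, 0.5, 100)
    kern = _PoissonKernel(y, E)
    ours = -(kern.deviance(eta)) / 2.0
    ref = poisson.logpmf(y, E * np.exp(eta)).sum()
    assert ours == pytest.approx(ref, abs=1e-10)


def test_intercept_only_matches_gamma_poisson_conjugate():
    """Single ward, no trend, no random effects: the posterior for theta
    matches the conjugate Gamma(sum Y, sum E) closed form (the N(0,1000)
    prior on beta0 is flat over the relevant range)."""
    rng = np.random.default_rng(0)
    E = np.full(8, 200.0)
    y = rng.poisson(E * 0.08)
    counts = pd.DataFrame(dict(ward_id=0, cohort=np.arange(2010, 2018),
                               y_high=y, n_assessed=E))
    spec = DMSpec(include_trend=False, include_ward_effects=False)
    fit = fit_dm(counts, spec,
                 InferenceConfig(chains=2, warmup=800, draws=1500, seed=1))
    theta = np.exp(fit.stacked("beta")[:, 0])
    a, b = y.sum(), E.sum()
    assert theta.mean() == pytest.approx(a / b, rel=0.02)
    assert theta.std() == pytest.approx(np.sqrt(a) / b, rel=0.1)
    q = np.quantile(theta, [0.025, 0.975])
    ref = gamma.ppf([0.025, 0.975], a, scale=1 / b)
    np.testing.assert_allclose(q, ref, rtol=0.03)


def test_exposure_must_be_positive():
    counts = simulate_dm_counts(0)
    counts.loc[3, "n_assessed"] = 0.0
    with pytest.raises(ValueError, match="positive exposure"):
        fit_dm(counts)


def test_null_model_recovery_multi_seed(fast_inf):
    """No heterogeneity, no trend: the 95% CrI for exp(beta1) covers 1
    and the ward-variance posterior concentrates near zero, across seeds."""
    covered = 0
    small_var = 0
    n_seeds = 8
    for seed in range(n_seeds):
        counts = simulate_dm_counts(seed, b1=0.0, sigma2_ward=0.0)
        fit = fit_dm(counts, DMSpec(), fast_inf)
        lo, hi = np.exp(fit.ci("beta")[:, 1])
        covered += lo <= 1.0 <= hi
        small_var += fit.mean("sigma2_u0") < 0.01
    assert covered >= n_seeds - 1
    assert small_var >= n_seeds - 1


def test_offset_shift_property(fast_inf):
    """Doubling every exposure E with Y fixed shifts beta0 by -log 2 and
    leaves ward RR contrasts unchanged, within MC error."""
    counts = simulate_dm_counts(17)
    fit1 = fit_dm(counts, DMSpec(), fast_inf)
    doubled = counts.assign(n_assessed=counts.n_assessed * 2)
    fit2 = fit_dm(doubled, DMSpec(), fast_inf)
    b0_1 = fit1.mean("beta")[0]
    b0_2 = fit2.mean("beta")[0]
    assert b0_2 - b0_1 == pytest.approx(-np.log(2), abs=0.02)
    np.testing.assert_allclose(fit1.mean("u0"), fit2.mean("u0"), atol=0.06)


def test_sum_to_zero_constraint(fast_inf):
    counts = simulate_dm_counts(2)
    fit = fit_dm(counts, DMSpec(), fast_inf)
    sums = fit.stacked("u0").sum(axis=1)
    assert np.abs(sums).max() < 1e-10


def test_rr_summaries_exceedance_equals_counting(fast_inf):
    counts = simulate_dm_counts(3)
    fit = fit_dm(counts, DMSpec(), fast_inf)
    rr = dm_rr_summaries(fit, force=True)
    draws = fit.stacked("u0")
    for i, row in rr["ward"].iterrows():
        brute = float((np.exp(draws[:, i]) > 1.0).mean())
        assert row.exceedance == pytest.approx(brute, abs=1e-12)
        assert row.flag_high_certainty == (brute >= 0.8)
    # interval ordering
    assert (rr["ward"]["rr_2.5"] <= rr["ward"]["rr_97.5"]).all()


def test_summaries_withheld_when_unconverged(fast_inf):
    counts = simulate_dm_counts(4)
    fit = fit_dm(counts, DMSpec(), fast_inf)
    fit.converged = False
    with pytest.raises(RuntimeError, match="not converged"):
        dm_rr_summaries(fit)
    assert "ward" in dm_rr_summaries(fit, force=True)


def test_exceedance_degenerate_draws():
    """All-positive draws give exceedance 1; symmetric draws give ~0.5."""
    from sdqmap.mcmc import rr_table
    pos = rr_table(np.abs(np.random.default_rng(0).normal(1, 0.1, 500)),
                   ["w"])
    assert pos.exceedance.iloc[0] == 1.0
    sym = np.random.default_rng(1).normal(0, 1, 20_000)
    tab = rr_table(sym, ["w"])
    assert tab.exceedance.iloc[0] == pytest.approx(0.5, abs=0.02)


def test_forward_build_empty_candidates(fast_inf):
    counts = simulate_dm_counts(5)
    spec, ledger = forward_build_dm(counts, candidate_order=(),
                                    inference=fast_inf)
    assert len(ledger) == 1
    assert ledger.iloc[0].term == "base"
    assert spec == DMSpec()


def test_median_variant_no_heterogeneity(fast_inf):
    """Identical ward medians: the ward-variance posterior concentrates
    at ~0."""
    rows = [dict(ward_id=j, cohort=2010 + t, median_score=4.0)
            for j in range(21) for t in range(8)]
    fit = fit_dm_median_variant(pd.DataFrame(rows), DMSpec(), fast_inf)
    assert fit.mean("sigma2_u0") < 0.02
    lo, _ = fit.ci("sigma2_u0")
    assert lo < 1e-3


def test_median_variant_recovers_known_variance(fast_inf):
    errs = []
    for seed in (1, 2):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, np.sqrt(0.05), 21)
        rows = [dict(ward_id=j, cohort=2010 + t,
                     median_score=4.0 + 0.02 * t + u[j]
                     + rng.normal(0, 0.1))
                for j in range(21) for t in range(8)]
        fit = fit_dm_median_variant(pd.DataFrame(rows), DMSpec(), fast_inf)
        errs.append(float(fit.mean("sigma2_u0")) - 0.05)
    assert abs(np.mean(errs)) < 0.03


def test_median_variant_single_cohort_refuses():
    rows = [dict(ward_id=j, cohort=2010, median_score=4.0)
            for j in range(21)]
    with pytest.raises(ValueError, match="single cohort"):
        fit_dm_median_variant(pd.DataFrame(rows))


def test_spec_validation():
    with pytest.raises(ValueError):
        DMSpec(correlate_slopes=True)
    with pytest.raises(ValueError):
        DMSpec(covariates=("prop_cats",))


def test_icar_option_agrees_on_unstructured_data(geo21, fast_inf):
    """The ICAR-smoothed variant needs adjacency, and on spatially
    unstructured data its estimates agree with the exchangeable fit."""
    counts = simulate_dm_counts(5)
    fit_ex = fit_dm(counts, DMSpec(), fast_inf)
    fit_icar = fit_dm(counts, DMSpec(spatial_structure="icar"), fast_inf,
                      adjacency=geo21.adjacency)
    np.testing.assert_allclose(fit_ex.mean("beta"), fit_icar.mean("beta"),
                               atol=0.05)
    r = np.corrcoef(fit_ex.mean("u0"), fit_icar.mean("u0"))[0, 1]
    assert r > 0.9
    with pytest.raises(ValueError, match="adjacency"):
        fit_dm(counts, DMSpec(spatial_structure="icar"), fast_inf)


def test_correlated_slopes_runs(fast_inf):
    """The correlated intercept-slope variant fits and reports rho."""
    counts = simulate_dm_counts(6, sigma2_slope=0.002)
    spec = DMSpec(include_slopes=True, correlate_slopes=True)
    fit = fit_dm(counts, spec, fast_inf)
    assert "rho" in fit.posterior
    assert -1 < fit.mean("rho") < 1
    assert "ward_trend" in dm_rr_summaries(fit, force=True)
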