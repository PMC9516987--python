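"""Moran's I, permutation inference, scaled residuals and DIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, norm

from sdqmap.diagnostics import (MoranResult, aggregate_residuals_by_ward,
                                compute_dic, moran_i, moran_test,
                                randomized_pit, residual_moran_screen,
                                ScaledResidualSet)


def moran_bruteforce(x, W):
    """Naive O(n^2) double loop straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for k in range(n):
            num += W[i, k] * z[i] * z[k]
            s0 += W[i, k]
    return n / s0 * num / np.sum(z ** 2)


def test_path_graph_hand_value():
    """Path of 4 nodes with values 1..4 gives I = 1/3 (hand evaluation)."""
    W = np.zeros((4, 4))
    for a, b in [(0, 1), (1, 2), (2, 3)]:
        W[a, b] = W[b, a] = 1
    assert moran_i([1, 2, 3, 4], W) == pytest.approx(1 / 3, abs=1e-15)


def test_two_node_perfect_dissimilarity():
    W = np.array([[0, 1], [1, 0]])
    assert moran_i([1.0, -1.0], W) == pytest.approx(-1.0, abs=1e-15)


def test_constant_values_rejected():
    W = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(ValueError, match="constant"):
        moran_i([2.0, 2.0, 2.0, 2.0], W)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=3, max_value=8), st.integers(0, 10_000))
def test_bruteforce_equivalence_small_graphs(n, seed):
    """Matrix form equals the naive double loop on random connected
    graphs with n <= 8, to 1e-12."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n, n))
    for i in range(1, n):  # random spanning tree keeps it connected
        k = rng.integers(0, i)
        W[i, k] = W[k, i] = 1
    extra = rng.random((n, n)) < 0.3
    W = np.maximum(W, np.triu(extra, 1) + np.triu(extra, 1).T)
    x = rng.normal(size=n)
    assert moran_i(x, W) == pytest.approx(moran_bruteforce(x, W), abs=1e-12)


def test_moran_on_synthetic_map_matches_bruteforce(geo21):
    rng = np.random.default_rng(12)
    x = rng.normal(size=21)
    assert moran_i(x, geo21.adjacency) == pytest.approx(
        moran_bruteforce(x, geo21.adjacency), abs=1e-12)


def test_permutation_expected_value(geo21):
    """E[I] under permutation equals -1/(n-1) within MC error."""
    rng = np.random.default_rng(4)
    x = rng.normal(size=21)
    perms = [moran_i(rng.permutation(x), geo21.adjacency)
             for _ in range(3000)]
    assert np.mean(perms) == pytest.approx(-1 / 20, abs=3 * np.std(perms)
                                           / np.sqrt(3000))


def test_permutation_test_determinism_and_positive_signal(geo21):
    # deterministic given seed
    x = np.random.default_rng(1).normal(size=21)
    a = moran_test(x, geo21.adjacency, n_permutations=199, seed=5)
    b = moran_test(x, geo21.adjacency, n_permutations=199, seed=5)
    assert a.p_value == b.p_value and a.I == b.I
    assert a.expected_I == pytest.approx(-1 / 20)
    # a smooth spatial surface (ward centroid coordinate sum) is detected
    coords = np.array([np.asarray(p.centroid.coords[0])
                       for p in geo21.polygons])
    smooth = coords.sum(axis=1)
    r = moran_test(smooth, geo21.adjacency, n_permutations=999, seed=0)
    assert r.p_value <= 0.05


def test_permutation_minimum():
    with pytest.raises(ValueError):
        moran_test(np.arange(5.0), np.ones((5, 5)) - np.eye(5),
                   n_permutations=50)


def test_pit_extreme_rank():
    """An observation below every replicate has residual < 1/(n_sim+1)."""
    rng = np.random.default_rng(0)
    reps = np.full((250, 3), 10.0)
    obs = np.array([1.0, 10.0, 20.0])
    r = randomized_pit(obs, reps, rng)
    assert r[0] < 1 / 251
    assert r[2] > 250 / 251
    assert 0 < r[1] < 1  # tie broken uniformly


def test_pit_matches_gaussian_cdf():
    """For a continuous Gaussian toy model the PIT equals the analytic
    CDF transform within MC error."""
    rng = np.random.default_rng(3)
    n_obs, n_sim = 400, 2000
    obs = rng.normal(1.0, 2.0, n_obs)
    reps = rng.normal(1.0, 2.0, (n_sim, n_obs))
    r = randomized_pit(obs, reps, rng)
    analytic = norm.cdf(obs, 1.0, 2.0)
    assert np.max(np.abs(r - analytic)) < 4.0 / np.sqrt(n_sim)
    assert kstest(r, "uniform").pvalue > 0.01


def test_residual_aggregation_matches_naive_groupby():
    rng = np.random.default_rng(2)
    res = rng.random(200)
    wards = rng.integers(0, 5, 200)
    agg = aggregate_residuals_by_ward(res, wards, list(range(5)))
    for w in range(5):
        assert agg[w] == pytest.approx(res[wards == w].mean(), abs=1e-15)


def test_residual_screen_null_calibration(geo21):
    """With spatially unstructured residuals the screen stays
    non-significant in >= 95% of null replicates."""
    rng = np.random.default_rng(11)
    hits = 0
    n_rep = 60
    for k in range(n_rep):
        res = ScaledResidualSet(rng.random(210), 1, k)
        wards = np.repeat(np.arange(21), 10)
        _, decision = residual_moran_screen(
            res, wards, geo21.adjacency, ward_ids=list(range(21)),
            n_permutations=199, seed=k)
        hits += decision == "structured"
    assert hits <= 0.15 * n_rep


def test_residual_screen_detects_injected_signal(geo21):
    """Neighbour-correlated residual signal of >= 0.5 SD is flagged."""
    coords = np.array([np.asarray(p.centroid.coords[0])
                       for p in geo21.polygons])
    smooth = coords.sum(axis=1)
    smooth = (smooth - smooth.mean()) / smooth.std()
    rng = np.random.default_rng(5)
    wards = np.repeat(np.arange(21), 30)
    res = 0.5 + 0.15 * smooth[wards] + rng.normal(0, 0.05, len(wards))
    res = np.clip(res, 0.001, 0.999)
    r, decision = residual_moran_screen(
        ScaledResidualSet(res, 1, 0), wards, geo21.adjacency,
        ward_ids=list(range(21)), n_permutations=999, seed=1)
    assert decision == "structured" and r.p_value <= 0.05


def test_dic_degenerate_posterior():
    """All draws identical: pD = 0 and DIC = D(theta-bar)."""
    y = np.array([1.0, 2.0, 3.0])

    def ll(point):
        return float(-0.5 * np.sum((y - point["mu"]) ** 2))

    with pytest.warns(UserWarning):
        d = compute_dic({"mu": np.full(50, 2.0)}, ll)
    assert d["p_d"] == pytest.approx(0.0, abs=1e-12)
    assert d["dic"] == pytest.approx(d["d_hat"], abs=1e-12)


def test_dic_gaussian_conjugate_closed_form():
    """Known-variance Gaussian with conjugate normal prior: pD equals
    n * Var_post(mu) / sigma^2 and DIC follows, within MC error."""
    rng = np.random.default_rng(1)
    n, sig = 60, 1.3
    y = rng.normal(0.7, sig, n)
    s0sq = 50.0
    post_var = 1 / (n / sig ** 2 + 1 / s0sq)
    post_mean = post_var * y.sum() / sig ** 2
    draws = rng.normal(post_mean, np.sqrt(post_var), 6000)

    def ll(point):
        mu = point["mu"]
        return float(-0.5 * np.sum((y - mu) ** 2) / sig ** 2
                     - 0.5 * n * np.log(2 * np.pi * sig ** 2))

    d = compute_dic({"mu": draws}, ll)
    pd_true = n * post_var / sig ** 2
    assert d["p_d"] == pytest.approx(pd_true, abs=0.08)
    d_hat_true = -2 * ll({"mu": post_mean})
    assert d["dic"] == pytest.approx(d_hat_true + 2 * pd_true, abs=0.2)
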