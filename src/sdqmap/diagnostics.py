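"""Spatial and model-fit diagnostics shared by both models.

* Moran's I with queen adjacency, with permutation inference (21 wards is
  far too few for the normal approximation);
* simulation-based scaled residuals: randomized probability-integral-
  transform (PIT) ranks of each observation among posterior-predictive
  replicates, uniform on (0, 1) under a correctly specified model;
* a Moran screen of ward-aggregated residuals that drives the
  structured-versus-unstructured choice for the spatial effect;
* a generic Deviance Information Criterion evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import ModelFit, dic_from_deviance
from .zinb import zinb_rvs


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    p_value: float
    n_permutations: int
    seed: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def moran_i(values, W) -> float:
    """Global Moran's I with binary (non-row-standardized) weights.

    I = (n / S0) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2),  z = x - mean(x).
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(W, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("Moran's I needs at least 2 areas")
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match values")
    z = x - x.mean()
    denom = np.sum(z ** 2)
    if denom == 0.0:
        raise ValueError("values are constant; Moran's I is undefined")
    s0 = W.sum()
    return float(n / s0 * (z @ W @ z) / denom)


def moran_test(values, W, n_permutations: int = 999, seed: int = 0
               ) -> MoranResult:
    """Two-sided permutation test of H0: I = E[I] = -1/(n-1).

    p = (1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(values, dtype=float)
    n = x.size
    e_i = -1.0 / (n - 1)
    i_obs = moran_i(x, W)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        i_perm = moran_i(rng.permutation(x), W)
        if abs(i_perm - e_i) >= abs(i_obs - e_i) - 1e-15:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return MoranResult(i_obs, e_i, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# simulation-based scaled residuals


@dataclass(frozen=True)
class ScaledResidualSet:
    residuals: np.ndarray  # per observation, in (0, 1)
    n_simulations: int
    seed: int


def randomized_pit(observed: np.ndarray, replicates: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Randomized PIT rank of each observation among its replicates.

    ``replicates`` is (n_sim, n_obs). For discrete outcomes ties are broken
    uniformly within the tie interval, giving residuals that are exactly
    Uniform(0, 1) when the observations come from the same distribution as
    the replicates.
    """
    n_sim, n_obs = replicates.shape
    less = (replicates < observed[None, :]).sum(axis=0)
    equal = (replicates == observed[None, :]).sum(axis=0)
    u = rng.random(n_obs)
    return (less + u * (equal + 1)) / (n_sim + 1)


def _simulate_replicates(fit: ModelFit, data: pd.DataFrame, n_sim: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Posterior-predictive replicate matrix (n_sim, n_obs), each replicate
    drawn under an independent posterior draw."""
    if "fixed_labels" in fit.meta:
        return _replicates_ml(fit, data, n_sim, rng)
    return _replicates_dm(fit, data, n_sim, rng)


def _dm_linpred(fit: ModelFit, counts: pd.DataFrame, idx: np.ndarray):
    counts = counts.sort_values(["ward_id", "cohort"]).reset_index(drop=True)
    wards = np.asarray(fit.meta["ward_ids"])
    j = np.searchsorted(wards, counts["ward_id"].to_numpy())
    years = counts["cohort"].to_numpy()
    t = (years - years.min()).astype(float)
    cov = fit.meta["spec"]["covariates"]
    X = (counts[cov].to_numpy(float) if cov
         else np.empty((len(counts), 0)))
    beta = fit.stacked("beta")[idx]
    eta = beta[:, [0]] + beta[:, [1]] * t[None, :]
    if "u0" in fit.posterior:
        eta = eta + fit.stacked("u0")[idx][:, j]
    if X.size:
        eta = eta + (X @ beta[:, 2:].T).T
    if fit.meta["spec"]["include_slopes"]:
        u1 = fit.stacked("u1")[idx]
        eta = eta + u1[:, j] * t[None, :]
    return counts, eta


def _replicates_dm(fit: ModelFit, counts: pd.DataFrame, n_sim: int,
                   rng: np.random.Generator) -> np.ndarray:
    n_draws = fit.stacked("beta").shape[0]
    idx = rng.integers(0, n_draws, size=n_sim)
    counts_s, eta = _dm_linpred(fit, counts, idx)
    if fit.meta.get("gaussian_outcome"):
        sd = np.sqrt(fit.stacked("sigma2_e")[idx])
        return rng.normal(eta, sd[:, None])
    E = counts_s["n_assessed"].to_numpy(float)
    return rng.poisson(E[None, :] * np.exp(eta))


def _replicates_ml(fit: ModelFit, records: pd.DataFrame, n_sim: int,
                   rng: np.random.Generator) -> np.ndarray:
    from .multilevel import MLSpec, design_matrix

    spec_d = fit.meta["spec"]
    spec = MLSpec(include_preschool=spec_d["include_preschool"],
                  include_slopes=spec_d["include_slopes"],
                  covariates=tuple(spec_d["covariates"]),
                  zero_inflation=spec_d["zero_inflation"])
    _, X = design_matrix(records, spec)
    wards = np.asarray(fit.meta["ward_ids"])
    j = np.searchsorted(wards, records["ward_id"].to_numpy())
    years = records["cohort"].to_numpy()
    t = (years - years.min()).astype(float)

    n_draws = fit.stacked("v0").shape[0]
    idx = rng.integers(0, n_draws, size=n_sim)
    beta = fit.stacked("beta")[idx]
    eta = beta[:, [0]] + beta[:, [1]] * t[None, :]
    if X.size:
        eta = eta + (X @ beta[:, 2:].T).T
    eta = eta + fit.stacked("v0")[idx][:, j]
    if spec.include_preschool:
        pres = np.asarray(fit.meta["preschool_ids"])
        k = np.searchsorted(pres, records["preschool_id"].to_numpy())
        eta = eta + fit.stacked("alpha")[idx][:, k]
    if spec.include_slopes:
        eta = eta + fit.stacked("v1")[idx][:, j] * t[None, :]
    p_draws = (fit.stacked("p")[idx] if spec.zero_inflation
               else np.zeros(n_sim))
    r_draws = fit.stacked("r")[idx]
    out = np.empty_like(eta)
    for s in range(n_sim):
        out[s] = zinb_rvs(np.exp(eta[s]), float(p_draws[s]),
                          float(r_draws[s]), rng)
    return out


def scaled_residuals(fit: ModelFit, data: pd.DataFrame,
                     n_simulations: int = 250, seed: int = 0
                     ) -> ScaledResidualSet:
    """DHARMa-style scaled residuals for a fitted model.

    For each observation, ``n_simulations`` posterior-predictive replicates
    are drawn (each under a fresh posterior draw) and the randomized PIT
    rank of the observed value among them is returned.
    """
    rng = np.random.default_rng(seed)
    reps = _simulate_replicates(fit, data, n_simulations, rng)
    if "fixed_labels" in fit.meta:
        obs = data["total_score"].to_numpy(float)
    elif fit.meta.get("gaussian_outcome"):
        obs = data.sort_values(["ward_id", "cohort"]
                               )["median_score"].to_numpy(float)
    else:
        obs = data.sort_values(["ward_id", "cohort"]
                               )["y_high"].to_numpy(float)
    res = randomized_pit(obs, reps, rng)
    return ScaledResidualSet(res, n_simulations, seed)


def aggregate_residuals_by_ward(residuals: np.ndarray, ward_of_obs,
                                ward_ids) -> np.ndarray:
    """Mean scaled residual per ward, ordered as ``ward_ids``."""
    ward_of_obs = np.asarray(ward_of_obs)
    out = np.empty(len(ward_ids))
    for i, w in enumerate(ward_ids):
        mask = ward_of_obs == w
        if not mask.any():
            raise ValueError(f"no observations map to ward {w}")
        out[i] = residuals[mask].mean()
    return out


def residual_moran_screen(residuals: ScaledResidualSet, ward_of_obs,
                          W, ward_ids=None, n_permutations: int = 999,
                          seed: int = 0, alpha: float = 0.05):
    """Moran test of ward-aggregated scaled residuals.

    Returns ``(MoranResult, decision)`` where decision is "structured"
    when spatial correlation is detected at level ``alpha`` (a spatially
    structured random effect would then be warranted) and "unstructured"
    otherwise.
    """
    if ward_ids is None:
        ward_ids = np.unique(np.asarray(ward_of_obs))
    agg = aggregate_residuals_by_ward(residuals.residuals, ward_of_obs,
                                      ward_ids)
    result = moran_test(agg, W, n_permutations=n_permutations, seed=seed)
    decision = "structured" if result.significant(alpha) else "unstructured"
    return result, decision


# ---------------------------------------------------------------------------
# DIC


def compute_dic(draws: dict[str, np.ndarray], loglik) -> dict[str, float]:
    """DIC from posterior draws and a pointwise log-likelihood evaluator.

    ``draws`` maps parameter names to (n_draws, ...) arrays; ``loglik``
    takes a {name: value} point and returns the total log-likelihood.
    D(theta) = -2 log L(theta); pD = D-bar - D(theta-bar); DIC = D-bar + pD.
    """
    import warnings

    names = list(draws)
    n = len(draws[names[0]])
    if n < 100:
        warnings.warn(f"only {n} draws: pD estimate may be unstable")
    dev = np.array([
        -2.0 * loglik({k: draws[k][i] for k in names}) for i in range(n)
    ])
    at_mean = -2.0 * loglik({k: np.mean(draws[k], axis=0) for k in names})
    return dic_from_deviance(dev, at_mean)
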