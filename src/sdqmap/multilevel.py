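"""Bayesian zero-inflated negative-binomial multilevel model of individual
SDQ total-difficulties scores.

Each child i, attending preschool k and living in ward j, has

    Y_ijk ~ ZINB(lambda_ijk, p, r)
    log lambda_ijk = beta0 + (beta1 + v1_j) * t + alpha_k + v0_j
                     + beta_phi' x_i

with cohort index t, preschool effects alpha_k ~ N(0, sigma2_preschool)
and ward effects v0_j ~ N(0, sigma2_ward) estimated as cross-classified
(a preschool draws children from more than one ward, so the factors are
crossed, not nested). Individual covariates are sex, age centred on 59
months and squared, and deprivation quintile as four dummies against the
least-deprived reference. The zero-inflation probability p and
overdispersion r are global scalars; the zero inflation is a structural-
zero mixture, not a hurdle.

Priors: N(0, 1000) fixed effects, Gamma(1, 0.0005) on random-effect
precisions, uniform on p, and a diffuse Gamma(1, 0.01) on r. Inference is
adaptive Metropolis-within-Gibbs with vectorized per-group updates (each
group's full conditional is independent given the rest); effects are
reported sum-to-zero with the mean folded into the intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .disease_mapping import PriorConfig
from .mcmc import (AdaptiveScale, InferenceConfig, ModelFit,
                   asis_rescale_logpost_delta, dic_from_deviance,
                   rhat_summary, rr_table, sample_precision)

logger = logging.getLogger(__name__)

ML_COVARIATES = ("sex", "age_centred_squared", "deprivation")
ML_BUILD_ORDER = ("preschool", "slopes", "age_centred_squared", "sex",
                  "deprivation")
AGE_CENTRE_MONTHS = 59.0

#: prior on the NB overdispersion r (shape, rate) — diffuse over (0, ~300)
R_PRIOR = (1.0, 0.01)


@dataclass(frozen=True)
class MLSpec:
    include_preschool: bool = True
    include_slopes: bool = False
    covariates: tuple[str, ...] = ()
    zero_inflation: bool = True
    prior_config: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(ML_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def design_matrix(records: pd.DataFrame, spec: MLSpec):
    """Fixed-effect design beyond intercept + cohort: (labels, X)."""
    cols, labels = [], []
    for cov in spec.covariates:
        if cov == "sex":
            cols.append((records["sex"] == "male").to_numpy(float))
            labels.append("male")
        elif cov == "age_centred_squared":
            a = records["age_months"].to_numpy(float) - AGE_CENTRE_MONTHS
            cols.append(a ** 2)
            labels.append("age_centred_squared")
        elif cov == "deprivation":
            q = records["deprivation_quintile"].to_numpy(int)
            # dummies vs least deprived (quintile 5), most deprived last
            for lev in (4, 3, 2, 1):
                cols.append((q == lev).astype(float))
                labels.append(f"dep_q{lev}")
    X = np.column_stack(cols) if cols else np.empty((len(records), 0))
    return labels, X


class _ZINBKernel:
    """Cached per-child ZINB log-likelihood for MCMC updates.

    Maintains the NB part as a vector so that updating p is O(n) without
    re-evaluating gamma functions, and group updates touch only changed
    rows.
    """

    def __init__(self, y: np.ndarray, zero_inflation: bool):
        self.y = y.astype(float)
        self.zero = self.y == 0
        self.gl_y1 = gammaln(self.y + 1.0)
        self.zero_inflation = zero_inflation

    def nb_vec(self, eta: np.ndarray, r: float) -> np.ndarray:
        lam = np.exp(eta)
        return (gammaln(self.y + r) - gammaln(r) - self.gl_y1
                + r * np.log(r) - (r + self.y) * np.log(r + lam)
                + self.y * eta)

    def combine(self, nb: np.ndarray, p: float) -> np.ndarray:
        if not self.zero_inflation or p == 0.0:
            return nb
        l1mp = np.log1p(-p)
        out = l1mp + nb
        out[self.zero] = np.logaddexp(np.log(p), out[self.zero])
        return out

    def deviance(self, eta: np.ndarray, p: float, r: float) -> float:
        return -2.0 * float(self.combine(self.nb_vec(eta, r), p).sum())


def _run_chain_ml(kern: _ZINBKernel, t, k_idx, j_idx, X, spec: MLSpec,
                  prior: PriorConfig, n_pre: int, n_wards: int,
                  warmup: int, draws: int, rng: np.random.Generator):
    n = len(t)
    K = X.shape[1]
    b_var = prior.fixed_effect_var

    beta = np.zeros(2 + K)
    beta[0] = np.log(kern.y.mean() + 0.5)
    beta += rng.normal(0, 0.05, beta.shape)
    alpha = rng.normal(0, 0.05, n_pre) if spec.include_preschool else \
        np.zeros(n_pre)
    v0 = rng.normal(0, 0.05, n_wards) if n_wards > 1 else np.zeros(n_wards)
    v1 = np.zeros(n_wards)
    tau_a = tau_v0 = tau_v1 = 20.0
    p = 0.10 if spec.zero_inflation else 0.0
    r = 2.0

    # centred design columns for the fixed-effect updates (converted back
    # at storage); random-slope terms keep the raw cohort index
    mt = t.mean()
    mX = X.mean(axis=0) if K else np.zeros(0)
    tc = t - mt
    Xc = X - mX
    cols = [np.ones(n), tc] + [Xc[:, c] for c in range(K)]
    eta = (beta[0] + beta[1] * tc + alpha[k_idx] + v0[j_idx]
           + Xc @ beta[2:])
    nb = kern.nb_vec(eta, r)
    use_ward = n_wards > 1

    sc_beta = AdaptiveScale(2 + K, init=0.05)
    sc_a = AdaptiveScale(n_pre, init=0.2)
    sc_v = AdaptiveScale(n_wards, init=0.1)
    sc_s = AdaptiveScale(n_wards, init=0.03)
    sc_pr = AdaptiveScale(2, init=0.1)  # logit p, log r
    sc_asis = AdaptiveScale(3, init=0.8)  # interweaving rescale moves

    def _rescale(u, tau, idx, mult, scale, eta, nb, ll_sum):
        # non-centred MH on log sigma^2 with z = u / sigma held fixed;
        # breaks the variance-effects funnel (see disease_mapping)
        x = -np.log(tau)
        x_new = x + rng.normal(0, scale)
        c = np.exp(0.5 * (x_new - x))
        eta_new = eta + (c - 1.0) * u[idx] * mult
        nb_new = kern.nb_vec(eta_new, r)
        dlp = (kern.combine(nb_new, p).sum() - ll_sum
               + asis_rescale_logpost_delta(x, x_new,
                                            prior.precision_shape,
                                            prior.precision_rate))
        if np.log(rng.random()) < dlp:
            return u * c, float(np.exp(-x_new)), eta_new, nb_new, True
        return u, tau, eta, nb, False

    out = {q: [] for q in ("beta", "alpha", "v0", "v1", "sigma2_preschool",
                           "sigma2_ward", "sigma2_slope", "p", "r",
                           "deviance")}

    for it in range(warmup + draws):
        adapting = it < warmup
        ll_cur = kern.combine(nb, p)
        acc_asis = np.zeros(3)

        acc = np.zeros(2 + K)
        for i in range(2 + K):
            d = rng.normal(0, sc_beta.scale[i])
            eta_p = eta + d * cols[i]
            nb_p = kern.nb_vec(eta_p, r)
            dlp = (kern.combine(nb_p, p).sum() - ll_cur.sum()
                   - 0.5 * ((beta[i] + d) ** 2 - beta[i] ** 2) / b_var)
            if np.log(rng.random()) < dlp:
                beta[i] += d
                eta, nb = eta_p, nb_p
                ll_cur = kern.combine(nb, p)
                acc[i] = 1
        if adapting:
            sc_beta.update(acc)

        if spec.include_preschool:
            d = rng.normal(0, sc_a.scale)
            eta_p = eta + d[k_idx]
            nb_p = kern.nb_vec(eta_p, r)
            dll = np.bincount(k_idx,
                              weights=kern.combine(nb_p, p) - ll_cur,
                              minlength=n_pre)
            dpr = -0.5 * tau_a * ((alpha + d) ** 2 - alpha ** 2)
            ok = np.log(rng.random(n_pre)) < dll + dpr
            alpha = np.where(ok, alpha + d, alpha)
            rows = ok[k_idx]
            eta = np.where(rows, eta_p, eta)
            nb = np.where(rows, nb_p, nb)
            ll_cur = kern.combine(nb, p)
            if adapting:
                sc_a.update(ok)
            tau_a = sample_precision(alpha, rng, prior.precision_shape,
                                     prior.precision_rate)
            alpha, tau_a, eta, nb, ok1 = _rescale(
                alpha, tau_a, k_idx, 1.0, sc_asis.scale[0], eta, nb,
                ll_cur.sum())
            acc_asis[0] = ok1
            if ok1:
                ll_cur = kern.combine(nb, p)

        if use_ward:
            d = rng.normal(0, sc_v.scale)
            eta_p = eta + d[j_idx]
            nb_p = kern.nb_vec(eta_p, r)
            dll = np.bincount(j_idx,
                              weights=kern.combine(nb_p, p) - ll_cur,
                              minlength=n_wards)
            dpr = -0.5 * tau_v0 * ((v0 + d) ** 2 - v0 ** 2)
            ok = np.log(rng.random(n_wards)) < dll + dpr
            v0 = np.where(ok, v0 + d, v0)
            rows = ok[j_idx]
            eta = np.where(rows, eta_p, eta)
            nb = np.where(rows, nb_p, nb)
            ll_cur = kern.combine(nb, p)
            if adapting:
                sc_v.update(ok)
            tau_v0 = sample_precision(v0, rng, prior.precision_shape,
                                      prior.precision_rate)
            v0, tau_v0, eta, nb, ok1 = _rescale(
                v0, tau_v0, j_idx, 1.0, sc_asis.scale[1], eta, nb,
                ll_cur.sum())
            acc_asis[1] = ok1
            if ok1:
                ll_cur = kern.combine(nb, p)

        if spec.include_slopes and use_ward:
            d = rng.normal(0, sc_s.scale)
            eta_p = eta + d[j_idx] * t
            nb_p = kern.nb_vec(eta_p, r)
            dll = np.bincount(j_idx,
                              weights=kern.combine(nb_p, p) - ll_cur,
                              minlength=n_wards)
            dpr = -0.5 * tau_v1 * ((v1 + d) ** 2 - v1 ** 2)
            ok = np.log(rng.random(n_wards)) < dll + dpr
            v1 = np.where(ok, v1 + d, v1)
            rows = ok[j_idx]
            eta = np.where(rows, eta_p, eta)
            nb = np.where(rows, nb_p, nb)
            ll_cur = kern.combine(nb, p)
            if adapting:
                sc_s.update(ok)
            tau_v1 = sample_precision(v1, rng, prior.precision_shape,
                                      prior.precision_rate)
            v1, tau_v1, eta, nb, ok1 = _rescale(
                v1, tau_v1, j_idx, t, sc_asis.scale[2], eta, nb,
                ll_cur.sum())
            acc_asis[2] = ok1
            if ok1:
                ll_cur = kern.combine(nb, p)
        if adapting:
            sc_asis.update(acc_asis)

        acc2 = np.zeros(2)
        if spec.zero_inflation:
            x = logit(p) + rng.normal(0, sc_pr.scale[0])
            p_new = float(expit(x))
            # uniform prior on p with logit Jacobian
            dlp = (kern.combine(nb, p_new).sum() - ll_cur.sum()
                   + np.log(p_new * (1 - p_new)) - np.log(p * (1 - p)))
            if np.log(rng.random()) < dlp:
                p = p_new
                ll_cur = kern.combine(nb, p)
                acc2[0] = 1

        lx = np.log(r) + rng.normal(0, sc_pr.scale[1])
        r_new = float(np.exp(lx))
        nb_new = kern.nb_vec(eta, r_new)
        a_r, b_r = R_PRIOR
        dlp = (kern.combine(nb_new, p).sum() - ll_cur.sum()
               + a_r * (np.log(r_new) - np.log(r)) - b_r * (r_new - r))
        if np.log(rng.random()) < dlp:
            r, nb = r_new, nb_new
            acc2[1] = 1
        if adapting:
            sc_pr.update(acc2)

        if it >= warmup:
            # convert to the uncentred design; report sum-to-zero effects
            # with their means folded into intercept/trend
            b = beta.copy()
            a_c, v0_c, v1_c = alpha, v0, v1
            shift = 0.0
            if spec.include_preschool:
                ma = alpha.mean()
                shift += ma
                a_c = alpha - ma
            if use_ward:
                mv = v0.mean()
                shift += mv
                v0_c = v0 - mv
            if spec.include_slopes and use_ward:
                ms = v1.mean()
                b[1] = beta[1] + ms
                v1_c = v1 - ms
            b[0] = beta[0] + shift - beta[1] * mt - beta[2:] @ mX
            out["beta"].append(b)
            out["alpha"].append(a_c)
            out["v0"].append(v0_c)
            out["v1"].append(v1_c)
            out["sigma2_preschool"].append(1.0 / tau_a)
            out["sigma2_ward"].append(1.0 / tau_v0)
            out["sigma2_slope"].append(1.0 / tau_v1)
            out["p"].append(p)
            out["r"].append(r)
            out["deviance"].append(kern.deviance(eta, p, r))
    return {q: np.asarray(v) for q, v in out.items()}


def fit_ml(records: pd.DataFrame, spec: MLSpec | None = None,
           inference: InferenceConfig | None = None) -> ModelFit:
    """Fit the cross-classified ZINB multilevel model to child records."""
    spec = spec or MLSpec()
    inference = inference or InferenceConfig()
    req = {"total_score", "ward_id", "preschool_id", "cohort"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records["total_score"].isna().any():
        raise ValueError("records must be filtered (no missing scores)")
    y = records["total_score"].to_numpy(float)
    if np.all(y == 0):
        raise ValueError("all scores are zero: the zero-inflation "
                         "component is unidentifiable")

    wards = np.sort(records["ward_id"].unique())
    pres = np.sort(records["preschool_id"].unique())
    if len(pres) < 2 and spec.include_preschool:
        logger.warning("fewer than 2 preschools: preschool effect excluded")
        spec = replace(spec, include_preschool=False)
    if len(wards) < 2:
        logger.warning("fewer than 2 wards: ward variance excluded")
    j_idx = np.searchsorted(wards, records["ward_id"].to_numpy())
    k_idx = np.searchsorted(pres, records["preschool_id"].to_numpy())
    years = records["cohort"].to_numpy()
    t = (years - years.min()).astype(float)
    if spec.include_slopes and len(np.unique(years)) < 2:
        raise ValueError("random slopes need at least 2 cohorts")

    labels, X = design_matrix(records, spec)
    kern = _ZINBKernel(y, spec.zero_inflation)

    ss = np.random.SeedSequence(inference.seed)
    chains_out = [
        _run_chain_ml(kern, t, k_idx, j_idx, X, spec, spec.prior_config,
                      len(pres), len(wards), inference.warmup,
                      inference.draws, np.random.default_rng(s))
        for s in ss.spawn(inference.chains)
    ]

    names = ["beta", "v0", "sigma2_ward", "r", "deviance"]
    if spec.include_preschool:
        names += ["alpha", "sigma2_preschool"]
    if spec.include_slopes:
        names += ["v1", "sigma2_slope"]
    if spec.zero_inflation:
        names += ["p"]
    posterior = {q: np.stack([c[q] for c in chains_out]) for q in names}
    deviance = posterior.pop("deviance")

    # conditional DIC: plug in posterior means of effects, p and r
    mb = posterior["beta"].reshape(-1, 2 + X.shape[1]).mean(0)
    eta_hat = mb[0] + mb[1] * t + X @ mb[2:]
    if spec.include_preschool:
        eta_hat = eta_hat + posterior["alpha"].reshape(-1, len(pres)
                                                       ).mean(0)[k_idx]
    eta_hat = eta_hat + posterior["v0"].reshape(-1, len(wards)).mean(0)[j_idx]
    if spec.include_slopes:
        eta_hat = eta_hat + posterior["v1"].reshape(-1, len(wards)
                                                    ).mean(0)[j_idx] * t
    p_hat = float(posterior["p"].mean()) if spec.zero_inflation else 0.0
    r_hat = float(posterior["r"].mean())
    dic = dic_from_deviance(deviance, kern.deviance(eta_hat, p_hat, r_hat))

    diagnostics = rhat_summary(posterior)
    converged = max(diagnostics.values()) < inference.rhat_threshold
    meta = {"ward_ids": [int(w) for w in wards],
            "preschool_ids": [int(q) for q in pres],
            "fixed_labels": ["intercept", "cohort"] + labels,
            "spec": {"include_preschool": spec.include_preschool,
                     "include_slopes": spec.include_slopes,
                     "covariates": list(spec.covariates),
                     "zero_inflation": spec.zero_inflation}}
    return ModelFit(posterior, deviance, dic, diagnostics, converged, meta)


def ml_rr_summaries(fit: ModelFit, force: bool = False
                    ) -> dict[str, pd.DataFrame]:
    """RR tables: fixed effects, per-ward exp(v0j), per-preschool
    exp(alpha_k) (and per-ward trend when slopes were fitted)."""
    if not fit.converged and not force:
        raise RuntimeError(
            f"fit not converged (max R-hat {fit.max_rhat:.3f}); "
            "pass force=True to summarise anyway")
    out = {"fixed": rr_table(fit.stacked("beta"), fit.meta["fixed_labels"]),
           "ward": rr_table(fit.stacked("v0"), fit.meta["ward_ids"])}
    if fit.meta["spec"]["include_preschool"]:
        out["preschool"] = rr_table(fit.stacked("alpha"),
                                    fit.meta["preschool_ids"])
    if fit.meta["spec"]["include_slopes"]:
        out["ward_trend"] = rr_table(fit.stacked("v1"),
                                     fit.meta["ward_ids"])
    return out


def forward_build_ml(records: pd.DataFrame,
                     candidate_order=ML_BUILD_ORDER,
                     inference: InferenceConfig | None = None,
                     keep_tol: float = 1.0):
    """DIC-driven forward build for the multilevel model.

    The base model has intercept, cohort trend and a ward effect. The
    preschool effect and random slopes are retained only when they lower
    DIC by more than ``keep_tol``; covariates are retained unless their
    removal lowers DIC by more than ``keep_tol``.
    """
    inference = inference or InferenceConfig()
    spec = MLSpec(include_preschool=False)
    fit = fit_ml(records, spec, inference)
    rows = [{"step": 0, "term": "base", "dic_without": np.nan,
             "dic_with": fit.dic["dic"], "retained": True,
             "converged": fit.converged}]
    dic_current = fit.dic["dic"]
    for step, term in enumerate(candidate_order, start=1):
        if term == "preschool":
            trial = replace(spec, include_preschool=True)
        elif term == "slopes":
            trial = replace(spec, include_slopes=True)
        else:
            trial = replace(spec, covariates=spec.covariates + (term,))
        trial_fit = fit_ml(records, trial, inference)
        if not trial_fit.converged:
            rows.append({"step": step, "term": term,
                         "dic_without": dic_current, "dic_with": np.nan,
                         "retained": False, "converged": False})
            continue
        dic_with = trial_fit.dic["dic"]
        if term in ("preschool", "slopes"):
            retained = dic_with < dic_current - keep_tol
        else:
            retained = dic_with <= dic_current + keep_tol
        rows.append({"step": step, "term": term, "dic_without": dic_current,
                     "dic_with": dic_with, "retained": retained,
                     "converged": True})
        if retained:
            spec = trial
            dic_current = dic_with
    return spec, pd.DataFrame(rows)
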