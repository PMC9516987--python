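"""Bayesian Poisson disease mapping of ward-year high-score counts.

The count of children with a high total-difficulties score (>= 15) in ward
``j`` and cohort ``t`` is modelled as

    Y_jt ~ Poisson(E_jt * theta_jt)
    log theta_jt = beta0 + (beta1 + u1_j) * t + u0_j + sum_k betak * x_jkt

with the number of assessed children E_jt as exposure, a linear cohort
trend beta1 common to all wards, exchangeable (unstructured) ward
intercepts u0_j ~ N(0, sigma2_u0) and optional differential trends
(random slopes) u1_j ~ N(0, sigma2_u1), possibly correlated with the
intercepts. Ward-level covariates x are the proportions of children
outside the expected school-start age, of boys, and in the most deprived
quintile. exp(beta0) is the baseline high-score rate in the first cohort;
exp(u0_j) is the ward's relative rate (RR) against the city average.

Priors are weakly informative: N(0, 1000) on fixed effects and
Gamma(1, 0.0005) on each random-effect precision. Inference is adaptive
Metropolis-within-Gibbs (see :mod:`sdqmap.mcmc`); unstructured effects are
the default because residual spatial correlation screens (Moran's I) drive
the structure choice upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .mcmc import (AdaptiveScale, InferenceConfig, ModelFit,
                   asis_rescale_logpost_delta, dic_from_deviance,
                   rhat_summary, rr_table, sample_precision)

DM_COVARIATES = ("prop_off_age", "prop_most_deprived", "prop_boys")
#: order in which terms enter the forward build
DM_BUILD_ORDER = ("slopes", "prop_off_age", "prop_most_deprived",
                  "prop_boys")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative default priors."""

    fixed_effect_var: float = 1000.0
    precision_shape: float = 1.0
    precision_rate: float = 0.0005

    def __post_init__(self) -> None:
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("precision prior shape and rate must be > 0")


@dataclass(frozen=True)
class DMSpec:
    include_trend: bool = True
    include_slopes: bool = False
    correlate_slopes: bool = False
    include_ward_effects: bool = True
    #: "exchangeable" (default; residual Moran screens found no spatial
    #: correlation) or "icar" — intrinsic CAR smoothing of the ward
    #: intercepts toward their queen neighbours (requires adjacency)
    spatial_structure: str = "exchangeable"
    covariates: tuple[str, ...] = ()
    prior_config: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.correlate_slopes and not self.include_slopes:
            raise ValueError("correlate_slopes requires include_slopes")
        if self.include_slopes and not self.include_trend:
            raise ValueError("random slopes require the cohort trend")
        if self.spatial_structure not in ("exchangeable", "icar"):
            raise ValueError(
                f"unknown spatial_structure {self.spatial_structure!r}")
        if self.spatial_structure == "icar" and self.correlate_slopes:
            raise ValueError("correlated slopes are only supported with "
                             "exchangeable intercepts")
        unknown = set(self.covariates) - set(DM_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


def _prepare(counts: pd.DataFrame, spec: DMSpec, outcome: str = "y_high"):
    counts = counts.sort_values(["ward_id", "cohort"]).reset_index(drop=True)
    wards = np.sort(counts["ward_id"].unique())
    j = np.searchsorted(wards, counts["ward_id"].to_numpy())
    years = counts["cohort"].to_numpy()
    if spec.include_trend and len(np.unique(years)) < 2:
        raise ValueError("a linear cohort trend is unidentifiable with a "
                         "single cohort of data")
    t = (years - years.min()).astype(float)
    X = (counts[list(spec.covariates)].to_numpy(dtype=float)
         if spec.covariates else np.empty((len(counts), 0)))
    y = counts[outcome].to_numpy(dtype=float)
    return counts, wards, j, t, X, y


def _gauss_bvn_logpdf(u0, u1, v0, v1, rho):
    det = v0 * v1 * (1 - rho ** 2)
    q = (u0 ** 2 / v0 - 2 * rho * u0 * u1 / np.sqrt(v0 * v1)
         + u1 ** 2 / v1) / (1 - rho ** 2)
    return -0.5 * (np.log(2 * np.pi) * 2 + np.log(det) + q).sum()


class _PoissonKernel:
    """Log-likelihood pieces for Y ~ Poisson(E * exp(eta))."""

    def __init__(self, y, E):
        self.y, self.E = y, E
        self.const = float(np.sum(y * np.log(E) - gammaln(y + 1)))

    def ll(self, eta):
        return float(np.sum(self.y * eta - self.E * np.exp(eta)))

    def delta_cells(self, eta, eta_new):
        return (self.y * (eta_new - eta)
                - self.E * (np.exp(eta_new) - np.exp(eta)))

    def delta_cells_at(self, idx, eta_old, eta_new):
        return np.sum(self.y[idx] * (eta_new - eta_old)
                      - self.E[idx] * (np.exp(eta_new) - np.exp(eta_old)))

    def deviance(self, eta):
        return -2.0 * (self.ll(eta) + self.const)


class _GaussKernel:
    """Log-likelihood pieces for Y ~ N(eta, 1/tau_e); tau_e sampled by
    conjugate Gibbs outside."""

    def __init__(self, y, E=None):
        self.y = y
        self.tau_e = 1.0

    def ll(self, eta):
        return float(-0.5 * self.tau_e * np.sum((self.y - eta) ** 2))

    def delta_cells(self, eta, eta_new):
        return -0.5 * self.tau_e * ((self.y - eta_new) ** 2
                                    - (self.y - eta) ** 2)

    def delta_cells_at(self, idx, eta_old, eta_new):
        return np.sum(-0.5 * self.tau_e * ((self.y[idx] - eta_new) ** 2
                                           - (self.y[idx] - eta_old) ** 2))

    def deviance(self, eta):
        n = self.y.size
        return -2.0 * (self.ll(eta)
                       + 0.5 * n * (np.log(self.tau_e) - np.log(2 * np.pi)))


def _run_chain(kernel, j, t, X, spec: DMSpec, prior: PriorConfig,
               n_wards: int, warmup: int, draws: int,
               rng: np.random.Generator, gaussian: bool, W=None):
    ncell = len(t)
    K = X.shape[1]
    b_var = prior.fixed_effect_var

    use_trend = spec.include_trend
    use_ward = spec.include_ward_effects and n_wards >= 2

    beta = np.zeros(2 + K)
    if not gaussian:
        beta[0] = np.log(max(kernel.y.sum(), 1.0) / kernel.E.sum())
    else:
        beta[0] = float(np.mean(kernel.y))
    beta += rng.normal(0, 0.1, size=beta.shape)
    if not use_trend:
        beta[1] = 0.0
    u0 = rng.normal(0, 0.05, n_wards) if use_ward else np.zeros(n_wards)
    u1 = np.zeros(n_wards)
    tau0, tau1 = 10.0, 10.0
    rho = 0.0

    # sample against centred design columns (intercept decorrelated from
    # trend/covariates); draws are converted back when stored
    mt = t.mean()
    mX = X.mean(axis=0) if K else np.zeros(0)
    tc = t - mt
    Xc = X - mX
    cols = [np.ones(ncell), tc] + [Xc[:, k] for k in range(K)]
    eta = beta[0] + beta[1] * tc + u0[j] + Xc @ beta[2:]
    if spec.include_slopes:
        eta = eta + u1[j] * t

    sc_beta = AdaptiveScale(2 + K, init=0.1)
    sc_u0 = AdaptiveScale(n_wards, init=0.1)
    sc_u1 = AdaptiveScale(n_wards, init=0.05)
    sc_var = AdaptiveScale(3, init=0.3)  # correlated-slope variance block
    sc_asis = AdaptiveScale(2, init=0.8)  # interweaving rescale moves

    out = {k: [] for k in ("beta", "u0", "u1", "sigma2_u0", "sigma2_u1",
                           "rho", "deviance", "sigma2_e")}

    for it in range(warmup + draws):
        adapting = it < warmup
        if gaussian:
            # conjugate Gibbs for the observation precision
            resid = kernel.y - eta
            kernel.tau_e = rng.gamma(
                prior.precision_shape + 0.5 * ncell,
                1.0 / (prior.precision_rate + 0.5 * np.sum(resid ** 2)))

        # fixed effects, coordinate-wise
        acc = np.zeros(2 + K)
        for i in range(2 + K):
            if i == 1 and not use_trend:
                continue
            d = rng.normal(0, sc_beta.scale[i])
            eta_new = eta + d * cols[i]
            dlp = (kernel.ll(eta_new) - kernel.ll(eta)
                   - 0.5 * ((beta[i] + d) ** 2 - beta[i] ** 2) / b_var)
            if np.log(rng.random()) < dlp:
                beta[i] += d
                eta = eta_new
                acc[i] = 1
        if adapting:
            sc_beta.update(acc)

        # ward intercepts under the ICAR prior: full conditionals depend
        # on neighbours, so wards update sequentially
        if use_ward and spec.spatial_structure == "icar":
            deg = W.sum(axis=1)
            cell_lists = [np.nonzero(j == w)[0] for w in range(n_wards)]
            acc_w = np.zeros(n_wards)
            for w in range(n_wards):
                d1 = rng.normal(0, sc_u0.scale[w])
                cells = cell_lists[w]
                eta_w = eta[cells]
                dll = float(kernel.delta_cells_at(cells, eta_w,
                                                  eta_w + d1))
                dpr = -0.5 * tau0 * (d1 ** 2 * deg[w] + 2 * d1
                                     * float(W[w] @ (u0[w] - u0)))
                if np.log(rng.random()) < dll + dpr:
                    u0[w] += d1
                    eta[cells] = eta_w + d1
                    acc_w[w] = 1
            if adapting:
                sc_u0.update(acc_w)
            pair_ss = 0.5 * float(
                (W * (u0[:, None] - u0[None, :]) ** 2).sum())
            tau0 = float(rng.gamma(
                prior.precision_shape + 0.5 * (n_wards - 1),
                1.0 / (prior.precision_rate + 0.5 * pair_ss)))

        # exchangeable ward intercepts: independent full conditionals,
        # vectorized MH
        if use_ward and spec.spatial_structure == "exchangeable":
            d = rng.normal(0, sc_u0.scale)
            eta_new = eta + d[j]
            dll = np.bincount(j, weights=kernel.delta_cells(eta, eta_new),
                              minlength=n_wards)
            if spec.correlate_slopes:
                s0, s1 = 1.0 / tau0, 1.0 / tau1
                dpr = np.array([
                    _gauss_bvn_logpdf(u0[w] + d[w], u1[w], s0, s1, rho)
                    - _gauss_bvn_logpdf(u0[w], u1[w], s0, s1, rho)
                    for w in range(n_wards)])
            else:
                dpr = -0.5 * tau0 * ((u0 + d) ** 2 - u0 ** 2)
            accept = np.log(rng.random(n_wards)) < dll + dpr
            u0 = np.where(accept, u0 + d, u0)
            eta = eta + np.where(accept, d, 0.0)[j]
            if adapting:
                sc_u0.update(accept)

        if spec.include_slopes and use_ward:
            d = rng.normal(0, sc_u1.scale)
            eta_new = eta + d[j] * t
            dll = np.bincount(j, weights=kernel.delta_cells(eta, eta_new),
                              minlength=n_wards)
            if spec.correlate_slopes:
                s0, s1 = 1.0 / tau0, 1.0 / tau1
                dpr = np.array([
                    _gauss_bvn_logpdf(u0[w], u1[w] + d[w], s0, s1, rho)
                    - _gauss_bvn_logpdf(u0[w], u1[w], s0, s1, rho)
                    for w in range(n_wards)])
            else:
                dpr = -0.5 * tau1 * ((u1 + d) ** 2 - u1 ** 2)
            accept = np.log(rng.random(n_wards)) < dll + dpr
            u1 = np.where(accept, u1 + d, u1)
            eta = eta + (np.where(accept, d, 0.0)[j] * t)
            if adapting:
                sc_u1.update(accept)

        # variance components: conjugate Gibbs, then an interweaving
        # rescale move (non-centred MH on log sigma^2 with the scaled
        # effects z = u / sigma held fixed) to break the variance-effects
        # funnel
        if not spec.correlate_slopes and use_ward:
            acc_asis = np.zeros(2)

            def _rescale(u, tau, mult, scale):
                x = -np.log(tau)
                x_new = x + rng.normal(0, scale)
                c = np.exp(0.5 * (x_new - x))
                eta_new = eta + (c - 1.0) * u[j] * mult
                dlp = (kernel.ll(eta_new) - kernel.ll(eta)
                       + asis_rescale_logpost_delta(
                           x, x_new, prior.precision_shape,
                           prior.precision_rate))
                if np.log(rng.random()) < dlp:
                    return u * c, float(np.exp(-x_new)), eta_new, True
                return u, tau, eta, False

            if spec.spatial_structure == "exchangeable":
                tau0 = sample_precision(u0, rng, prior.precision_shape,
                                        prior.precision_rate)
                u0, tau0, eta, ok = _rescale(u0, tau0, 1.0,
                                             sc_asis.scale[0])
                acc_asis[0] = ok
            if spec.include_slopes:
                tau1 = sample_precision(u1, rng, prior.precision_shape,
                                        prior.precision_rate)
                u1, tau1, eta, ok = _rescale(u1, tau1, t,
                                             sc_asis.scale[1])
                acc_asis[1] = ok
            if adapting:
                sc_asis.update(acc_asis)
        elif spec.correlate_slopes:
            tau0, tau1, rho, acc3 = _update_corr_block(
                u0, u1, tau0, tau1, rho, prior, sc_var.scale, rng)
            if adapting:
                sc_var.update(acc3)

        if it >= warmup:
            # convert to the uncentred design and move effect means into
            # the intercept/trend (sum-to-zero reporting)
            m0 = u0.mean()
            m1 = u1.mean() if spec.include_slopes else 0.0
            b = beta.copy()
            b[1] = beta[1] + m1
            b[0] = beta[0] + m0 - beta[1] * mt - beta[2:] @ mX
            u0c = u0 - m0
            u1c = u1 - m1 if spec.include_slopes else u1
            out["beta"].append(b)
            out["u0"].append(u0c)
            out["u1"].append(u1c)
            out["sigma2_u0"].append(1.0 / tau0)
            out["sigma2_u1"].append(1.0 / tau1)
            out["rho"].append(rho)
            out["deviance"].append(kernel.deviance(eta))
            if gaussian:
                out["sigma2_e"].append(1.0 / kernel.tau_e)
    return {k: np.asarray(v) for k, v in out.items() if len(v)}


def _update_corr_block(u0, u1, tau0, tau1, rho, prior, scales, rng):
    """Joint MH update of (log sigma2_u0, log sigma2_u1, atanh rho) under
    Gamma precision priors and a uniform prior on the correlation."""
    a, b = prior.precision_shape, prior.precision_rate

    def logpost(x0, x1, z):
        v0, v1 = np.exp(x0), np.exp(x1)
        r = np.tanh(z)
        lp = _gauss_bvn_logpdf(u0, u1, v0, v1, r)
        # Gamma(a, b) on precisions, transformed to log-variance scale
        lp += -a * x0 - b / v0 - a * x1 - b / v1
        lp += np.log1p(-r ** 2)  # uniform rho with z Jacobian
        return lp

    x = np.array([-np.log(tau0), -np.log(tau1), np.arctanh(rho)])
    acc = np.zeros(3)
    for i in range(3):
        prop = x.copy()
        prop[i] += rng.normal(0, scales[i])
        if logpost(*prop) - logpost(*x) > np.log(rng.random()):
            x = prop
            acc[i] = 1
    return float(np.exp(-x[0])), float(np.exp(-x[1])), float(np.tanh(x[2])), acc


def _assemble_fit(chains_out, spec, wards, kernel, j, t, X, gaussian,
                  inference, meta_extra=None) -> ModelFit:
    use_ward = spec.include_ward_effects and len(wards) >= 2
    names = ["beta", "deviance"]
    if use_ward:
        names += ["u0", "sigma2_u0"]
    if spec.include_slopes and use_ward:
        names += ["u1", "sigma2_u1"]
    if spec.correlate_slopes:
        names += ["rho"]
    if gaussian:
        names += ["sigma2_e"]
    posterior = {k: np.stack([c[k] for c in chains_out]) for k in names}
    deviance = posterior.pop("deviance")

    # deviance at the posterior mean (conditional DIC focus)
    mb = posterior["beta"].reshape(-1, posterior["beta"].shape[-1]).mean(0)
    mu0 = (posterior["u0"].reshape(-1, len(wards)).mean(0) if use_ward
           else np.zeros(len(wards)))
    eta_hat = mb[0] + mb[1] * t + mu0[j] + X @ mb[2:]
    if spec.include_slopes and use_ward:
        mu1 = posterior["u1"].reshape(-1, len(wards)).mean(0)
        eta_hat = eta_hat + mu1[j] * t
    if gaussian:
        kernel.tau_e = 1.0 / posterior["sigma2_e"].mean()
    dic = dic_from_deviance(deviance, kernel.deviance(eta_hat))

    diag_params = {k: v for k, v in posterior.items()}
    diagnostics = rhat_summary(diag_params)
    converged = max(diagnostics.values()) < inference.rhat_threshold
    meta = {"ward_ids": [int(w) for w in wards],
            "spec": {"include_trend": spec.include_trend,
                     "include_slopes": spec.include_slopes and use_ward,
                     "correlate_slopes": spec.correlate_slopes,
                     "include_ward_effects": use_ward,
                     "spatial_structure": spec.spatial_structure,
                     "covariates": list(spec.covariates)},
            "gaussian_outcome": gaussian}
    meta.update(meta_extra or {})
    return ModelFit(posterior, deviance, dic, diagnostics, converged, meta)


def fit_dm(counts: pd.DataFrame, spec: DMSpec | None = None,
           inference: InferenceConfig | None = None,
           adjacency: np.ndarray | None = None) -> ModelFit:
    """Fit the Poisson disease-mapping model to ward-year counts.

    ``counts`` needs columns ward_id, cohort, y_high, n_assessed and any
    covariates named in the spec. Cohort is coded t = year - first year,
    so exp(beta0) is the first-cohort baseline rate. ``adjacency`` (binary
    queen matrix, ward order matching sorted ward ids) is only required
    for the ICAR spatial structure.
    """
    spec = spec or DMSpec()
    inference = inference or InferenceConfig()
    counts, wards, j, t, X, y = _prepare(counts, spec)
    E = counts["n_assessed"].to_numpy(dtype=float)
    if np.any(E <= 0):
        raise ValueError("every ward-year must have positive exposure E")
    W = _check_adjacency_for(spec, adjacency, len(wards))
    kernel = _PoissonKernel(y, E)

    ss = np.random.SeedSequence(inference.seed)
    chains_out = [
        _run_chain(kernel, j, t, X, spec, spec.prior_config, len(wards),
                   inference.warmup, inference.draws,
                   np.random.default_rng(s), gaussian=False, W=W)
        for s in ss.spawn(inference.chains)
    ]
    return _assemble_fit(chains_out, spec, wards, kernel, j, t, X, False,
                         inference)


def _check_adjacency_for(spec: DMSpec, adjacency, n_wards: int):
    if spec.spatial_structure != "icar":
        return None
    if adjacency is None:
        raise ValueError("ICAR structure needs the ward adjacency matrix")
    W = np.asarray(adjacency, dtype=float)
    if W.shape != (n_wards, n_wards):
        raise ValueError("adjacency shape does not match the ward set")
    return W


def fit_dm_median_variant(counts: pd.DataFrame, spec: DMSpec | None = None,
                          inference: InferenceConfig | None = None
                          ) -> ModelFit:
    """Sensitivity variant: Gaussian model of the ward-year median score.

    Same linear predictor and random-effect structure as the count model,
    but the outcome is the median total-difficulties score and the
    likelihood is normal with an unknown observation variance.
    """
    spec = spec or DMSpec()
    inference = inference or InferenceConfig()
    if "median_score" not in counts.columns:
        raise ValueError("counts must carry a median_score column")
    counts, wards, j, t, X, y = _prepare(counts, spec,
                                         outcome="median_score")
    kernel = _GaussKernel(y)
    ss = np.random.SeedSequence(inference.seed)
    chains_out = [
        _run_chain(_GaussKernel(y), j, t, X, spec, spec.prior_config,
                   len(wards), inference.warmup, inference.draws,
                   np.random.default_rng(s), gaussian=True)
        for s in ss.spawn(inference.chains)
    ]
    return _assemble_fit(chains_out, spec, wards, kernel, j, t, X, True,
                         inference)


def dm_rr_summaries(fit: ModelFit, force: bool = False
                    ) -> dict[str, pd.DataFrame]:
    """Relative-rate tables: fixed effects, per-ward exp(u0j) and, when
    fitted, per-ward differential trends exp(u1j).

    Summaries are withheld for unconverged fits unless ``force``.
    """
    if not fit.converged and not force:
        raise RuntimeError(
            f"fit not converged (max R-hat {fit.max_rhat:.3f}); "
            "pass force=True to summarise anyway")
    wards = fit.meta["ward_ids"]
    cov = fit.meta["spec"]["covariates"]
    beta = fit.stacked("beta")
    out = {"fixed": rr_table(beta, ["intercept", "cohort"] + list(cov))}
    if "u0" in fit.posterior:
        out["ward"] = rr_table(fit.stacked("u0"), wards)
    if fit.meta["spec"]["include_slopes"]:
        out["ward_trend"] = rr_table(fit.stacked("u1"), wards)
    return out


def forward_build_dm(counts: pd.DataFrame,
                     candidate_order=DM_BUILD_ORDER,
                     inference: InferenceConfig | None = None,
                     keep_tol: float = 1.0):
    """Forward model building driven by DIC.

    Starting from intercept + cohort trend + ward intercepts, candidate
    terms are added in order. A random-slope term is retained only if it
    lowers DIC by more than ``keep_tol``; a covariate is retained unless
    removing it lowers DIC by more than ``keep_tol`` (covariates influence
    the ward variance even when their credible interval spans 1).
    Returns ``(final_spec, ledger)``.
    """
    inference = inference or InferenceConfig()
    spec = DMSpec()
    fit = fit_dm(counts, spec, inference)
    rows = [{"step": 0, "term": "base", "dic_without": np.nan,
             "dic_with": fit.dic["dic"], "retained": True,
             "converged": fit.converged}]
    dic_current = fit.dic["dic"]
    for step, term in enumerate(candidate_order, start=1):
        if term == "slopes":
            trial = replace(spec, include_slopes=True)
        else:
            trial = replace(spec, covariates=spec.covariates + (term,))
        trial_fit = fit_dm(counts, trial, inference)
        if not trial_fit.converged:
            rows.append({"step": step, "term": term,
                         "dic_without": dic_current, "dic_with": np.nan,
                         "retained": False, "converged": False})
            continue
        dic_with = trial_fit.dic["dic"]
        if term == "slopes":
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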