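"""Shared MCMC machinery for the two Bayesian models.

Both models are fitted by adaptive random-walk Metropolis-within-Gibbs:
fixed effects are updated coordinate-wise with per-coordinate adaptive
step sizes, each set of exchangeable random effects is updated with
independent per-group proposals (their full conditionals are independent
given everything else, so the accept/reject step vectorizes), and the
random-effect precisions are drawn from their conjugate Gamma full
conditionals. Step sizes adapt during warmup by a Robbins-Monro rule
targeting the usual 0.44 acceptance rate for scalar updates; adaptation is
frozen after warmup so the post-warmup chain is a valid Markov chain.

Identifiability of the intercept alongside exchangeable effects is handled
by post-hoc centring: the likelihood depends on the effects only through
``intercept + effect``, so each stored draw is transformed to sum-to-zero
effects with the mean moved into the intercept. This leaves the posterior
of every identified quantity unchanged.

Convergence is summarised by split-R-hat and effective sample size
(via arviz) over all scalar parameters and random effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InferenceConfig", "AdaptiveScale", "sample_precision",
    "rhat_summary", "dic_from_deviance", "ModelFit", "rr_table",
]


@dataclass
class InferenceConfig:
    chains: int = 4
    warmup: int = 2000
    draws: int = 2000
    seed: int = 0
    #: maximum split-R-hat for the fit to count as converged
    rhat_threshold: float = 1.05
    target_accept: float = 0.44


class AdaptiveScale:
    """Vector of log step sizes with Robbins-Monro adaptation."""

    def __init__(self, n: int, init: float = 0.1,
                 target: float = 0.44) -> None:
        self.log_s = np.full(n, np.log(init))
        self.target = target
        self._it = 0

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_s)

    def update(self, accepted) -> None:
        """``accepted`` is a boolean/0-1 array (or scalar) per component."""
        self._it += 1
        gamma = min(0.25, 2.0 / self._it ** 0.6)
        self.log_s += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, np.log(1e-5), np.log(50.0), out=self.log_s)


def asis_rescale_logpost_delta(x_old: float, x_new: float,
                               shape: float, rate: float) -> float:
    """Prior + Jacobian part of the interweaving variance move.

    In the non-centred parameterization u = sigma * z with z held fixed, a
    Metropolis step on x = log sigma^2 has target contribution
    log p(sigma^2) + x (Jacobian), which for a Gamma(shape, rate) prior on
    the precision is -shape * x - rate * exp(-x).
    """
    return (-shape * x_new - rate * np.exp(-x_new)
            + shape * x_old + rate * np.exp(-x_old))


def sample_precision(u: np.ndarray, rng: np.random.Generator,
                     shape: float = 1.0, rate: float = 0.0005) -> float:
    """Conjugate Gamma draw for a normal precision.

    Prior 1/sigma^2 ~ Gamma(shape, rate); with m iid N(0, sigma^2) effects
    the full conditional is Gamma(shape + m/2, rate + sum(u^2)/2).
    """
    m = u.size
    return float(rng.gamma(shape + 0.5 * m, 1.0 / (rate + 0.5 * np.sum(u ** 2))))


def rhat_summary(posterior: dict[str, np.ndarray]) -> dict[str, float]:
    """Max split-R-hat per parameter block from (chain, draw, ...) arrays."""
    import arviz as az

    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={k: v for k, v in posterior.items()})
        rh = az.rhat(idata)
        for k in posterior:
            val = np.asarray(rh[k].values, dtype=float)
            # a parameter held constant (e.g. a disabled term) is trivially
            # converged; arviz reports NaN for zero-variance chains
            val = np.where(np.isnan(val), 1.0, val)
            out[k] = float(np.max(val))
    return out


def dic_from_deviance(deviance_draws: np.ndarray,
                      deviance_at_mean: float) -> dict[str, float]:
    """DIC = D-bar + pD with pD = D-bar - D(theta-bar)."""
    d_bar = float(np.mean(deviance_draws))
    p_d = d_bar - deviance_at_mean
    return {"d_bar": d_bar, "d_hat": float(deviance_at_mean),
            "p_d": p_d, "dic": d_bar + p_d}


@dataclass
class ModelFit:
    """Posterior representation shared by both models.

    ``posterior`` maps parameter names to (chain, draw, ...) arrays;
    ``deviance_draws`` is (chain, draw); ``dic`` holds d_bar/d_hat/p_d/dic;
    ``diagnostics`` holds max split-R-hat per parameter.
    """

    posterior: dict[str, np.ndarray]
    deviance_draws: np.ndarray
    dic: dict[str, float]
    diagnostics: dict[str, float]
    converged: bool
    meta: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """(chain*draw, ...) draws for one parameter."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def mean(self, name: str):
        return np.mean(self.stacked(name), axis=0)

    def ci(self, name: str, level: float = 0.95):
        a = (1 - level) / 2
        s = self.stacked(name)
        return np.quantile(s, [a, 1 - a], axis=0)

    @property
    def max_rhat(self) -> float:
        return max(self.diagnostics.values())

    def summary_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        out = {"dic": self.dic, "diagnostics": self.diagnostics,
               "converged": bool(self.converged), "params": {}}
        for name in self.posterior:
            mean = np.asarray(self.mean(name))
            lo, hi = self.ci(name)
            out["params"][name] = {
                "mean": mean.tolist(), "q2.5": np.asarray(lo).tolist(),
                "q97.5": np.asarray(hi).tolist(),
            }
        out["meta"] = {k: v for k, v in self.meta.items()
                       if isinstance(v, (str, int, float, bool, list, dict))}
        return out


def rr_table(draws: np.ndarray, labels: list) -> "pd.DataFrame":
    """Relative-rate summary for log-scale parameter draws.

    ``draws`` is (n_draws,) or (n_draws, k). RR = exp(parameter); the
    exceedance probability is the posterior probability that RR > 1;
    RRs with exceedance >= 0.8 are flagged as high-certainty elevations.
    """
    import pandas as pd

    d = np.atleast_2d(draws.T).T
    if d.ndim == 1:
        d = d[:, None]
    rr = np.exp(d)
    q = np.quantile(rr, [0.025, 0.5, 0.975], axis=0)
    exceed = (rr > 1.0).mean(axis=0)
    return pd.DataFrame({
        "label": labels,
        "rr_mean": rr.mean(axis=0),
        "rr_median": q[1],
        "rr_2.5": q[0],
        "rr_97.5": q[2],
        "exceedance": exceed,
        "flag_high_certainty": exceed >= 0.8,
    })
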