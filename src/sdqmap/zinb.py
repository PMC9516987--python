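"""Zero-inflated negative binomial (ZINB) distribution.

The individual-level model for SDQ total-difficulties scores assumes a
mixture of a structural-zero mass ``p`` and a negative binomial with mean
``lam`` and overdispersion (size) ``r``:

    P(Y = 0)     = p + (1 - p) * NB(0; lam, r)
    P(Y = y > 0) = (1 - p) * NB(y; lam, r)

with NB(y; lam, r) = Gamma(y + r) / (Gamma(r) * y!)
                     * (r / (r + lam))**r * (lam / (r + lam))**y,

so that E[Y] = (1 - p) * lam and, for p = 0, Var[Y] = lam * (1 + lam / r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class ZINBParams:
    """Parameters of the zero-inflated negative binomial.

    lam : NB mean (> 0)
    p   : zero-inflation probability in [0, 1)
    r   : overdispersion / size parameter (> 0); r -> inf recovers Poisson
    """

    lam: float
    p: float
    r: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.lam) > 0):
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"p must be in [0, 1), got {self.p}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")


def nb_logpmf(y, lam, r):
    """Log pmf of the negative binomial in mean/size parameterization.

    Vectorized over ``y`` and ``lam``.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    log_r_rl = np.log(r) - np.log(r + lam)
    log_l_rl = np.log(lam) - np.log(r + lam)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * log_r_rl + y * log_l_rl
    )


def zinb_logpmf(y, params: ZINBParams):
    """Log probability of counts under the ZINB mixture.

    ``y`` may be a scalar or array of non-negative integers; ``params.lam``
    may be an array broadcastable against ``y`` (per-observation means).
    """
    y_arr = np.asarray(y)
    if np.any(y_arr < 0):
        raise ValueError("y must be non-negative")
    if not np.all(np.equal(np.mod(y_arr, 1), 0)):
        raise ValueError("y must be integer-valued")
    y_arr = y_arr.astype(float)
    lam = np.asarray(params.lam, dtype=float)
    p, r = params.p, params.r

    nb_ll = nb_logpmf(y_arr, lam, r)
    if p == 0.0:
        out = nb_ll
    else:
        with np.errstate(divide="ignore"):
            log_p = np.log(p)
        log_1mp = np.log1p(-p)
        # y == 0: logsumexp(log p, log(1-p) + NB(0)); y > 0: log(1-p) + NB(y)
        zero_mix = np.logaddexp(log_p, log_1mp + nb_ll)
        out = np.where(y_arr == 0, zero_mix, log_1mp + nb_ll)
    if np.isscalar(y) and out.ndim == 0:
        return float(out)
    return out


def zinb_pmf(y, params: ZINBParams):
    return np.exp(zinb_logpmf(y, params))


def zinb_mean(params: ZINBParams) -> float:
    return (1.0 - params.p) * float(np.asarray(params.lam))


def zinb_var(params: ZINBParams) -> float:
    lam, p, r = float(np.asarray(params.lam)), params.p, params.r
    return (1.0 - p) * lam * (1.0 + lam / r + p * lam)


def zinb_sf(y: int, params: ZINBParams) -> float:
    """P(Y > y) by complementing the cumulative pmf up to ``y``."""
    grid = np.arange(0, y + 1)
    return float(1.0 - np.exp(logsumexp(zinb_logpmf(grid, params))))


def zinb_rvs(lam, p, r, rng: np.random.Generator, size=None):
    """Draw ZINB variates.

    ``lam`` may be an array (per-observation means); ``size`` defaults to
    the shape of ``lam``. The NB is drawn via its gamma-Poisson mixture
    representation so that non-integer ``r`` is supported.
    """
    lam = np.asarray(lam, dtype=float)
    if size is None:
        size = lam.shape if lam.shape else None
    g = rng.gamma(shape=r, scale=lam / r, size=size)
    y = rng.poisson(g)
    if p > 0:
        y = np.where(rng.random(size=np.shape(y)) < p, 0, y)
    return y
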