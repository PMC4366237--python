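"""Numerically stable log probability mass functions for count-data families.

Four building blocks are provided, all evaluated on the log scale:

* Poisson with mean ``lam``;
* negative binomial (NB) with mean ``lam`` and dispersion ``theta`` so that
  ``Var[Y] = lam + theta * lam**2`` (``theta -> 0`` recovers the Poisson);
* zero-inflated mixtures, placing extra point mass ``p`` at zero on top of a
  base count distribution;
* hurdle (two-part) models, where zero vs. non-zero is Bernoulli(``p``) and
  positive counts follow the base distribution truncated at zero.

The NB dispersion convention used throughout the package is the
"theta * lam**2" one; software parameterized by a *size* parameter ``r``
corresponds to ``r = 1/theta``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import gammaln
from scipy import stats

__all__ = [
    "poisson_logpmf",
    "nb_logpmf",
    "zero_inflated_logpmf",
    "hurdle_logpmf",
    "support_bound",
]

LogPmf = Callable[[np.ndarray], np.ndarray]

# dispersion below which the NB log-pmf switches to the cancellation-free
# rising-factorial form (the gammaln difference loses ~half its digits once
# 1/theta approaches 1/eps**0.5)
_SMALL_THETA = 1e-6


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    return y.astype(np.float64)


def poisson_logpmf(y, lam) -> np.ndarray | float:
    """log P(Y=y) for Y ~ Poisson(lam): ``-lam + y*log(lam) - log(y!)``."""
    y = _check_counts(y)
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("lam must be a finite positive real")
    out = -lam + y * np.log(lam) - gammaln(y + 1.0)
    return out if out.ndim else float(out)


def nb_logpmf(y, lam, theta) -> np.ndarray | float:
    """log P(Y=y) for the negative binomial with mean lam, variance lam+theta*lam^2.

    ``theta`` must be strictly positive; use :func:`poisson_logpmf` for the
    theta -> 0 limit.
    """
    y = _check_counts(y)
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("lam must be a finite positive real")
    theta = float(theta)
    if theta <= 0:
        raise ValueError("theta must be > 0 (Poisson limit: use poisson_logpmf)")
    a = 1.0 / theta  # NB size parameter
    if a > 1.0 / _SMALL_THETA:
        # log Gamma(y+a) - log Gamma(a) = sum_{k<y} log(a+k), exact for integer y
        ymax = int(np.max(y)) if y.size else 0
        ks = np.arange(max(ymax, 1))
        cum = np.concatenate(([0.0], np.cumsum(np.log(a + ks))))
        rising = cum[y.astype(np.intp)]
    else:
        rising = gammaln(y + a) - gammaln(a)
    out = (
        rising
        - gammaln(y + 1.0)
        - a * np.log1p(lam / a)
        + y * (np.log(lam) - np.log(a + lam))
    )
    return out if out.ndim else float(out)


def zero_inflated_logpmf(y, p, base_logpmf: LogPmf) -> np.ndarray | float:
    """log PMF of a zero-inflated distribution.

    P(Y=0) = p + (1-p) f(0) and P(Y=y) = (1-p) f(y) for y > 0, where f is the
    base pmf supplied as a log-pmf callable. The zero class is combined with
    log-sum-exp, so tiny p or tiny f(0) do not underflow.
    """
    y = _check_counts(y)
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    base = np.asarray(base_logpmf(y), dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    out = np.where(y == 0, np.logaddexp(log_p, log_q + base), log_q + base)
    return out if out.ndim else float(out)


def hurdle_logpmf(y, p, base_logpmf: LogPmf) -> np.ndarray | float:
    """log PMF of a hurdle model: P(Y=0)=p, P(Y=y)=(1-p) f(y)/(1-f(0)) for y>0."""
    y = _check_counts(y)
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    log_f0 = float(np.asarray(base_logpmf(np.array([0.0]))).ravel()[0])
    one_minus_f0 = -np.expm1(log_f0)  # 1 - f(0), accurate for f(0) near 1
    if one_minus_f0 <= 0.0:
        raise ValueError("base distribution is degenerate at zero: f(0) >= 1")
    base = np.asarray(base_logpmf(y), dtype=np.float64)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    out = np.where(y == 0, log_p, log_q + base - np.log(one_minus_f0))
    return out if out.ndim else float(out)


def support_bound(lam, theta: float | None = None, tol: float = 1e-12) -> int:
    """Smallest J such that the base-family tail mass beyond J is below tol.

    Used to truncate infinite-support sums (normalization checks, diagnostic
    tables). ``lam`` may be an array; the bound covers every element.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=np.float64))
    if theta is None:
        bound = stats.poisson.ppf(1.0 - tol, lam)
    else:
        a = 1.0 / float(theta)
        bound = stats.nbinom.ppf(1.0 - tol, a, a / (a + lam))
    return int(np.max(bound)) + 5
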