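"""Vectorized log-likelihood kernels shared by all twelve models.

Everything is evaluated on sorted-by-county arrays so that per-cluster sums
are a single ``np.add.reduceat``. The per-observation kernel accepts a block
of ``C`` random-effect columns per cluster (quadrature nodes, or finite
difference stencils during posterior-mode search) and returns ``(n, C)``
log-likelihood contributions together with the analytic derivatives needed
elsewhere:

* ``du1`` — derivative w.r.t. the count-intercept random effect (equals the
  derivative w.r.t. the count linear predictor);
* ``dzeta`` — derivative w.r.t. the zero-model linear predictor (multiply by
  the slope covariate to get the ``u2`` derivative);
* ``da`` — derivative w.r.t. the NB size ``a = 1/theta`` (fixed-effects
  gradient only).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, log_expit

from .models import ModelSpec, ParamVector


@dataclass
class ModelMatrices:
    """Design matrices and cluster bookkeeping for one (spec, data) pair."""

    y: np.ndarray            # (n,) counts, cluster-sorted
    Xc: np.ndarray           # (n, 1+pc) count design incl. intercept
    Xz: np.ndarray | None    # (n, pz) zero design (intercept col if any)
    slope: np.ndarray | None  # (n,) random-slope covariate values
    starts: np.ndarray       # (K,) reduceat offsets
    cluster_of: np.ndarray   # (n,) cluster codes, non-decreasing
    counties: list[str]
    order: np.ndarray        # original-row positions of the sorted rows

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def K(self) -> int:
        return len(self.counties)


def build_matrices(spec: ModelSpec, data) -> ModelMatrices:
    df = data.frame
    codes, uniques = pd.factorize(df["county"], sort=False)
    order = np.argsort(codes, kind="stable")
    n = len(df)
    y = df["fire_count"].to_numpy(np.float64)[order]
    Xc = np.column_stack(
        [np.ones(n), data.covariate_matrix(spec.count_covariates)]
    )[order]
    Xz = slope = None
    if spec.is_two_part:
        cols = [data.covariate_matrix(spec.zero_covariates)]
        if spec.zero_intercept:
            cols.insert(0, np.ones((n, 1)))
        Xz = np.column_stack(cols)[order]
        slope = data.covariate_matrix([spec.zero_random_slope])[:, 0][order]
    codes_sorted = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes_sorted) > 0])
    return ModelMatrices(
        y=y, Xc=Xc, Xz=Xz, slope=slope, starts=starts,
        cluster_of=codes_sorted, counties=list(uniques), order=order,
    )


def cluster_sum(arr: np.ndarray, mat: ModelMatrices) -> np.ndarray:
    return np.add.reduceat(arr, mat.starts, axis=0)


def count_pieces(
    family: str,
    y: np.ndarray,
    eta: np.ndarray,
    theta: float | None,
    *,
    want_du: bool = False,
    want_da: bool = False,
) -> SimpleNamespace:
    """Base-count log-pmf pieces on an ``(n, C)`` block of linear predictors.

    Returns llb (log f(y)), l0 (log f(0)) and, on request, the derivatives
    g = dllb/d eta, g0 = dl0/d eta, h = dllb/da, h0 = dl0/da (NB size
    a = 1/theta). These depend only on the count side, so for tensor
    quadrature grids they can be evaluated on the few unique count nodes and
    expanded.
    """
    y = y[:, None]
    # clip linear predictors: beyond +-40 the log-likelihood is astronomically
    # negative anyway, and unclipped values stall on denormals/overflow at
    # extreme quadrature nodes
    eta = np.clip(eta, -40.0, 40.0)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        lam = np.exp(eta)
        if family in ("poisson", "zip", "hp"):
            llb = y * eta - lam - gammaln(y + 1.0)
            l0 = -lam
            g = (y - lam) if want_du else None
            g0 = -lam if want_du else None
            h = h0 = None
        else:
            a = 1.0 / theta
            denom = a + lam
            rising = gammaln(y + a) - gammaln(a)
            llb = rising - gammaln(y + 1.0) - a * np.log1p(lam / a) + y * (
                eta - np.log(denom)
            )
            l0 = -a * np.log1p(lam / a)
            g = a * (y - lam) / denom if want_du else None
            g0 = (-a * lam / denom) if want_du else None
            if want_da:
                h = (
                    digamma(y + a) - digamma(a) + np.log(a) - np.log(denom)
                    + 1.0 - (a + y) / denom
                )
                h0 = np.log(a) - np.log(denom) + 1.0 - a / denom
            else:
                h = h0 = None
    return SimpleNamespace(llb=llb, l0=l0, g=g, g0=g0, h=h, h0=h0)


def combine_two_part(
    family: str,
    y: np.ndarray,
    cp: SimpleNamespace,
    zeta: np.ndarray,
    *,
    want_du: bool = False,
    want_da: bool = False,
) -> SimpleNamespace:
    """Mix the base-count pieces with the logistic zero model."""
    n = zeta.shape[0]
    C = zeta.shape[1]
    i0 = np.asarray(y == 0)                      # (n,) zero-class rows
    ip = ~i0
    zeta = np.clip(zeta, -40.0, 40.0)

    def rows(arr, idx):
        return arr[idx] if arr.shape[0] == n else np.broadcast_to(arr, (n, C))[idx]

    out = SimpleNamespace(ll=np.empty((n, C)), du1=None, dzeta=None, da=None)
    want_grad = want_du or want_da
    if want_grad:
        out.du1 = np.empty((n, C))
        out.dzeta = np.empty((n, C))
        if want_da and cp.h is not None:
            out.da = np.empty((n, C))

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # each row only ever uses one branch of the two-part pmf, so the
        # zero-class and positive-class rows are computed separately
        z0, zp = zeta[i0], zeta[ip]
        logp0 = log_expit(z0)
        logq0 = logp0 - z0          # log sigma(-z) = log sigma(z) - z
        logpp = log_expit(zp)
        logqp = logpp - zp
        if family in ("zip", "zinb"):
            l0_0 = rows(cp.l0, i0)
            M = np.logaddexp(logp0, logq0 + l0_0)
            out.ll[i0] = M
            out.ll[ip] = logqp + rows(cp.llb, ip)
            if want_grad:
                w1 = np.exp(logq0 + l0_0 - M)   # posterior count-zero weight
                out.du1[i0] = w1 * rows(cp.g0, i0)
                out.du1[ip] = rows(cp.g, ip)
                out.dzeta[i0] = (np.exp(logp0 + logq0 - M)
                                 * (-np.expm1(l0_0)))
                out.dzeta[ip] = -np.exp(logpp)
                if out.da is not None:
                    out.da[i0] = w1 * rows(cp.h0, i0)
                    out.da[ip] = rows(cp.h, ip)
        else:  # hurdle
            l0_p = rows(cp.l0, ip)
            log1mf0 = np.log(-np.expm1(l0_p))
            out.ll[i0] = logp0
            out.ll[ip] = logqp + rows(cp.llb, ip) - log1mf0
            if want_grad:
                trunc = np.exp(l0_p - log1mf0)  # f0 / (1 - f0)
                out.du1[i0] = 0.0
                out.du1[ip] = rows(cp.g, ip) + trunc * rows(cp.g0, ip)
                out.dzeta[i0] = np.exp(logq0)
                out.dzeta[ip] = -np.exp(logpp)
                if out.da is not None:
                    out.da[i0] = 0.0
                    out.da[ip] = rows(cp.h, ip) + trunc * rows(cp.h0, ip)
        bad = np.isnan(out.ll)
        if bad.any():
            out.ll[bad] = -np.inf
    return out


def per_obs_loglik(
    family: str,
    y: np.ndarray,
    eta: np.ndarray,
    zeta: np.ndarray | None,
    theta: float | None,
    *,
    want_du: bool = False,
    want_da: bool = False,
) -> SimpleNamespace:
    """Per-observation log-likelihood block and derivatives.

    ``eta`` and ``zeta`` are full linear predictors (fixed part plus any
    random-effect column offsets), shape ``(n, C)``; ``y`` is ``(n,)``.
    """
    cp = count_pieces(family, y, eta, theta,
                      want_du=want_du or want_da, want_da=want_da)
    if family in ("poisson", "nb"):
        out = SimpleNamespace(ll=np.where(np.isnan(cp.llb), -np.inf, cp.llb),
                              du1=None, dzeta=None, da=None)
        if want_du or want_da:
            out.du1 = cp.g
            out.da = cp.h
        return out
    return combine_two_part(family, y, cp, zeta,
                            want_du=want_du or want_da, want_da=want_da)


def linear_predictors(
    mat: ModelMatrices, pv: ParamVector
) -> tuple[np.ndarray, np.ndarray | None]:
    """Fixed-effect parts of the count and zero linear predictors, shape (n,)."""
    eta = mat.Xc @ pv.beta
    zeta = mat.Xz @ pv.gamma if mat.Xz is not None else None
    return eta, zeta
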