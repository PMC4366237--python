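"""Maximum-likelihood estimation for the six families, fixed or mixed.

Fixed-effects models are fitted by BFGS with analytic gradients of the
log-likelihood. Mixed models integrate the county-level random effects out
of the likelihood with adaptive Gauss-Hermite quadrature: per cluster the
posterior mode of the random effects is located by Newton iteration (batched
across clusters), the quadrature grid is centred and scaled there, and the
cluster integrals are accumulated with log-sum-exp. Dispersion and variance
parameters are optimized on the log scale so positivity never needs an
explicit constraint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats

from ._likelihood import (
    ModelMatrices,
    build_matrices,
    cluster_sum,
    combine_two_part,
    count_pieces,
    linear_predictors,
    per_obs_loglik,
)
from .models import ModelSpec, ParamVector

__all__ = [
    "FitResult",
    "ScreeningResult",
    "conditional_loglik",
    "marginal_loglik",
    "fit",
    "screen_covariates",
]

_LOG_CLIP = 30.0          # bounds on log(theta), log(v) during optimization
_ACTIVE_V = 1e-12         # variance below which a random effect is inert
_NEWTON_TOL = 1e-7
_NEWTON_MAX = 60
_FD_H = 1e-4              # step for mode-curvature finite differences

# convergence declaration thresholds on the gradient inf-norm
_CTOL_FIXED = 1e-5
_CTOL_MIXED = 5e-2


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------
class ParamPacker:
    """Maps a ParamVector to/from the unconstrained optimization vector.

    theta, v1, v2 are carried as logs; the optional (u1,u2) correlation as an
    inverse hyperbolic tangent.
    """

    def __init__(self, spec: ModelSpec, beta_scale=None, gamma_scale=None):
        self.spec = spec
        names = ["count:intercept"] + [f"count:{c}" for c in spec.count_covariates]
        self.n_beta = len(names)
        self.n_gamma = 0
        if spec.is_two_part:
            if spec.zero_intercept:
                names.append("zero:intercept")
            names += [f"zero:{c}" for c in spec.zero_covariates]
            self.n_gamma = len(names) - self.n_beta
        if spec.has_dispersion:
            names.append("theta")
        if spec.is_mixed:
            names.append("v1")
            if spec.is_two_part:
                names.append("v2")
                if spec.re_structure == "unstructured":
                    names.append("corr12")
        self.names = names
        # optional design-column scales: the free vector carries coef*scale,
        # matching design matrices whose columns were divided by scale
        self.beta_scale = (np.ones(self.n_beta) if beta_scale is None
                           else np.asarray(beta_scale, dtype=np.float64))
        self.gamma_scale = (np.ones(self.n_gamma) if gamma_scale is None
                            else np.asarray(gamma_scale, dtype=np.float64))
        assert len(names) == spec.n_params()

    def pack(self, pv: ParamVector) -> np.ndarray:
        x = list(np.atleast_1d(pv.beta) * self.beta_scale)
        if self.spec.is_two_part:
            x += list(np.atleast_1d(pv.gamma) * self.gamma_scale)
        if self.spec.has_dispersion:
            x.append(np.log(pv.theta))
        if self.spec.is_mixed:
            x.append(np.log(max(pv.v1, 1e-8)))
            if self.spec.is_two_part:
                x.append(np.log(max(pv.v2, 1e-8)))
                if self.spec.re_structure == "unstructured":
                    denom = np.sqrt(max(pv.v1 * pv.v2, 1e-30))
                    rho = np.clip(pv.cov12 / denom, -0.999, 0.999)
                    x.append(np.arctanh(rho))
        return np.asarray(x, dtype=np.float64)

    def unpack(self, x: np.ndarray) -> ParamVector:
        x = np.asarray(x, dtype=np.float64)
        i = self.n_beta
        beta = x[:i]                      # internal (scaled-design) coords
        gamma = None
        if self.spec.is_two_part:
            gamma = x[i:i + self.n_gamma]
            i += self.n_gamma
        theta = None
        if self.spec.has_dispersion:
            theta = float(np.exp(np.clip(x[i], -_LOG_CLIP, _LOG_CLIP)))
            i += 1
        v1 = v2 = cov12 = 0.0
        if self.spec.is_mixed:
            v1 = float(np.exp(np.clip(x[i], -_LOG_CLIP, _LOG_CLIP)))
            i += 1
            if self.spec.is_two_part:
                v2 = float(np.exp(np.clip(x[i], -_LOG_CLIP, _LOG_CLIP)))
                i += 1
                if self.spec.re_structure == "unstructured":
                    cov12 = float(np.tanh(x[i]) * np.sqrt(v1 * v2))
                    i += 1
        return ParamVector(beta=beta, gamma=gamma, theta=theta,
                           v1=v1, v2=v2, cov12=cov12)

    def to_natural_pv(self, x: np.ndarray) -> ParamVector:
        """ParamVector on the original covariate scale (for reporting)."""
        pv = self.unpack(x)
        return ParamVector(
            beta=pv.beta / self.beta_scale,
            gamma=None if pv.gamma is None else pv.gamma / self.gamma_scale,
            theta=pv.theta, v1=pv.v1, v2=pv.v2, cov12=pv.cov12,
        )

    def natural(self, x: np.ndarray) -> np.ndarray:
        """Natural-scale parameter values aligned with :attr:`names`."""
        pv = self.to_natural_pv(x)
        vals = list(pv.beta)
        if self.spec.is_two_part:
            vals += list(pv.gamma)
        if self.spec.has_dispersion:
            vals.append(pv.theta)
        if self.spec.is_mixed:
            vals.append(pv.v1)
            if self.spec.is_two_part:
                vals.append(pv.v2)
                if self.spec.re_structure == "unstructured":
                    vals.append(pv.cov12 / np.sqrt(max(pv.v1 * pv.v2, 1e-30)))
        return np.asarray(vals)

    def dnatural(self, x: np.ndarray) -> np.ndarray:
        """d(natural)/d(free), diagonal Jacobian for the delta method."""
        d = np.ones(len(self.names))
        d[:self.n_beta] = 1.0 / self.beta_scale
        d[self.n_beta:self.n_beta + self.n_gamma] = 1.0 / self.gamma_scale
        nat = self.natural(x)
        for j, name in enumerate(self.names):
            if name in ("theta", "v1", "v2"):
                d[j] = nat[j]              # d exp(x) / dx
            elif name == "corr12":
                d[j] = 1.0 - nat[j] ** 2   # d tanh(x) / dx
        return d


# ---------------------------------------------------------------------------
# conditional likelihood
# ---------------------------------------------------------------------------
def _u_arrays(spec, mat, u):
    K = mat.K
    if u is None:
        return np.zeros(K), np.zeros(K)
    if isinstance(u, dict):
        rows = [np.atleast_1d(np.asarray(u[c], dtype=np.float64)) for c in mat.counties]
        u = np.vstack([np.pad(r, (0, 2 - r.size)) if r.size < 2 else r[:2] for r in rows])
    u = np.asarray(u, dtype=np.float64)
    if u.ndim == 1:
        return u, np.zeros(K)
    return u[:, 0], u[:, 1]


def _domain_check(spec: ModelSpec, pv: ParamVector) -> None:
    if spec.has_dispersion and (pv.theta is None or pv.theta <= 0):
        raise ValueError("NB-based families require theta > 0")
    if spec.is_two_part and pv.gamma is None:
        raise ValueError("two-part families require zero-model coefficients")


def conditional_loglik(spec: ModelSpec, params: ParamVector, data, u=None) -> float:
    """Log-likelihood conditional on random-effect values ``u``.

    ``u`` maps county -> u1 (or (u1, u2) for two-part specs), or is an array
    in county order of appearance; ``None`` means all zeros, which for a
    fixed-effects spec *is* the likelihood.
    """
    _domain_check(spec, params)
    mat = build_matrices(spec, data)
    u1, u2 = _u_arrays(spec, mat, u)
    eta, zeta = linear_predictors(mat, params)
    eta = eta[:, None] + u1[mat.cluster_of, None]
    if zeta is not None:
        zeta = zeta[:, None] + (u2[mat.cluster_of] * mat.slope)[:, None]
    res = per_obs_loglik(spec.family, mat.y, eta, zeta, params.theta)
    return float(res.ll.sum())


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------
class _MarginalEvaluator:
    """Caches quadrature nodes and cluster posterior modes across calls."""

    def __init__(self, spec: ModelSpec, mat: ModelMatrices,
                 quad_order: int, adaptive: bool):
        self.spec = spec
        self.mat = mat
        self.adaptive = adaptive
        z, w = hermgauss(quad_order)
        self.z1, self.logw1 = z, np.log(w)
        ZA, ZB = np.meshgrid(z, z, indexing="ij")
        WA, WB = np.meshgrid(np.log(w), np.log(w), indexing="ij")
        self.z2a, self.z2b = ZA.ravel(), ZB.ravel()
        self.logw2 = (WA + WB).ravel()
        self.modes = np.zeros((mat.K, 2))

    # -- raw cluster log-likelihood at a block of (u1, u2) columns ----------
    def _cluster_ll(self, pv, eta0, zeta0, U1, U2, want_du=False,
                    want_da=False, return_raw=False,
                    u1_unique=None, colmap=None):
        mat = self.mat
        zeta = None
        if zeta0 is not None:
            zeta = zeta0[:, None] + U2[mat.cluster_of, :] * mat.slope[:, None]
        if u1_unique is not None and zeta is not None:
            # tensor grid: the count side only sees the few unique u1 nodes;
            # evaluate the expensive pmf pieces there and expand columns
            eta_small = eta0[:, None] + u1_unique[mat.cluster_of, :]
            cp = count_pieces(self.spec.family, mat.y, eta_small, pv.theta,
                              want_du=want_du or want_da, want_da=want_da)
            from types import SimpleNamespace
            cpx = SimpleNamespace(**{
                k: (v[:, colmap] if isinstance(v, np.ndarray) else v)
                for k, v in vars(cp).items()
            })
            res = combine_two_part(self.spec.family, mat.y, cpx, zeta,
                                   want_du=want_du or want_da,
                                   want_da=want_da)
        else:
            eta = eta0[:, None] + U1[mat.cluster_of, :]
            res = per_obs_loglik(self.spec.family, mat.y, eta, zeta, pv.theta,
                                 want_du=want_du, want_da=want_da)
        out = SimpleNamespaceLL(
            ll=cluster_sum(res.ll, mat),
            du1=cluster_sum(res.du1, mat) if want_du and res.du1 is not None else None,
            du2=cluster_sum(res.dzeta * mat.slope[:, None], mat)
            if want_du and res.dzeta is not None else None,
        )
        if return_raw:
            out.raw = res
        return out

    # -- posterior modes and curvatures -------------------------------------
    def _modes_and_hessians(self, pv, eta0, zeta0, dims, P):
        """Damped Newton search for per-cluster posterior modes.

        The zero-model random slope multiplies a covariate of magnitude
        ~10^2, so the curvature across the (u1, u2) dimensions can differ by
        orders of magnitude; a per-cluster backtracking line search keeps
        pure Newton from limit-cycling. Returns modes (K, nd) and negative
        Hessians (K, nd, nd), guaranteed positive definite (prior precision
        fallback when the data curvature is degenerate).
        """
        K, nd = self.mat.K, len(dims)
        m = self.modes[:, dims].copy()
        h = _FD_H

        def value(mcur):
            # cluster joint log density up to a constant
            U = np.zeros((K, 1, 2))
            for j, d in enumerate(dims):
                U[:, 0, d] = mcur[:, j]
            res = self._cluster_ll(pv, eta0, zeta0, U[:, :, 0], U[:, :, 1])
            quad = np.einsum("kj,ji,ki->k", mcur, P, mcur)
            return res.ll[:, 0] - 0.5 * quad

        def full_eval(mcur):
            # batched stencil: centre + (+h, -h) per active dim
            C = 1 + 2 * nd
            U = np.zeros((K, C, 2))
            for j, d in enumerate(dims):
                U[:, :, d] = mcur[:, j:j + 1]
            for j, d in enumerate(dims):
                U[:, 1 + 2 * j, d] += h
                U[:, 2 + 2 * j, d] -= h
            res = self._cluster_ll(pv, eta0, zeta0, U[:, :, 0], U[:, :, 1],
                                   want_du=True)
            comp = [res.du1, res.du2]
            G = np.stack([comp[d] for d in dims], axis=-1)  # (K, C, nd)
            G = G - np.einsum("ij,kcj->kci", P, U[:, :, dims])
            g0 = G[:, 0, :]
            H = np.empty((K, nd, nd))
            for j in range(nd):
                H[:, :, j] = (G[:, 1 + 2 * j, :] - G[:, 2 + 2 * j, :]) / (2 * h)
            H = 0.5 * (H + np.swapaxes(H, 1, 2))
            quad = np.einsum("kj,ji,ki->k", mcur, P, mcur)
            return g0, H, res.ll[:, 0] - 0.5 * quad

        g0, H, gval = full_eval(m)
        for _ in range(_NEWTON_MAX):
            negH = _make_pd(-H, P)
            # convergence measured in posterior-sd units, scale-free
            sd = 1.0 / np.sqrt(negH[:, np.arange(nd), np.arange(nd)])
            if np.max(np.abs(g0) * sd) < _NEWTON_TOL:
                break
            step = np.linalg.solve(negH, g0[..., None])[..., 0]
            alpha = np.ones((K, 1))
            newm = m + step
            gnew = value(newm)
            for _ in range(12):
                worse = gnew < gval - 1e-10
                if not np.any(worse):
                    break
                alpha[worse] *= 0.5
                newm = m + alpha * step
                gnew = value(newm)
            still = gnew < gval - 1e-10
            if np.any(still):          # plateau: keep previous point there
                newm[still] = m[still]
            if np.max(np.abs(newm - m)) < 1e-12:
                break
            m = newm
            g0, H, gval = full_eval(m)
        negH = _make_pd(-H, P)
        self.modes[:, dims] = m
        return m, negH

    def build_rule(self, pv: ParamVector) -> "QuadRule":
        """Adapt the quadrature rule (nodes, constants) to ``pv``.

        The returned rule can be evaluated at other parameter values with
        :meth:`rule_loglik`; freezing it during inner optimization steps
        makes Fisher's-identity scores exact for the frozen integral.
        """
        spec, mat = self.spec, self.mat
        _domain_check(spec, pv)
        dims = []
        if pv.v1 > _ACTIVE_V:
            dims.append(0)
        if spec.is_two_part and pv.v2 > _ACTIVE_V:
            dims.append(1)
        if not dims:
            z1 = np.zeros((mat.K, 1))
            return QuadRule(dims=(), U1=z1, U2=z1, const=np.zeros((mat.K, 1)),
                            logdet=np.zeros(mat.K))
        V = pv.re_cov[np.ix_(dims, dims)]
        P = np.linalg.inv(V)
        nd = len(dims)
        eta0, zeta0 = linear_predictors(mat, pv)
        if self.adaptive:
            m, negH = self._modes_and_hessians(pv, eta0, zeta0, dims, P)
        else:
            m = np.zeros((mat.K, nd))
            negH = np.broadcast_to(P, (mat.K, nd, nd)).copy()
        if nd == 1:
            s = 1.0 / np.sqrt(negH[:, 0, 0])            # (K,)
            nodes = m[:, 0:1] + np.sqrt(2.0) * s[:, None] * self.z1[None, :]
            zeros = np.zeros_like(nodes)
            U1 = nodes if dims[0] == 0 else zeros
            U2 = nodes if dims[0] == 1 else zeros
            const = np.broadcast_to(
                self.logw1[None, :] + self.z1[None, :] ** 2, nodes.shape
            )
            logdet = 0.5 * np.log(2.0) + np.log(s)
        else:
            L11, L21, L22 = _chol_inv_2x2(negH)         # chol of negH^{-1}
            za, zb = self.z2a[None, :], self.z2b[None, :]
            U1 = m[:, 0:1] + np.sqrt(2.0) * (L11[:, None] * za)
            U2 = m[:, 1:2] + np.sqrt(2.0) * (L21[:, None] * za + L22[:, None] * zb)
            const = np.broadcast_to(self.logw2[None, :] + za ** 2 + zb ** 2,
                                    U1.shape)
            logdet = np.log(2.0) + np.log(L11) + np.log(L22)
            q = self.z1.size
            u1u = m[:, 0:1] + np.sqrt(2.0) * L11[:, None] * self.z1[None, :]
            return QuadRule(dims=tuple(dims), U1=U1, U2=U2, const=const,
                            logdet=logdet, u1_unique=u1u,
                            colmap=np.repeat(np.arange(q), q))
        return QuadRule(dims=tuple(dims), U1=U1, U2=U2, const=const,
                        logdet=logdet)

    def rule_loglik(self, rule: "QuadRule", pv: ParamVector,
                    want_grad: bool = False):
        """Log-likelihood (and optionally exact score) under a frozen rule.

        With the nodes held fixed, the gradient of the log integral w.r.t.
        the parameters is exactly the posterior-weighted conditional score
        plus the prior score — no node-movement term. Gradient pieces:
        ``S1, S2`` (per-observation weighted scores of the count and zero
        linear predictors), ``Sa`` (NB size), ``gv1, gv2`` (log-variance
        scores). Diagonal random-effects structure only.
        """
        spec, mat = self.spec, self.mat
        _domain_check(spec, pv)
        want_da = want_grad and spec.has_dispersion
        eta0, zeta0 = linear_predictors(mat, pv)
        res = self._cluster_ll(pv, eta0, zeta0, rule.U1, rule.U2,
                               want_du=want_grad, want_da=want_da,
                               return_raw=want_grad,
                               u1_unique=rule.u1_unique, colmap=rule.colmap)
        if not rule.dims:
            total = float(res.ll.sum())
            if not want_grad:
                return total
            raw = res.raw
            pieces = SimpleNamespaceLL(ll=None)
            pieces.S1 = raw.du1[:, 0]
            pieces.S2 = raw.dzeta[:, 0] if raw.dzeta is not None else None
            pieces.Sa = float(raw.da.sum()) if raw.da is not None else None
            pieces.gv1 = pieces.gv2 = 0.0
            return total, pieces

        lprior = np.zeros_like(res.ll)
        if 0 in rule.dims:
            lprior = lprior - 0.5 * (np.log(2 * np.pi * pv.v1)
                                     + rule.U1 ** 2 / pv.v1)
        if 1 in rule.dims:
            lprior = lprior - 0.5 * (np.log(2 * np.pi * pv.v2)
                                     + rule.U2 ** 2 / pv.v2)
        body = res.ll + lprior + rule.const
        lse = _logsumexp(body)
        per_cluster = lse + rule.logdet
        total = float(per_cluster.sum())
        if np.isnan(total):
            raise FloatingPointError(
                "non-finite marginal likelihood; offending cluster(s): "
                f"{[mat.counties[i] for i in np.flatnonzero(~np.isfinite(per_cluster))]}"
            )
        if not want_grad:
            return total
        omega = np.exp(body - lse[:, None])              # (K, Q) posterior weights
        wrow = omega[mat.cluster_of, :]
        raw = res.raw
        pieces = SimpleNamespaceLL(ll=None)
        pieces.S1 = (raw.du1 * wrow).sum(axis=1)
        pieces.S2 = (raw.dzeta * wrow).sum(axis=1) if raw.dzeta is not None else None
        pieces.Sa = float((raw.da * wrow).sum()) if raw.da is not None else None
        pieces.gv1 = pieces.gv2 = 0.0
        if 0 in rule.dims:
            pieces.gv1 = float((omega * 0.5 * (rule.U1 ** 2 / pv.v1 - 1.0)).sum())
        if 1 in rule.dims:
            pieces.gv2 = float((omega * 0.5 * (rule.U2 ** 2 / pv.v2 - 1.0)).sum())
        return total, pieces

    def loglik(self, pv: ParamVector, want_grad: bool = False):
        """Adaptive marginal log-likelihood (rule re-adapted at ``pv``)."""
        rule = self.build_rule(pv)
        return self.rule_loglik(rule, pv, want_grad=want_grad)


@dataclass
class QuadRule:
    """A frozen (adapted) Gauss-Hermite rule: nodes plus constant weights."""

    dims: tuple
    U1: np.ndarray       # (K, Q) count-intercept nodes
    U2: np.ndarray       # (K, Q) zero-slope nodes
    const: np.ndarray    # (K, Q) parameter-independent log-weight part
    logdet: np.ndarray   # (K,) log Jacobian of the node transform
    u1_unique: np.ndarray | None = None   # (K, q) distinct count nodes of a
    colmap: np.ndarray | None = None      # tensor grid + column expansion map


class SimpleNamespaceLL:
    __slots__ = ("ll", "du1", "du2", "raw", "S1", "S2", "Sa", "gv1", "gv2")

    def __init__(self, ll, du1=None, du2=None):
        self.ll, self.du1, self.du2 = ll, du1, du2


def _logsumexp(a, axis=1):
    amax = np.max(a, axis=axis, keepdims=True)
    amax = np.where(np.isfinite(amax), amax, 0.0)
    out = np.log(np.sum(np.exp(a - amax), axis=axis)) + amax[:, 0]
    return out


def _make_pd(negH, P):
    """Replace non-positive-definite cluster curvatures by the prior precision."""
    K, nd, _ = negH.shape
    if nd == 1:
        bad = negH[:, 0, 0] <= 1e-10
    else:
        det = negH[:, 0, 0] * negH[:, 1, 1] - negH[:, 0, 1] ** 2
        bad = (negH[:, 0, 0] <= 1e-10) | (det <= 1e-16)
    if np.any(bad):
        negH = negH.copy()
        negH[bad] = P
    return negH


def _chol_inv_2x2(negH):
    """Cholesky factor (lower) of negH^{-1} for a batch of 2x2 PD matrices."""
    a, b, c = negH[:, 0, 0], negH[:, 0, 1], negH[:, 1, 1]
    det = a * c - b * b
    ia, ib, ic = c / det, -b / det, a / det
    L11 = np.sqrt(ia)
    L21 = ib / L11
    L22 = np.sqrt(np.maximum(ic - L21 ** 2, 1e-300))
    return L11, L21, L22


def marginal_loglik(
    spec: ModelSpec,
    params: ParamVector,
    data,
    quad_order: int = 20,
    adaptive: bool = True,
) -> float:
    """Random-effects-integrated log-likelihood of a mixed spec.

    Degenerate variances (v = 0) drop the corresponding integration
    dimension; with both variances zero this reduces to the conditional
    log-likelihood at u = 0.
    """
    if quad_order < 1:
        raise ValueError("quad_order must be >= 1")
    mat = build_matrices(spec, data)
    ev = _MarginalEvaluator(spec, mat, quad_order, adaptive)
    return ev.loglik(params)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
@dataclass
class FitResult:
    """Estimates, uncertainty and fit statistics for one fitted model."""

    spec: ModelSpec
    params: ParamVector
    names: list[str]
    estimates: dict[str, float]
    se: dict[str, float]
    wald: dict[str, tuple[float, float]]
    loglik: float
    n_obs: int
    n_clusters: int
    k: int
    converged: bool
    gradient_norm: float
    n_iter: int
    message: str
    quad_order: int | None
    data_signature: str
    se_ok: bool
    x_free: np.ndarray = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def bic(self, n_convention: str = "auto") -> float:
        if n_convention == "auto":
            n = self.n_clusters if self.spec.is_mixed else self.n_obs
        elif n_convention == "obs":
            n = self.n_obs
        elif n_convention == "clusters":
            n = self.n_clusters
        else:
            raise ValueError("n_convention must be auto/obs/clusters")
        return -2.0 * self.loglik + self.k * np.log(n)

    def to_frame(self) -> pd.DataFrame:
        """Parameter table with Wald tests and significance stars
        (** p<0.05, * 0.05<=p<0.1)."""
        rows = []
        for name in self.names:
            t, p = self.wald[name]
            stars = "**" if p < 0.05 else ("*" if p < 0.1 else "")
            rows.append(
                {"parameter": name, "estimate": self.estimates[name],
                 "se": self.se[name], "t": t, "p": p, "sig": stars}
            )
        return pd.DataFrame(rows)

    def __repr__(self) -> str:
        return (
            f"<FitResult {self.spec.label}: loglik={self.loglik:.3f} "
            f"k={self.k} AIC={self.aic:.1f} converged={self.converged}>"
        )


def data_signature(data) -> str:
    df = data.frame
    hasher = hashlib.sha1()
    hasher.update(df["county"].astype(str).str.cat(sep="|").encode())
    for col in ("year", "month", "fire_count"):
        hasher.update(np.ascontiguousarray(df[col].to_numpy()).tobytes())
    return hasher.hexdigest()


def _default_quad_order(spec: ModelSpec) -> int:
    # adaptive GH: 9 nodes per dimension. Below 9 the 2-D families' adaptive
    # fixed point stops contracting (the zero-slope direction drifts), so
    # this is a stability floor, not only an accuracy choice.
    return 9


def _default_start(spec: ModelSpec, mat: ModelMatrices) -> ParamVector:
    """Intercept-only closed form: beta0 = log mean count, rest 0, theta 1."""
    mean_y = float(np.mean(mat.y))
    beta = np.zeros(1 + len(spec.count_covariates))
    beta[0] = np.log(max(mean_y, 1e-3))
    gamma = None
    if spec.is_two_part:
        gamma = np.zeros(len(spec.zero_covariates) + int(spec.zero_intercept))
    theta = 1.0 if spec.has_dispersion else None
    return ParamVector(beta=beta, gamma=gamma, theta=theta)


def _newton_inner(obj, x, H, tol: float = 1e-6, maxit: int = 25,
                  step_cap: float = 2.0):
    """Damped Newton steps on a frozen-rule objective with a reusable Hessian.

    Returns (x, n_evals, ok); ok is False when the Hessian is too stale to
    make progress, signalling the caller to fall back to BFGS.
    """
    f, g = obj(x)
    nit = 1
    if not np.isfinite(f):
        return x, nit, False
    for _ in range(maxit):
        if np.max(np.abs(g)) < tol:
            return x, nit, True
        step = np.linalg.solve(H, -g)
        mx = np.max(np.abs(step))
        if mx > step_cap:
            step *= step_cap / mx
        t = 1.0
        moved = False
        while t > 1e-4:
            f2, g2 = obj(x + t * step)
            nit += 1
            if np.isfinite(f2) and f2 <= f:
                x = x + t * step
                f, g = f2, g2
                moved = True
                break
            t *= 0.5
        if not moved:
            return x, nit, False
    return x, nit, bool(np.max(np.abs(g)) < 10 * tol)


def _hessian_from_grad(gradf, x, h_rel=1e-5, central=True):
    """Finite-difference Hessian from an (analytic) gradient; symmetrized.

    ``central=False`` halves the cost (p+1 gradient calls) at slightly lower
    accuracy — sufficient wherever the Hessian feeds Newton steps or
    percent-level standard errors.
    """
    p = x.size
    h = h_rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    if central:
        for i in range(p):
            ei = np.zeros(p); ei[i] = h[i]
            H[:, i] = (gradf(x + ei) - gradf(x - ei)) / (2 * h[i])
    else:
        g0 = gradf(x)
        for i in range(p):
            ei = np.zeros(p); ei[i] = h[i]
            H[:, i] = (gradf(x + ei) - g0) / h[i]
    return 0.5 * (H + H.T)


def _hessian(f, x, h_rel=1e-4):
    """Central-difference Hessian of scalar f at x."""
    p = x.size
    h = h_rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp + fmm - 2 * f0) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) + f(x - ei - ej) - f(x + ei - ej) - f(x - ei + ej)
            ) / (4 * h[i] * h[j])
    return H


def fit(
    spec: ModelSpec,
    data,
    start: ParamVector | None = None,
    quad_order: int | None = None,
    seed: int = 0,
    adaptive: bool = True,
    maxiter: int = 500,
    restarts: int = 3,
) -> FitResult:
    """Fit one model by maximum likelihood.

    Fixed-effects specs use analytic gradients; mixed specs maximize the
    adaptive-quadrature marginal likelihood (numerically differentiated) and
    are warm-started from their fixed-effects twin with small starting
    variances. Up to ``restarts`` jittered restarts are attempted on
    non-convergence; the flag in the result is honest either way.
    """
    mat = build_matrices(spec, data)
    if np.unique(mat.y).size < 2:
        raise ValueError("data must contain at least 2 distinct count values")
    if spec.is_mixed and mat.K < 2:
        raise ValueError("mixed specs need at least 2 clusters")

    # scale design columns to unit RMS for optimizer conditioning (scale
    # only, never center: a no-intercept zero model must not gain a hidden
    # constant); estimates and SEs are mapped back exactly
    def _col_scales(X):
        if X is None:
            return None
        s = np.sqrt(np.mean(X ** 2, axis=0))
        s[~np.isfinite(s) | (s <= 0)] = 1.0
        return s

    beta_scale = _col_scales(mat.Xc)
    gamma_scale = _col_scales(mat.Xz)
    mat = replace(
        mat, Xc=mat.Xc / beta_scale,
        Xz=None if mat.Xz is None else mat.Xz / gamma_scale,
    )
    packer = ParamPacker(spec, beta_scale=beta_scale, gamma_scale=gamma_scale)
    if quad_order is None:
        quad_order = _default_quad_order(spec)
    fixed_ref_ll = None
    if start is None:
        if spec.is_mixed:
            base = fit(spec.fixed_version(), data, quad_order=quad_order,
                       adaptive=adaptive, seed=seed)
            fixed_ref_ll = base.loglik
            start = replace(base.params, v1=0.05,
                            v2=0.05 if spec.is_two_part else 0.0, cov12=0.0)
        else:
            start = _default_start(spec, mat)
    x0 = packer.pack(start)

    if spec.is_mixed:
        ev = _MarginalEvaluator(spec, mat, quad_order, adaptive)
        analytic = spec.re_structure == "diagonal"

        def _assemble_grad(pv, pieces):
            g = [mat.Xc.T @ pieces.S1]
            if spec.is_two_part:
                g.append(mat.Xz.T @ pieces.S2)
            if spec.has_dispersion:
                g.append(np.array([-(1.0 / pv.theta) * pieces.Sa]))
            g.append(np.array([pieces.gv1]))
            if spec.is_two_part:
                g.append(np.array([pieces.gv2]))
            return np.concatenate(g)

        def make_frozen_objective(rule):
            def obj(x):
                pv = packer.unpack(x)
                try:
                    val, pieces = ev.rule_loglik(rule, pv, want_grad=True)
                except FloatingPointError:
                    return np.inf, np.zeros_like(x)
                if not np.isfinite(val):
                    return np.inf, np.zeros_like(x)
                return -val, -_assemble_grad(pv, pieces)
            return obj

        def objective(x):
            # re-adapted evaluation (used for reporting and the numeric
            # fallback of the unstructured covariance path)
            pv = packer.unpack(x)
            try:
                out = ev.loglik(pv, want_grad=analytic)
            except FloatingPointError:
                return (np.inf, np.zeros_like(x)) if analytic else np.inf
            if analytic:
                val, pieces = out
                if not np.isfinite(val):
                    return np.inf, np.zeros_like(x)
                return -val, -_assemble_grad(pv, pieces)
            return -out if np.isfinite(out) else np.inf

        jac = True if analytic else None
        gtol, ctol = 1e-3, _CTOL_MIXED
    else:
        eta_builder = mat

        def objective(x):
            pv = packer.unpack(x)
            eta, zeta = linear_predictors(mat, pv)
            res = per_obs_loglik(spec.family, mat.y, eta[:, None],
                                 None if zeta is None else zeta[:, None],
                                 pv.theta, want_du=True,
                                 want_da=spec.has_dispersion)
            ll = float(res.ll.sum())
            if not np.isfinite(ll):
                return np.inf, np.zeros_like(x)
            g = [mat.Xc.T @ res.du1[:, 0]]
            if spec.is_two_part:
                g.append(mat.Xz.T @ res.dzeta[:, 0])
            if spec.has_dispersion:
                a = 1.0 / pv.theta
                g.append(np.array([-a * float(res.da.sum())]))
            grad = np.concatenate(g)
            return -ll, -grad

        jac = True
        gtol, ctol = 1e-8, _CTOL_FIXED

    def solve_from(x_init):
        """One optimization run; returns an OptimizeResult-like object.

        For mixed diagonal specs this iterates the adaptive fixed point:
        freeze the rule adapted at x, maximize it exactly (Fisher-identity
        scores are exact under a frozen rule), re-adapt, repeat, and finish
        with a polish solve so the reported estimate is an exact stationary
        point of a self-adapted rule. The first cycle uses BFGS; later
        cycles take safeguarded Newton steps reusing one finite-difference
        Hessian, since re-adaptation moves the optimum only slightly. If the
        fixed point fails to settle (low-order rules can cycle when a
        cluster's zero-slope posterior is strongly skewed), the quadrature
        order is escalated until the map contracts.
        """
        if spec.is_mixed and spec.re_structure == "diagonal":
            x = np.asarray(x_init, dtype=np.float64)
            nit = 0
            dx = np.inf
            message = "rule build failed"
            any_inner = False
            settled = False
            ev_cur = ev
            H_newton = None

            def bfgs(obj, z, gtol_):
                return optimize.minimize(obj, z, jac=True, method="BFGS",
                                         options={"gtol": gtol_,
                                                  "maxiter": maxiter})

            def build_H(obj, z):
                try:
                    H = _hessian_from_grad(lambda w: obj(w)[1], z,
                                           central=False)
                    if np.all(np.linalg.eigvalsh(H) > 0):
                        return H
                except np.linalg.LinAlgError:
                    pass
                return None

            se_ref = None
            for phase, q_phase in enumerate(
                    (quad_order, quad_order + 4, quad_order + 8)):
                if phase > 0:
                    # escalated order: reuse the warm posterior modes and the
                    # scaled-coordinate Hessian — the surface changes only by
                    # quadrature error, so Newton steps remain effective
                    ev_next = _MarginalEvaluator(spec, mat, q_phase, adaptive)
                    ev_next.modes = ev_cur.modes.copy()
                    ev_cur = ev_next
                for _outer in range(8 if phase == 0 else 5):
                    try:
                        rule = ev_cur.build_rule(packer.unpack(x))
                    except FloatingPointError:
                        break
                    obj = make_frozen_objective(rule)
                    if H_newton is None:
                        # loose inner solves while the fixed point drifts;
                        # that precision is discarded by the re-adaptation
                        res = bfgs(obj, x, 1e-3 if dx > 0.1 else 1e-5)
                        nit += res.nit
                        xn = res.x
                        message = res.message
                    else:
                        xn, add_nit, ok_n = _newton_inner(obj, x, H_newton)
                        nit += add_nit
                        if not ok_n:
                            res = bfgs(obj, xn, 1e-5)
                            nit += res.nit
                            xn = res.x
                            H_newton = None
                        message = "Newton refinement"
                    any_inner = True
                    step = xn - x
                    dx = float(np.max(np.abs(step)))
                    x = xn
                    if H_newton is None and (dx < 0.2 or phase > 0):
                        H_newton = build_H(obj, xn)
                        if H_newton is not None:
                            try:
                                se_ref = np.sqrt(
                                    np.diag(np.linalg.inv(H_newton)))
                            except np.linalg.LinAlgError:
                                se_ref = None
                    # settled when the re-adaptation moves the estimate by a
                    # statistically negligible amount: either an absolute
                    # tolerance or a quarter of each parameter's standard
                    # error (rule ambiguity below that level has no
                    # inferential consequence; escalation handles the rest)
                    if dx < 1e-3 * (1.0 + float(np.max(np.abs(x)))) or (
                        se_ref is not None
                        and np.all(np.abs(step) <= 0.25 * se_ref)
                    ):
                        settled = True
                        break
                    # a phase that is clearly cycling rather than contracting
                    # will not settle — escalate the order instead
                    if _outer >= 3 and dx > 0.05 * (
                            1.0 + float(np.max(np.abs(x)))):
                        break
                if settled:
                    break

            # polish: exact stationary point of the final self-adapted rule
            gnorm_f = np.inf
            fval = np.inf
            final_rule = None
            if any_inner:
                try:
                    final_rule = ev_cur.build_rule(packer.unpack(x))
                    obj = make_frozen_objective(final_rule)
                    done = False
                    if H_newton is not None:
                        x, add_nit, done = _newton_inner(obj, x, H_newton,
                                                         tol=1e-6)
                        nit += add_nit
                    if not done:
                        res = bfgs(obj, x, 1e-6)
                        nit += res.nit
                        x = res.x
                    fval, g = obj(x)
                    gnorm_f = float(np.max(np.abs(g)))
                except FloatingPointError:
                    final_rule = None
            out = optimize.OptimizeResult()
            out.x, out.fun, out.nit = x, fval, nit
            out.gnorm = gnorm_f
            out.rule = final_rule
            out.final_order = ev_cur.z1.size
            out.success = bool(
                any_inner and np.isfinite(fval) and gnorm_f <= _CTOL_MIXED
                and settled
            )
            out.message = (
                f"adaptive-rule fixed point at order {ev_cur.z1.size} "
                f"(last inner: {message})"
            )
            return out
        res = optimize.minimize(
            objective, x_init, jac=jac, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        res.gnorm = _grad_norm(objective, res.x, jac)
        return res

    fixed_point_path = spec.is_mixed and spec.re_structure == "diagonal"
    rng = np.random.default_rng(seed)
    best = None
    x_try = x0
    n_attempts = 0
    for attempt in range(restarts + 1):
        n_attempts += 1
        res = solve_from(x_try)
        gnorm = res.gnorm
        ok = bool(np.isfinite(res.fun) and gnorm <= ctol)
        if fixed_point_path:
            ok = bool(res.success)
            if fixed_ref_ll is not None and np.isfinite(res.fun):
                # nesting sanity: the marginal likelihood at the optimum can
                # never fall below the fixed-effects (v -> 0) likelihood
                ok = ok and (-res.fun >= fixed_ref_ll - 1e-6)
        cand = (res, gnorm, ok)
        if best is None or res.fun < best[0].fun:
            best = cand
        if ok:
            best = cand
            break
        x_try = best[0].x + rng.normal(0.0, 0.1 * (1.0 + np.abs(best[0].x)))
    res, gnorm, converged = best
    loglik = -float(res.fun)
    xhat = res.x

    def f_only(x):
        val = objective(x)
        return val[0] if isinstance(val, tuple) else val

    se_free = np.full(xhat.size, np.nan)
    se_ok = False
    try:
        if jac and spec.is_mixed:
            # observed information under the rule the optimum was polished
            # on: xhat is an exact stationary point of that frozen surface,
            # so its analytic score differentiates cleanly
            rule_hat = getattr(res, "rule", None)
            if rule_hat is None:
                rule_hat = ev.build_rule(packer.unpack(xhat))
            frozen_obj = make_frozen_objective(rule_hat)
            H = _hessian_from_grad(lambda x: frozen_obj(x)[1], xhat,
                                   central=False)
        elif jac:
            H = _hessian_from_grad(lambda x: objective(x)[1], xhat)
        else:
            H = _hessian(f_only, xhat)   # Hessian of -loglik
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(np.isfinite(d)) and np.all(d > 0):
            se_free = np.sqrt(d)
            se_ok = True
    except np.linalg.LinAlgError:
        pass

    nat = packer.natural(xhat)
    dnat = packer.dnatural(xhat)
    se_nat = se_free * np.abs(dnat)
    wald = {}
    for j, name in enumerate(packer.names):
        if se_ok and se_nat[j] > 0:
            t = nat[j] / se_nat[j]
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            t, p = np.nan, np.nan
        wald[name] = (float(t), float(p))

    return FitResult(
        spec=spec,
        params=packer.to_natural_pv(xhat),
        names=list(packer.names),
        estimates={n: float(v) for n, v in zip(packer.names, nat)},
        se={n: float(s) for n, s in zip(packer.names, se_nat)},
        wald=wald,
        loglik=loglik,
        n_obs=mat.n,
        n_clusters=mat.K,
        k=spec.n_params(),
        converged=converged,
        gradient_norm=float(gnorm),
        n_iter=int(res.nit) + (n_attempts - 1) * maxiter,
        message=str(res.message),
        quad_order=(int(getattr(res, "final_order", quad_order))
                    if spec.is_mixed else None),
        data_signature=data_signature(data),
        se_ok=se_ok,
        x_free=xhat,
    )


def _grad_norm(objective, x, jac):
    if jac:
        _, g = objective(x)
        return float(np.max(np.abs(g)))
    g = optimize.approx_fprime(x, objective, 1.49e-8 * np.maximum(1, np.abs(x)))
    return float(np.max(np.abs(g)))


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------
@dataclass
class ScreeningResult:
    """Reduced spec plus the per-covariate Wald report behind it."""

    spec: ModelSpec
    removed: dict[str, float]
    kept: dict[str, float]
    full_fit: FitResult


def screen_covariates(
    spec: ModelSpec, data, alpha: float = 0.1, **fit_kwargs
) -> ScreeningResult:
    """Drop covariates whose full-model Wald p-value exceeds ``alpha``.

    All failing covariates are removed at once from a single full fit.
    Intercepts are never screened, and in a two-part mixed spec the
    covariate carrying the zero-model random slope is retained regardless
    (removing it would remove the random effect itself).
    """
    full = fit(spec, data, **fit_kwargs)
    if not full.converged:
        raise RuntimeError(
            f"screening aborted: full fit did not converge "
            f"(gradient norm {full.gradient_norm:.3g}, {full.message})"
        )
    protected = set()
    if spec.is_two_part and spec.is_mixed:
        protected.add(f"zero:{spec.zero_random_slope}")
    removed, kept = {}, {}
    keep_count, keep_zero = [], []
    for c in spec.count_covariates:
        p = full.wald[f"count:{c}"][1]
        if p > alpha:
            removed[f"count:{c}"] = p
        else:
            kept[f"count:{c}"] = p
            keep_count.append(c)
    for c in spec.zero_covariates:
        name = f"zero:{c}"
        p = full.wald[name][1]
        if p > alpha and name not in protected:
            removed[name] = p
        else:
            kept[name] = p
            keep_zero.append(c)
    reduced = replace(spec, count_covariates=tuple(keep_count),
                      zero_covariates=tuple(keep_zero))
    return ScreeningResult(spec=reduced, removed=removed, kept=kept,
                           full_fit=full)
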