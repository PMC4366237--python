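"""Model comparison (AIC/BIC) and count-class goodness-of-fit diagnostics.

The d_j diagnostic compares, for each count class j, the mean fitted
probability of observing j with the observed proportion of j's:

    d_j = (1/n) * sum_i P(y_i = j | fitted model)  -  (#{i: y_i = j} / n)

Positive d_j means the model over-predicts class j. For mixed fits the
per-observation probabilities marginalize over the county random effects by
Gauss-Hermite quadrature against the fitted Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from ._likelihood import build_matrices, linear_predictors, per_obs_loglik
from .estimation import FitResult
from .models import ParamVector

__all__ = [
    "aic",
    "bic",
    "relative_criterion_increase",
    "DiagnosticTable",
    "dj_table",
    "dj_from_probabilities",
    "predicted_probabilities",
    "compare_models",
]


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2*loglik + 2k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * loglik + 2.0 * k


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2*loglik + k*ln(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * np.log(n)


def relative_criterion_increase(value_a: float, value_b: float) -> float:
    """Percent by which criterion value_a exceeds value_b: 100*(a-b)/b."""
    if value_b <= 0:
        raise ValueError("reference criterion value must be positive")
    return 100.0 * (value_a - value_b) / value_b


@dataclass
class DiagnosticTable:
    """Per count-class fitted-vs-observed probability comparison."""

    table: pd.DataFrame      # columns: j, mean_predicted_prob, observed_prop, d_j
    tail_mass: float         # mean predicted probability beyond the last class

    @property
    def d(self) -> np.ndarray:
        return self.table["d_j"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def dj_from_probabilities(probs: np.ndarray, y: np.ndarray) -> DiagnosticTable:
    """Build a diagnostic table from an (n, J+1) matrix of P(y_i = j)."""
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y)
    n, ncls = probs.shape
    js = np.arange(ncls)
    mean_pred = probs.mean(axis=0)
    observed = np.bincount(y.astype(np.intp), minlength=ncls)[:ncls] / n
    table = pd.DataFrame(
        {"j": js, "mean_predicted_prob": mean_pred,
         "observed_prop": observed, "d_j": mean_pred - observed}
    )
    return DiagnosticTable(table=table, tail_mass=float(1.0 - mean_pred.sum()))


def _prob_matrix(family, y_classes, lam, p, theta):
    """P(Y=j) for each observation (rows) and class j (columns)."""
    n = lam.size
    out = np.empty((n, y_classes.size))
    for idx, j in enumerate(y_classes):
        yj = np.full(n, float(j))
        zeta = None
        if p is not None:
            # logit is re-derived from p; per_obs_loglik wants linear predictors
            with np.errstate(divide="ignore"):
                zeta = np.log(p) - np.log1p(-p)
            zeta = zeta[:, None]
        res = per_obs_loglik(family, yj, np.log(lam)[:, None], zeta, theta)
        out[:, idx] = np.exp(res.ll[:, 0])
    return out


def predicted_probabilities(
    fit: FitResult, data, max_class: int, quad_order: int = 30
) -> np.ndarray:
    """(n, max_class+1) matrix of fitted P(y_i = j), marginal over random effects."""
    spec = fit.spec
    pv: ParamVector = fit.params
    mat = build_matrices(spec, data)
    eta0, zeta0 = linear_predictors(mat, pv)
    classes = np.arange(max_class + 1)

    if not spec.is_mixed or (pv.v1 <= 0 and pv.v2 <= 0):
        lam = np.exp(eta0)
        p = expit(zeta0) if zeta0 is not None else None
        probs = _prob_matrix(spec.family, classes, lam, p, pv.theta)
    else:
        z, w = hermgauss(quad_order)
        wnorm = w / np.sqrt(np.pi)
        probs = np.zeros((mat.n, classes.size))
        if spec.is_two_part and pv.v2 > 0:
            # tensor grid over (u1, u2); prior-centred nodes are adequate
            # because a single observation barely narrows the posterior
            nodes1 = np.sqrt(2.0 * pv.v1) * z if pv.v1 > 0 else np.array([0.0])
            w1 = wnorm if pv.v1 > 0 else np.array([1.0])
            nodes2 = np.sqrt(2.0 * pv.v2) * z
            for a, wa in zip(nodes1, w1):
                lam = np.exp(eta0 + a)
                for b, wb in zip(nodes2, wnorm):
                    p = expit(zeta0 + b * mat.slope)
                    probs += wa * wb * _prob_matrix(
                        spec.family, classes, lam, p, pv.theta
                    )
        else:
            for a, wa in zip(np.sqrt(2.0 * pv.v1) * z, wnorm):
                lam = np.exp(eta0 + a)
                p = expit(zeta0) if zeta0 is not None else None
                probs += wa * _prob_matrix(spec.family, classes, lam, p, pv.theta)
    # undo the cluster sort so rows align with the input panel
    unsorted = np.empty_like(probs)
    unsorted[mat.order] = probs
    return unsorted


def dj_table(
    fit: FitResult, data, max_class: int | None = None, quad_order: int = 30
) -> DiagnosticTable:
    """Fitted-vs-observed count-class table for one fitted model.

    ``max_class`` defaults to the largest observed count plus 5; the
    remaining predicted tail mass is reported on the result.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    y = data.counts
    if max_class is None:
        max_class = int(y.max()) + 5
    probs = predicted_probabilities(fit, data, max_class, quad_order=quad_order)
    return dj_from_probabilities(probs, y)


def compare_models(fits, bic_n: str = "auto") -> pd.DataFrame:
    """Rank fitted models by AIC (BIC as tie-break).

    All fits must come from the same panel; mixing datasets raises. The
    returned table flags the minimum of each criterion.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    sigs = {f.data_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError(
            "fits were produced on different datasets and cannot be compared"
        )
    rows = []
    for order, f in enumerate(fits):
        rows.append(
            {
                "model": f.spec.label,
                "family": f.spec.family,
                "effects": f.spec.effects,
                "loglik": f.loglik,
                "k": f.k,
                "n_obs": f.n_obs,
                "n_clusters": f.n_clusters,
                "aic": f.aic,
                "bic": f.bic(bic_n),
                "converged": f.converged,
                "_order": order,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["aic", "bic", "_order"], kind="stable"
    ).drop(columns="_order").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["best_aic"] = df["aic"] == df["aic"].min()
    df["best_bic"] = df["bic"] == df["bic"].min()
    return df
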