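"""Regression structure shared by the twelve fire-occurrence models.

Every model couples a log-link count mean ``lam = exp(x . beta [+ u1])`` with,
for the two-part families, a logistic zero model
``p = expit(x0 . gamma [+ u2 * E])``. The mixed variants add county-level
Gaussian random effects: ``u1 ~ N(0, v1)`` on the count intercept and, for
two-part families, ``u2 ~ N(0, v2)`` on the zero-model slope of one covariate
(evaporation in the reference analysis). The random-effects covariance is
diagonal by default; an unstructured 2x2 option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "FAMILIES",
    "TWO_PART_FAMILIES",
    "NB_FAMILIES",
    "ModelSpec",
    "ParamVector",
    "count_mean",
    "zero_prob",
]

FAMILIES = ("poisson", "nb", "zip", "zinb", "hp", "hnb")
TWO_PART_FAMILIES = frozenset({"zip", "zinb", "hp", "hnb"})
NB_FAMILIES = frozenset({"nb", "zinb", "hnb"})
HURDLE_FAMILIES = frozenset({"hp", "hnb"})


@dataclass(frozen=True)
class ModelSpec:
    """Family x effects x covariate lists defining one of the candidate models.

    Parameters
    ----------
    family : one of ``poisson, nb, zip, zinb, hp, hnb``.
    effects : ``"fixed"`` or ``"mixed"``.
    count_covariates : covariate names entering the log-link count mean
        (an intercept is always included and is not listed).
    zero_covariates : covariate names entering the logistic zero model
        (two-part families only).
    zero_intercept : whether the zero model has an intercept. The reference
        analysis uses one for the Poisson-based two-part models and none for
        the NB-based ones.
    zero_random_slope : covariate whose zero-model slope carries the random
        effect ``u2`` in two-part mixed models.
    re_structure : ``"diagonal"`` (default) or ``"unstructured"`` covariance
        between (u1, u2).
    """

    family: str
    effects: str = "fixed"
    count_covariates: tuple[str, ...] = ()
    zero_covariates: tuple[str, ...] = ()
    zero_intercept: bool = True
    zero_random_slope: str = "evaporation"
    re_structure: str = "diagonal"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.effects not in ("fixed", "mixed"):
            raise ValueError("effects must be 'fixed' or 'mixed'")
        if self.re_structure not in ("diagonal", "unstructured"):
            raise ValueError("re_structure must be 'diagonal' or 'unstructured'")
        object.__setattr__(self, "count_covariates", tuple(self.count_covariates))
        object.__setattr__(self, "zero_covariates", tuple(self.zero_covariates))
        if not self.is_two_part and (self.zero_covariates or False):
            raise ValueError(
                f"{self.family} has no zero model; zero_covariates must be empty"
            )
        if self.is_two_part and self.is_mixed:
            if self.zero_random_slope not in self.zero_covariates:
                raise ValueError(
                    "two-part mixed models place u2 on the zero-model slope of "
                    f"{self.zero_random_slope!r}, which must appear in zero_covariates"
                )

    # -- structural properties -------------------------------------------------
    @property
    def is_two_part(self) -> bool:
        return self.family in TWO_PART_FAMILIES

    @property
    def is_hurdle(self) -> bool:
        return self.family in HURDLE_FAMILIES

    @property
    def has_dispersion(self) -> bool:
        return self.family in NB_FAMILIES

    @property
    def is_mixed(self) -> bool:
        return self.effects == "mixed"

    @property
    def n_random_effects(self) -> int:
        if not self.is_mixed:
            return 0
        return 2 if self.is_two_part else 1

    def n_params(self) -> int:
        """Number of freely estimated parameters (k in AIC/BIC)."""
        k = 1 + len(self.count_covariates)
        if self.is_two_part:
            k += len(self.zero_covariates) + int(self.zero_intercept)
        if self.has_dispersion:
            k += 1
        if self.is_mixed:
            k += 1  # v1
            if self.is_two_part:
                k += 1  # v2
                if self.re_structure == "unstructured":
                    k += 1  # cov12
        return k

    @property
    def label(self) -> str:
        return f"{self.family}-{self.effects}"

    def fixed_version(self) -> "ModelSpec":
        return replace(self, effects="fixed")

    # -- plain-text round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "effects": self.effects,
            "count_covariates": list(self.count_covariates),
            "zero_covariates": list(self.zero_covariates),
            "zero_intercept": self.zero_intercept,
            "zero_random_slope": self.zero_random_slope,
            "re_structure": self.re_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=d["family"],
            effects=d.get("effects", "fixed"),
            count_covariates=tuple(d.get("count_covariates", ())),
            zero_covariates=tuple(d.get("zero_covariates", ())),
            zero_intercept=bool(d.get("zero_intercept", True)),
            zero_random_slope=d.get("zero_random_slope", "evaporation"),
            re_structure=d.get("re_structure", "diagonal"),
        )


@dataclass
class ParamVector:
    """Parameter values for one model.

    beta : count-model coefficients, intercept first.
    gamma : zero-model coefficients (intercept first when the spec has one);
        None for one-part families.
    theta : NB dispersion (None for Poisson-based families).
    v1, v2 : random-effect variances (count intercept, zero slope).
    cov12 : covariance of (u1, u2); 0 under the diagonal structure.
    """

    beta: np.ndarray
    gamma: np.ndarray | None = None
    theta: float | None = None
    v1: float = 0.0
    v2: float = 0.0
    cov12: float = 0.0

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        if self.gamma is not None:
            self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=np.float64))
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be > 0 when present")
        if self.v1 < 0 or self.v2 < 0:
            raise ValueError("random-effect variances must be >= 0")
        if self.cov12 ** 2 > self.v1 * self.v2 + 1e-15:
            raise ValueError(
                "random-effects covariance matrix must be positive semidefinite"
            )

    @property
    def re_cov(self) -> np.ndarray:
        return np.array([[self.v1, self.cov12], [self.cov12, self.v2]])


def count_mean(x, beta, u1: float = 0.0):
    """Log-link count mean ``lam = exp(beta0 + x . beta[1:] + u1)``.

    ``x`` holds the covariate values (no intercept column); ``beta`` includes
    the intercept as its first element. Accepts a single row or a 2-D array
    of rows.
    """
    x = np.asarray(x, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    lp = beta[0] + x @ beta[1:] + u1
    if not np.all(np.isfinite(lp)):
        bad = np.flatnonzero(~np.isfinite(np.atleast_1d(lp)))
        raise OverflowError(f"non-finite linear predictor at row(s) {bad.tolist()}")
    lam = np.exp(lp)
    return lam if np.ndim(lam) else float(lam)


def zero_prob(x0, gamma, u2: float = 0.0, slope_value=0.0):
    """Logistic zero-model probability ``p = expit(x0 . gamma + u2*slope_value)``.

    ``x0`` is the zero-model design row(s) (including the intercept column if
    the spec has one); ``u2`` acts on the covariate whose value is passed as
    ``slope_value`` (evaporation in the reference analysis).
    """
    x0 = np.asarray(x0, dtype=np.float64)
    gamma = np.asarray(gamma, dtype=np.float64)
    lp = x0 @ gamma + u2 * np.asarray(slope_value, dtype=np.float64)
    p = expit(lp)
    return p if np.ndim(p) else float(p)
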