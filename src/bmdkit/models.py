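"""Dose-response families and the covariate-adjusted log-outcome model.

The outcome model used throughout the package is

    log Y = alpha_0 + sum_j alpha_j z_j + f(d) + eps,   eps ~ N(0, sigma^2)

where ``Y`` is a positive outcome (e.g. a serum antibody concentration),
``d`` a non-negative exposure (e.g. the summed serum-PFAS concentration in
ng/mL), ``z_j`` covariates, and ``f`` a dose-response function with
``f(0) = 0``.  Four families of ``f`` are supported:

====================  =============================================
family                f(d)
====================  =============================================
``linear``            beta * d
``piecewise``         beta1 * min(d, d0) + beta2 * max(d - d0, 0)
``kpower``            beta * d**K              (K >= 1)
``hockey``            beta * (d - gamma)_+     (gamma >= 0)
====================  =============================================

All four are continuous in ``d`` and satisfy ``f(0) = 0``.  The piecewise
model is linear in its parameters with a fixed break ``d0``; the hockey-stick
threshold ``gamma`` and the power ``K`` are estimated from data.  At the
piecewise break the two branches agree, so the value there is defined by
continuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "DoseResponseSpec",
    "ModelParameters",
    "evaluate_f",
    "linear_predictor",
]

FAMILIES = ("linear", "piecewise", "kpower", "hockey")


@dataclass(frozen=True)
class DoseResponseSpec:
    """Tagged specification of a dose-response function f(d).

    A single tagged type (rather than a subclass per family) so that fitting
    and benchmark code can switch on ``family`` without duplicating the
    outcome-model wrapper.

    Parameters
    ----------
    family : str
        One of ``linear``, ``piecewise``, ``kpower``, ``hockey``.
    beta : float
        Slope (linear, kpower, hockey).
    beta1, beta2 : float
        Slopes below/above the fixed break (piecewise).
    d0 : float
        Fixed break point, ng/mL (piecewise only); must be positive.
    K : float
        Power exponent, constrained to ``K >= 1`` (kpower only).
    gamma : float
        Threshold, ng/mL, constrained to ``gamma >= 0`` (hockey only).
    """

    family: str
    beta: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    d0: float | None = None
    K: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "linear":
            self._require("beta")
        elif self.family == "piecewise":
            self._require("beta1", "beta2", "d0")
            if self.d0 <= 0:
                raise ValueError("piecewise break d0 must be positive")
        elif self.family == "kpower":
            self._require("beta", "K")
            if self.K < 1:
                raise ValueError("kpower exponent K must satisfy K >= 1")
        elif self.family == "hockey":
            self._require("beta", "gamma")
            if self.gamma < 0:
                raise ValueError("hockey threshold gamma must be >= 0")

    def _require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(f"family {self.family!r} requires parameter {name!r}")

    # -- convenience constructors -------------------------------------------
    @classmethod
    def linear(cls, beta: float) -> "DoseResponseSpec":
        return cls("linear", beta=beta)

    @classmethod
    def piecewise(cls, beta1: float, beta2: float, d0: float) -> "DoseResponseSpec":
        return cls("piecewise", beta1=beta1, beta2=beta2, d0=d0)

    @classmethod
    def kpower(cls, beta: float, K: float) -> "DoseResponseSpec":
        return cls("kpower", beta=beta, K=K)

    @classmethod
    def hockey(cls, beta: float, gamma: float) -> "DoseResponseSpec":
        return cls("hockey", beta=beta, gamma=gamma)

    @property
    def f_coefficients(self) -> np.ndarray:
        """Coefficients of f that enter the mean structure linearly."""
        if self.family == "piecewise":
            return np.array([self.beta1, self.beta2])
        return np.array([self.beta])


def evaluate_f(spec: DoseResponseSpec, d) -> np.ndarray | float:
    """Evaluate the dose-response function f at dose(s) ``d``.

    ``d`` may be a scalar or array; doses must be non-negative.  The returned
    effect is on the log-outcome scale and satisfies ``f(0) = 0``.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("doses must be non-negative")
    if spec.family == "linear":
        out = spec.beta * d_arr
    elif spec.family == "piecewise":
        out = spec.beta1 * np.minimum(d_arr, spec.d0) + spec.beta2 * np.maximum(
            d_arr - spec.d0, 0.0
        )
    elif spec.family == "kpower":
        out = spec.beta * d_arr**spec.K
    else:  # hockey
        out = spec.beta * np.maximum(d_arr - spec.gamma, 0.0)
    if np.isscalar(d) or np.ndim(d) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the covariate-adjusted log-outcome model.

    Attributes
    ----------
    alpha0 : float
        Intercept on the log-outcome scale.
    alpha : ndarray
        Covariate coefficients (length p; may be empty).
    drs : DoseResponseSpec
        The dose-response part f(d).
    sigma2 : float
        Residual variance of the log outcome; must be positive.
    """

    alpha0: float
    alpha: np.ndarray
    drs: DoseResponseSpec
    sigma2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, float)))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def p(self) -> int:
        return self.alpha.size


def linear_predictor(params: ModelParameters, d, z=None) -> np.ndarray | float:
    """Expected log outcome: alpha0 + sum_j alpha_j z_j + f(d).

    ``z`` is a covariate vector (length p) or matrix (n, p); omit it (or pass
    an empty array) for a covariate-free model.
    """
    if z is None:
        z = np.empty((0,)) if np.ndim(d) == 0 else np.empty((np.shape(d)[0], 0))
    z_arr = np.asarray(z, dtype=float)
    p = params.p
    if z_arr.ndim <= 1:
        if z_arr.size != p:
            raise ValueError(f"expected covariate vector of length {p}, got {z_arr.size}")
        cov_term = float(z_arr @ params.alpha) if p else 0.0
    else:
        if z_arr.shape[1] != p:
            raise ValueError(
                f"expected covariate matrix with {p} columns, got {z_arr.shape[1]}"
            )
        cov_term = z_arr @ params.alpha if p else np.zeros(z_arr.shape[0])
    return params.alpha0 + cov_term + evaluate_f(params.drs, d)
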