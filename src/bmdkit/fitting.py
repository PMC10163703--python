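"""Estimation of the dose-response model for each family.

Models linear in their parameters (linear, piecewise) are fitted by ordinary
least squares; the K-power exponent and the hockey-stick threshold are
profiled on one-dimensional searches, where the inner problem is again
ordinary least squares.  Grouped summary data are fitted by weighted least
squares with the group sizes as weights.

Likelihood convention
---------------------
The Gaussian log-likelihood is reported with the maximum-likelihood variance
estimate (RSS/n), which defines ``logL`` and the AIC and makes them
comparable across families.  Covariance matrices of the regression
coefficients (used for t-based closed-form confidence limits) use the
df-corrected variance RSS/df instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .data import IndividualDataset
from .models import DoseResponseSpec, ModelParameters
from .summary_data import SummaryDataset

__all__ = [
    "DoseResponseFit",
    "BreakpointProfile",
    "fit",
    "fit_linear",
    "fit_piecewise",
    "fit_kpower",
    "fit_hockey",
    "fit_summary",
]

logger = logging.getLogger(__name__)

K_MAX = 15.0  # upper bound of the K-power profiling interval
_K_BOUNDARY_TOL = 1e-6


@dataclass
class BreakpointProfile:
    """Profile of -2 log-likelihood over candidate hockey-stick thresholds."""

    gamma_grid: np.ndarray
    profile_neg2logL: np.ndarray
    gamma_hat: float
    is_boundary: bool


@dataclass
class DoseResponseFit:
    """Results of fitting one dose-response family (a results object).

    Carries the parameter estimates, the covariance matrix of the regression
    coefficients, the maximized Gaussian log-likelihood and derived fit
    statistics, plus references to the data needed by the benchmark module
    (closed-form, profile-likelihood and bootstrap BMDL computations).
    """

    params: ModelParameters
    cov: np.ndarray
    coef: np.ndarray
    coef_names: list[str]
    se_f_coeffs: np.ndarray
    logL: float
    p_count: int
    df: int
    data_kind: str
    family: str
    nobs: int
    rss: float
    sigma2_unbiased: float
    fitted_mean: np.ndarray
    data: object
    d0: float | None = None
    profile: BreakpointProfile | None = None
    boundary_K: bool = False
    weights: np.ndarray | None = None

    @property
    def neg2logL(self) -> float:
        return -2.0 * self.logL

    @property
    def aic(self) -> float:
        return self.neg2logL + 2 * self.p_count

    def bmd(self, bmr: float) -> float:
        """Benchmark dose for a fractional reduction ``bmr`` in the geometric
        mean; NaN (with a log note) when the fitted slope is not adverse."""
        from .benchmark import bmd_from_fit

        return bmd_from_fit(self, bmr)

    def benchmark(self, config=None, **kwargs):
        """Full BMD/BMDL result; see :func:`bmdkit.benchmark.benchmark_from_fit`."""
        from .benchmark import BenchmarkConfig, benchmark_from_fit

        if config is None:
            config = BenchmarkConfig(**kwargs)
        return benchmark_from_fit(self, config)

    def summary(self) -> str:
        lines = [
            f"Dose-response fit: family={self.family}, data={self.data_kind}, "
            f"nobs={self.nobs}",
            f"{'coef':>12} {'estimate':>12} {'std err':>12}",
        ]
        se = np.sqrt(np.diag(self.cov))
        for name, b, s in zip(self.coef_names, self.coef, se):
            lines.append(f"{name:>12} {b:12.5g} {s:12.4g}")
        drs = self.params.drs
        if self.family == "kpower":
            lines.append(f"{'K':>12} {drs.K:12.5g} {'(profiled)':>12}")
        if self.family == "hockey":
            lines.append(f"{'gamma':>12} {drs.gamma:12.5g} {'(profiled)':>12}")
        if self.d0 is not None:
            lines.append(f"{'d0 (fixed)':>12} {self.d0:12.5g}")
        lines.append(
            f"sigma2(ML)={self.params.sigma2:.5g}  -2logL={self.neg2logL:.4f}  "
            f"p={self.p_count}  AIC={self.aic:.4f}  df={self.df}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer observations than regression coefficients")
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = [names[j] for j in range(len(names)) if diag[j] <= scale * 1e-10]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an (already weighted) least-squares fit."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _covariate_block(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, SummaryDataset):
        Z = data.mean_covariates
    else:
        Z = data.covariates
    n = Z.shape[0]
    C = np.column_stack([np.ones(n), Z]) if Z.shape[1] else np.ones((n, 1))
    names = ["const"] + list(
        data.covariate_names[: Z.shape[1]] if data.covariate_names else []
    )
    return C, names


def _gauss_loglike(rss: float, nobs: int, sum_log_w: float = 0.0) -> float:
    sigma2 = rss / nobs
    return -0.5 * nobs * (np.log(2 * np.pi * sigma2) + 1.0) + 0.5 * sum_log_w


def _assemble(
    *,
    res,
    coef_names: list[str],
    family: str,
    data,
    data_kind: str,
    n_f: int,
    extra_params: int,
    make_spec,
    d0=None,
    profile=None,
    boundary_K=False,
    weights=None,
    f_scale: float | np.ndarray = 1.0,
) -> DoseResponseFit:
    """Build a DoseResponseFit from a statsmodels OLS/WLS result.

    ``f_scale`` converts the last ``n_f`` (possibly rescaled) regression
    coefficients back to the dose scale; ``extra_params`` counts profiled
    parameters (K or gamma) toward the parameter count and df.
    """
    coef = np.asarray(res.params, float)
    nobs = int(res.nobs)
    rss = float(res.ssr)
    m = coef.size + extra_params
    df = nobs - m
    if df <= 0:
        raise ValueError("not enough observations for the requested model")
    sigma2_unb = rss / df
    cov = np.asarray(res.cov_params(), float) / res.scale * sigma2_unb

    # convert rescaled f-regressors (used for numerical stability) back
    scale_vec = np.ones(coef.size)
    scale_vec[-n_f:] = f_scale
    coef = coef * scale_vec
    cov = cov * np.outer(scale_vec, scale_vec)

    sum_log_w = float(np.sum(np.log(weights))) if weights is not None else 0.0
    logL = _gauss_loglike(rss, nobs, sum_log_w)
    spec = make_spec(coef)
    p = coef.size - 1 - n_f  # covariate count
    # a perfectly interpolating fit has RSS 0; keep sigma2 strictly positive
    params = ModelParameters(
        alpha0=coef[0], alpha=coef[1 : 1 + p], drs=spec,
        sigma2=max(rss / nobs, np.finfo(float).tiny),
    )
    return DoseResponseFit(
        params=params,
        cov=cov,
        coef=coef,
        coef_names=coef_names,
        se_f_coeffs=np.sqrt(np.diag(cov)[-n_f:]),
        logL=logL,
        p_count=m + 1,  # mean-structure parameters + sigma^2
        df=df,
        data_kind=data_kind,
        family=family,
        nobs=nobs,
        rss=rss,
        sigma2_unbiased=sigma2_unb,
        fitted_mean=np.asarray(res.fittedvalues, float),
        data=data,
        d0=d0,
        profile=profile,
        boundary_K=boundary_K,
        weights=weights,
    )


def _ols(X, y, weights=None):
    if weights is None:
        return sm.OLS(y, X).fit()
    return sm.WLS(y, X, weights=weights).fit()


# ---------------------------------------------------------------------------
# individual-level fits
# ---------------------------------------------------------------------------


def fit_linear(data: IndividualDataset) -> DoseResponseFit:
    """OLS fit of the linear dose-response model f(d) = beta * d."""
    C, names = _covariate_block(data)
    d = data.single_dose
    X = np.column_stack([C, d])
    names = names + ["dose"]
    _check_rank(X, names)
    res = _ols(X, data.y)
    return _assemble(
        res=res,
        coef_names=names,
        family="linear",
        data=data,
        data_kind="individual",
        n_f=1,
        extra_params=0,
        make_spec=lambda b: DoseResponseSpec.linear(beta=b[-1]),
    )


def _piecewise_regressors(d: np.ndarray, d0: float) -> np.ndarray:
    return np.column_stack([np.minimum(d, d0), np.maximum(d - d0, 0.0)])


def fit_piecewise(data: IndividualDataset, d0: float | None = None) -> DoseResponseFit:
    """OLS fit of the piecewise linear model with fixed break ``d0``.

    The model is linear in (beta1, beta2) via the constructed regressors
    min(d, d0) and max(d - d0, 0).  When ``d0`` is not given it defaults to
    the median observed dose.
    """
    d = data.single_dose
    if d0 is None:
        d0 = float(np.median(d))
        logger.info("piecewise break d0 defaulted to median dose %.4g", d0)
    if not (d.min() < d0 < d.max()):
        raise ValueError(
            f"break d0={d0:.4g} must lie strictly inside the observed dose range "
            f"[{d.min():.4g}, {d.max():.4g}]"
        )
    if np.sum(d < d0) < 3 or np.sum(d > d0) < 3:
        raise ValueError("need at least 3 observations on each side of d0")
    C, names = _covariate_block(data)
    X = np.column_stack([C, _piecewise_regressors(d, d0)])
    names = names + ["dose_lo", "dose_hi"]
    _check_rank(X, names)
    res = _ols(X, data.y)
    return _assemble(
        res=res,
        coef_names=names,
        family="piecewise",
        data=data,
        data_kind="individual",
        n_f=2,
        extra_params=0,
        make_spec=lambda b: DoseResponseSpec.piecewise(beta1=b[-2], beta2=b[-1], d0=d0),
        d0=d0,
    )


def _profile_K(C: np.ndarray, u: np.ndarray, y: np.ndarray) -> float:
    """Profile the K-power exponent over [1, K_MAX]; ``u`` is dose / max dose."""

    def rss_at(K: float) -> float:
        return _lstsq_rss(np.column_stack([C, u**K]), y)

    grid = np.linspace(1.0, K_MAX, 141)
    vals = np.array([rss_at(K) for K in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 2, 0)]
    hi = grid[min(j + 2, grid.size - 1)]
    if hi <= lo:
        return float(grid[j])
    opt = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    if not np.isfinite(opt.fun):
        raise RuntimeError(f"K-power profiling failed to converge: {opt}")
    return float(opt.x) if opt.fun <= vals[j] else float(grid[j])


def fit_kpower(data: IndividualDataset) -> DoseResponseFit:
    """ML fit of the restricted K-power model f(d) = beta * d**K, K >= 1.

    For fixed K the model is linear in beta, so K is profiled on a bounded
    one-dimensional search over [1, 15]; the regressor is internally scaled
    by the maximum dose to keep the design well conditioned.  A fit with
    K at the lower bound is flagged (``boundary_K``), where the model reduces
    to the linear one.
    """
    C, names = _covariate_block(data)
    d = data.single_dose
    dref = float(d.max())
    if dref <= 0:
        raise ValueError("all doses are zero; K-power model is undefined")
    u = d / dref
    K_hat = _profile_K(C, u, data.y)
    boundary = K_hat < 1.0 + _K_BOUNDARY_TOL
    if boundary:
        K_hat = 1.0
    X = np.column_stack([C, u**K_hat])
    names = names + ["dose^K"]
    _check_rank(X, names)
    res = _ols(X, data.y)
    scale = dref**-K_hat  # coefficient on u**K -> beta on the dose scale
    return _assemble(
        res=res,
        coef_names=names,
        family="kpower",
        data=data,
        data_kind="individual",
        n_f=1,
        extra_params=1,
        make_spec=lambda b: DoseResponseSpec.kpower(beta=b[-1], K=K_hat),
        boundary_K=boundary,
        f_scale=scale,
    )


def fit_hockey(
    data: IndividualDataset, grid_size: int = 200
) -> tuple[DoseResponseFit, BreakpointProfile]:
    """Grid-profiled fit of the hockey-stick model f(d) = beta * (d - gamma)_+.

    The threshold is profiled over a deterministic grid spanning
    [0, 95th percentile of doses]; at each candidate the model is OLS in
    beta.  The *global* grid minimizer is returned (local searches are known
    to stop at spurious interior thresholds), with ties broken toward the
    smaller threshold.  ``is_boundary`` marks a minimizer at or below the
    smallest observed dose, where the model is indistinguishable from the
    linear one.
    """
    if grid_size < 10:
        raise ValueError("grid_size must be at least 10")
    if data.n < 20:
        raise ValueError("hockey-stick profiling requires at least 20 observations")
    C, names = _covariate_block(data)
    d = data.single_dose
    grid = np.linspace(0.0, float(np.quantile(d, 0.95)), grid_size)
    rss = np.array(
        [_lstsq_rss(np.column_stack([C, np.maximum(d - g, 0.0)]), data.y) for g in grid]
    )
    near_min = rss <= rss.min() * (1.0 + 1e-9)
    j = int(np.argmax(near_min))  # first (smallest gamma) among numerical ties
    gamma_hat = float(grid[j])
    is_boundary = gamma_hat <= float(d.min())
    n = data.n
    profile = BreakpointProfile(
        gamma_grid=grid,
        profile_neg2logL=n * (np.log(2 * np.pi * rss / n) + 1.0),
        gamma_hat=gamma_hat,
        is_boundary=is_boundary,
    )
    X = np.column_stack([C, np.maximum(d - gamma_hat, 0.0)])
    names = names + ["(dose-gamma)+"]
    _check_rank(X, names)
    res = _ols(X, data.y)
    fit_res = _assemble(
        res=res,
        coef_names=names,
        family="hockey",
        data=data,
        data_kind="individual",
        n_f=1,
        extra_params=1,
        make_spec=lambda b: DoseResponseSpec.hockey(beta=b[-1], gamma=gamma_hat),
        profile=profile,
    )
    return fit_res, profile


# ---------------------------------------------------------------------------
# summary-data fits
# ---------------------------------------------------------------------------


def fit_summary(
    data: SummaryDataset, family: str = "linear", d0: float | None = None
) -> DoseResponseFit:
    """Weighted least-squares fit on group means, with weights n_g.

    Under the group-mean model Ybar_g ~ N(alpha + f-part, sigma^2 / n_g) the
    linear and piecewise parameters are interpretable exactly as the
    individual-level ones.  For the piecewise family the break should be a
    group boundary dose so that the response is linear within each group;
    otherwise a warning is issued (consistency is no longer guaranteed).
    """
    if family not in ("linear", "piecewise", "kpower"):
        raise ValueError(f"summary-data fitting not supported for family {family!r}")
    C, names = _covariate_block(data)
    d = data.mean_dose
    w = np.asarray(data.n_g, float)
    y = data.mean_log_outcome
    extra = 0
    boundary_K = False

    if family == "linear":
        X = np.column_stack([C, d])
        names = names + ["dose"]
        n_f = 1
        make_spec = lambda b: DoseResponseSpec.linear(beta=b[-1])
        f_scale: float = 1.0
    elif family == "piecewise":
        if d0 is None:
            if data.boundaries is None:
                d0 = float(np.median(d))
                warnings.warn(
                    "no group boundaries recorded; piecewise break defaulted to the "
                    "median of the group mean doses (consistency not guaranteed)"
                )
            else:
                d0 = float(data.boundaries[data.K // 2])
                logger.info("piecewise break d0 set to the median boundary %.4g", d0)
        elif data.boundaries is not None and not np.any(
            np.isclose(d0, data.boundaries, rtol=1e-6, atol=1e-12)
        ):
            warnings.warn(
                f"piecewise break d0={d0:.4g} is not a group boundary dose; "
                "the summary-data fit is no longer guaranteed to be consistent"
            )
        X = np.column_stack([C, _piecewise_regressors(d, d0)])
        names = names + ["dose_lo", "dose_hi"]
        n_f = 2
        make_spec = lambda b: DoseResponseSpec.piecewise(
            beta1=b[-2], beta2=b[-1], d0=d0
        )
        f_scale = 1.0
    else:  # kpower
        dref = float(d.max())
        u = d / dref
        K_hat = _profile_K_weighted(C, u, y, w)
        boundary_K = K_hat < 1.0 + _K_BOUNDARY_TOL
        if boundary_K:
            K_hat = 1.0
        X = np.column_stack([C, u**K_hat])
        names = names + ["dose^K"]
        n_f = 1
        extra = 1
        make_spec = lambda b: DoseResponseSpec.kpower(beta=b[-1], K=K_hat)
        f_scale = dref**-K_hat

    _check_rank(X * np.sqrt(w)[:, None], names)
    res = _ols(X, y, weights=w)
    return _assemble(
        res=res,
        coef_names=names,
        family=family,
        data=data,
        data_kind="summary",
        n_f=n_f,
        extra_params=extra,
        make_spec=make_spec,
        d0=d0 if family == "piecewise" else None,
        boundary_K=boundary_K,
        weights=w,
        f_scale=f_scale,
    )


def _profile_K_weighted(C, u, y, w) -> float:
    sw = np.sqrt(w)

    def rss_at(K: float) -> float:
        X = np.column_stack([C, u**K]) * sw[:, None]
        return _lstsq_rss(X, y * sw)

    grid = np.linspace(1.0, K_MAX, 141)
    vals = np.array([rss_at(K) for K in grid])
    j = int(np.argmin(vals))
    lo, hi = grid[max(j - 2, 0)], grid[min(j + 2, grid.size - 1)]
    opt = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    return float(opt.x) if opt.fun <= vals[j] else float(grid[j])


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def fit(
    data, family: str = "linear", d0: float | None = None, grid_size: int = 200
) -> DoseResponseFit:
    """Fit one dose-response family to individual or summary data."""
    if isinstance(data, SummaryDataset):
        return fit_summary(data, family=family, d0=d0)
    if family == "linear":
        return fit_linear(data)
    if family == "piecewise":
        return fit_piecewise(data, d0=d0)
    if family == "kpower":
        return fit_kpower(data)
    if family == "hockey":
        return fit_hockey(data, grid_size=grid_size)[0]
    raise ValueError(f"unknown family {family!r}")
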