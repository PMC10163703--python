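"""Benchmark dose (BMD) and its lower confidence limit (BMDL).

The BMD is the dose producing a pre-specified fractional reduction (the BMR)
in the geometric mean of the outcome, i.e. the solution of

    f(d) = log(1 - BMR),

and the BMDL is its one-sided lower 95% confidence limit — the regulatory
point of departure.  Three BMDL methods are implemented:

``closed_form``
    For families linear in their parameters.  A lower confidence limit
    LC(d) for f(d) is built from the t-distribution of the regression
    coefficients and the BMDL solves LC(d) = log(1 - BMR).  In the linear
    model this gives BMDL = log(1-BMR) / [beta_hat - t(df, 95%) se(beta_hat)],
    which is exact: its coverage is 95% at any sample size.
``profile_likelihood``
    The model is reparametrized so the BMD is a parameter; the BMDL is the
    smallest BMD whose profile deviance from the global maximum does not
    exceed the 90th percentile of chi-square(1) (~2.7055; the one-sided 95%
    limit inverts a two-sided 90% region).
``parametric_bootstrap``
    Outcomes are re-simulated from the fitted Gaussian model at the observed
    doses and covariates; the BMDL is the 5th percentile of the re-estimated
    BMDs.

Model retention across families follows the delta-AIC rule: every model
within 2 AIC units of the best (among models with a defined BMDL) is
retained, and the reported BMDL is the smallest among the retained ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .fitting import (
    DoseResponseFit,
    _covariate_block,
    _lstsq_rss,
    _piecewise_regressors,
    fit as fit_family,
)
from .models import DoseResponseSpec
from .data import IndividualDataset
from .summary_data import SummaryDataset

__all__ = [
    "CHI2_1_90",
    "BenchmarkConfig",
    "BenchmarkResult",
    "ModelSelection",
    "bmd_from_spec",
    "bmd_from_fit",
    "bmdl_closed_form",
    "bmdl_profile_likelihood",
    "bmdl_parametric_bootstrap",
    "benchmark_from_fit",
    "compute_bmdl",
    "select_models",
]

logger = logging.getLogger(__name__)

#: 90th percentile of the chi-square distribution with 1 df (~2.7055),
#: the deviance cut-off defining the one-sided 95% profile-likelihood limit.
CHI2_1_90: float = float(stats.chi2.ppf(0.90, 1))

METHODS = ("closed_form", "profile_likelihood", "parametric_bootstrap")


@dataclass
class BenchmarkConfig:
    """Settings of a BMD/BMDL computation.

    bmr is the fractional reduction in the geometric mean (0.05 or 0.10 in
    typical regulatory use); alpha the one-sided level of the lower limit.
    """

    bmr: float = 0.10
    method: str = "closed_form"
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.bmr < 1:
            raise ValueError("bmr must be in (0, 1)")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass
class BenchmarkResult:
    """BMD and BMDL (ng/mL) with method metadata and diagnostics.

    Undefined quantities are NaN with the reason recorded in ``diagnostics``;
    whenever both are finite, ``bmdl <= bmd``.
    """

    bmd: float
    bmdl: float
    method: str
    family: str
    bmr: float
    diagnostics: dict = field(default_factory=dict)
    fit: DoseResponseFit | None = None

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.bmd) and np.isfinite(self.bmdl))

    def to_dict(self) -> dict:
        def _num(x):
            return None if x is None or not np.isfinite(x) else float(x)

        return {
            "bmd": _num(self.bmd),
            "bmdl": _num(self.bmdl),
            "method": self.method,
            "family": self.family,
            "bmr": self.bmr,
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }


# ---------------------------------------------------------------------------
# BMD point estimate
# ---------------------------------------------------------------------------


def bmd_from_spec(spec: DoseResponseSpec, bmr: float) -> float:
    """Closed-form BMD for a dose-response specification.

    Returns NaN when the response never reaches the benchmark reduction for
    any non-negative dose (non-adverse effective slope).
    """
    if not 0 < bmr < 1:
        raise ValueError("bmr must be in (0, 1)")
    A = np.log1p(-bmr)  # log(1 - BMR) < 0
    if spec.family == "linear":
        return A / spec.beta if spec.beta < 0 else float("nan")
    if spec.family == "hockey":
        return spec.gamma + A / spec.beta if spec.beta < 0 else float("nan")
    if spec.family == "kpower":
        return (A / spec.beta) ** (1.0 / spec.K) if spec.beta < 0 else float("nan")
    # piecewise: below the break if reachable there, else on the upper segment
    if spec.beta1 < 0 and A / spec.beta1 <= spec.d0:
        return A / spec.beta1
    if spec.beta2 < 0:
        return spec.d0 + (A - spec.beta1 * spec.d0) / spec.beta2
    return float("nan")


def bmd_from_fit(fit: DoseResponseFit, bmr: float) -> float:
    """BMD point estimate from a fitted model (NaN if slope not adverse)."""
    bmd = bmd_from_spec(fit.params.drs, bmr)
    if not np.isfinite(bmd):
        logger.info(
            "BMD undefined for %s fit: fitted dose response is not adverse",
            fit.family,
        )
    return bmd


# ---------------------------------------------------------------------------
# closed form BMDL (families linear in the parameters)
# ---------------------------------------------------------------------------


def bmdl_closed_form(fit: DoseResponseFit, config: BenchmarkConfig) -> BenchmarkResult:
    """t-based closed-form BMDL for the linear and piecewise families."""
    if fit.family not in ("linear", "piecewise"):
        raise ValueError(
            "closed-form BMDL requires a family linear in its parameters "
            f"(linear or piecewise), got {fit.family!r}"
        )
    A = float(np.log1p(-config.bmr))
    bmd = bmd_from_fit(fit, config.bmr)
    t_crit = float(stats.t.ppf(1 - config.alpha, fit.df))
    diagnostics: dict = {"t_crit": t_crit, "df": fit.df}

    if fit.family == "linear":
        beta = fit.params.drs.beta
        se = float(fit.se_f_coeffs[0])
        denom = beta - t_crit * se
        if denom >= 0:
            diagnostics["undefined"] = "lower confidence limit of the slope is >= 0"
            bmdl = float("nan")
        else:
            bmdl = A / denom
    else:
        spec = fit.params.drs
        b = np.array([spec.beta1, spec.beta2])
        V = fit.cov[-2:, -2:]
        d0 = spec.d0

        def LC(d):
            d = np.asarray(d, float)
            c1 = np.minimum(d, d0)
            c2 = np.maximum(d - d0, 0.0)
            est = c1 * b[0] + c2 * b[1]
            var = c1 * c1 * V[0, 0] + 2 * c1 * c2 * V[0, 1] + c2 * c2 * V[1, 1]
            return est - t_crit * np.sqrt(np.maximum(var, 0.0))

        bmdl = _smallest_crossing(LC, A, scale=d0)
        if not np.isfinite(bmdl):
            diagnostics["undefined"] = (
                "lower confidence limit of f never reaches log(1-BMR)"
            )
    return BenchmarkResult(
        bmd=bmd,
        bmdl=bmdl,
        method="closed_form",
        family=fit.family,
        bmr=config.bmr,
        diagnostics=diagnostics,
        fit=fit,
    )


def _smallest_crossing(LC, A: float, scale: float) -> float:
    """Smallest positive dose with LC(d) <= A (LC(0) = 0 > A).

    ``LC`` must accept dose arrays.  Scans an expanding grid for the first
    sign change, then solves by brentq within the bracketing cell.
    """
    upper = 4.0 * scale
    for _ in range(40):
        grid = np.linspace(0.0, upper, 2049)
        vals = np.asarray(LC(grid))
        below = vals <= A
        if below.any():
            j = int(np.argmax(below))
            lo, hi = grid[j - 1], grid[j]
            if vals[j] == A:
                return float(grid[j])
            return float(
                brentq(lambda x: float(LC(x)) - A, lo, hi, xtol=1e-14, rtol=1e-15)
            )
        upper *= 4.0
        if upper > 1e9 * scale:
            break
    return float("nan")


# ---------------------------------------------------------------------------
# profile likelihood BMDL
# ---------------------------------------------------------------------------


def _profile_pieces(data):
    """(y, C, d, sqrt_w, nobs_eff) for constrained refits on either data kind."""
    C, _ = _covariate_block(data)
    if isinstance(data, SummaryDataset):
        return (
            data.mean_log_outcome,
            C,
            data.mean_dose,
            np.sqrt(np.asarray(data.n_g, float)),
            data.K,
        )
    return data.y, C, data.single_dose, None, data.n


def _constrained_rss(y, C, d, sw, family, b: float, A: float, d0, gamma_max) -> float:
    """Minimized (weighted) RSS subject to the constraint f(b) = A.

    For every family the constraint pins the linear f-coefficients given the
    profiled shape parameter, so the inner problem is least squares of an
    offset outcome on the covariate block (plus, for piecewise, a modified
    free regressor).
    """

    def solve(X, target):
        if sw is not None:
            X = X * sw[:, None]
            target = target * sw
        return _lstsq_rss(X, target)

    if family == "linear":
        return solve(C, y - (A / b) * d)
    if family == "piecewise":
        x1 = np.minimum(d, d0)
        x2 = np.maximum(d - d0, 0.0)
        if b <= d0:
            return solve(np.column_stack([C, x2]), y - (A / b) * x1)
        xmod = x2 - ((b - d0) / d0) * x1
        return solve(np.column_stack([C, xmod]), y - (A / d0) * x1)
    if family == "kpower":

        def rss_at(K: float) -> float:
            return solve(C, y - A * (d / b) ** K)

        grid = np.linspace(1.0, 15.0, 57)
        vals = [rss_at(K) for K in grid]
        j = int(np.argmin(vals))
        from scipy.optimize import minimize_scalar

        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
        opt = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded")
        return min(float(opt.fun), vals[j])
    # hockey: profile the threshold below the candidate BMD
    gmax = min(b * (1.0 - 1e-9), gamma_max)
    grid = np.linspace(0.0, gmax, 200)
    best = np.inf
    for g in grid:
        rss = solve(C, y - (A / (b - g)) * np.maximum(d - g, 0.0))
        if rss < best:
            best = rss
    return best


def bmdl_profile_likelihood(
    data,
    family: str = "linear",
    config: BenchmarkConfig | None = None,
    d0: float | None = None,
    grid_size: int = 200,
    fit: DoseResponseFit | None = None,
) -> BenchmarkResult:
    """Profile-likelihood BMDL for any family (bisection below the BMD).

    The deviance profile 2*(logL_hat - logL_p(BMD)) is compared with the
    chi-square(1) 90th percentile; the BMDL is the smallest BMD meeting the
    cut-off, located by root finding below the BMD estimate.
    """
    if config is None:
        config = BenchmarkConfig(method="profile_likelihood")
    if fit is None:
        fit = fit_family(data, family=family, d0=d0, grid_size=grid_size)
    data = fit.data
    family = fit.family
    bmd = bmd_from_fit(fit, config.bmr)
    diagnostics: dict = {"chi2_cutoff": CHI2_1_90}
    if not np.isfinite(bmd):
        diagnostics["undefined"] = "BMD undefined (non-adverse fitted slope)"
        return BenchmarkResult(
            bmd=bmd, bmdl=float("nan"), method="profile_likelihood",
            family=family, bmr=config.bmr, diagnostics=diagnostics, fit=fit,
        )

    y, C, d, sw, nobs = _profile_pieces(data)
    A = float(np.log1p(-config.bmr))
    rss_full = fit.rss
    gamma_max = float(np.quantile(d, 0.95))

    def deviance(b: float) -> float:
        rss = _constrained_rss(y, C, d, sw, family, b, A, fit.d0, gamma_max)
        return max(nobs * np.log(rss / rss_full), 0.0)

    target = CHI2_1_90
    b_hi = bmd
    b_lo = bmd
    for _ in range(200):
        b_lo *= 0.5
        if deviance(b_lo) > target:
            break
    else:
        trace = [(b, deviance(b)) for b in bmd * 2.0 ** -np.arange(1, 8)]
        raise RuntimeError(
            f"could not bracket the profile deviance cut-off below BMD={bmd:.4g}; "
            f"profile trace: {trace}"
        )
    bmdl = float(
        brentq(lambda b: deviance(b) - target, b_lo, b_hi, xtol=1e-12, rtol=1e-10)
    )
    diagnostics["deviance_at_bmdl"] = deviance(bmdl)
    return BenchmarkResult(
        bmd=bmd,
        bmdl=bmdl,
        method="profile_likelihood",
        family=family,
        bmr=config.bmr,
        diagnostics=diagnostics,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# parametric bootstrap BMDL
# ---------------------------------------------------------------------------


def _replace_outcome(data, y_new):
    if isinstance(data, SummaryDataset):
        return SummaryDataset(
            mean_dose=data.mean_dose,
            mean_log_outcome=y_new,
            n_g=data.n_g,
            mean_covariates=data.mean_covariates,
            covariate_names=data.covariate_names,
            boundaries=data.boundaries,
        )
    return data.replace_outcome(y_new)


def bmdl_parametric_bootstrap(
    data,
    family: str = "linear",
    config: BenchmarkConfig | None = None,
    d0: float | None = None,
    grid_size: int = 200,
    fit: DoseResponseFit | None = None,
) -> BenchmarkResult:
    """Parametric-bootstrap BMDL: 5th percentile of re-estimated BMDs.

    ``n_boot`` outcome vectors are simulated from the fitted Gaussian model
    at the observed doses and covariates, the model is refitted to each, and
    the BMDL is the empirical ``alpha`` percentile of the BMD estimates.
    Replicates with an undefined BMD enter the percentile as +infinity
    (conservative for a lower limit) and are counted in the diagnostics; if
    more than half are undefined the BMDL itself is reported undefined.

    When a hockey-stick fit puts the threshold at the boundary (at or below
    the smallest dose), the model is indistinguishable from the linear one
    and the bootstrap is carried out under the linear model, with a
    diagnostic flag, rather than resampling an unidentified threshold.
    """
    if config is None:
        config = BenchmarkConfig(method="parametric_bootstrap")
    if fit is None:
        fit = fit_family(data, family=family, d0=d0, grid_size=grid_size)
    data = fit.data
    family = fit.family
    diagnostics: dict = {"n_boot": config.n_boot, "seed": config.seed}

    boot_family = family
    if family == "hockey" and fit.profile is not None and fit.profile.is_boundary:
        boot_family = "linear"
        diagnostics["hockey_boundary"] = (
            "threshold at/below the smallest dose; bootstrap run under the "
            "linear-model limit"
        )

    rng = np.random.default_rng(config.seed)
    mean = fit.fitted_mean
    if isinstance(data, SummaryDataset):
        sd = np.sqrt(fit.params.sigma2 / np.asarray(data.n_g, float))
    else:
        sd = np.sqrt(fit.params.sigma2)
    bmds = np.empty(config.n_boot)
    n_fail = 0
    for i in range(config.n_boot):
        y_star = mean + sd * rng.standard_normal(mean.size)
        try:
            fit_star = fit_family(
                _replace_outcome(data, y_star),
                family=boot_family,
                d0=fit.d0,
                grid_size=grid_size,
            )
            b = bmd_from_fit(fit_star, config.bmr)
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            n_fail += 1
            b = float("nan")
        bmds[i] = b if np.isfinite(b) else np.inf

    n_undef = int(np.sum(~np.isfinite(bmds)))
    diagnostics["n_undefined"] = n_undef
    diagnostics["n_fit_failures"] = n_fail
    finite = bmds[np.isfinite(bmds)]
    if finite.size:
        diagnostics["boot_percentiles"] = {
            str(q): float(np.percentile(finite, q)) for q in (5, 25, 50, 75, 95)
        }
    if n_undef > 0.5 * config.n_boot:
        diagnostics["undefined"] = "more than half of the bootstrap BMDs undefined"
        bmdl = float("nan")
    else:
        bmdl = float(np.quantile(bmds, config.alpha))
    return BenchmarkResult(
        bmd=bmd_from_fit(fit, config.bmr),
        bmdl=bmdl,
        method="parametric_bootstrap",
        family=family,
        bmr=config.bmr,
        diagnostics=diagnostics,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# dispatch and model retention
# ---------------------------------------------------------------------------


def benchmark_from_fit(fit: DoseResponseFit, config: BenchmarkConfig) -> BenchmarkResult:
    """Compute the BMDL for an existing fit with the configured method."""
    if config.method == "closed_form":
        return bmdl_closed_form(fit, config)
    if config.method == "profile_likelihood":
        return bmdl_profile_likelihood(fit.data, config=config, fit=fit)
    return bmdl_parametric_bootstrap(fit.data, config=config, fit=fit)


def compute_bmdl(
    data, family: str, config: BenchmarkConfig, d0: float | None = None,
    grid_size: int = 200,
) -> tuple[DoseResponseFit, BenchmarkResult]:
    """Fit one family and compute its benchmark result in one call."""
    fitted = fit_family(data, family=family, d0=d0, grid_size=grid_size)
    return fitted, benchmark_from_fit(fitted, config)


@dataclass
class ModelSelection:
    """Outcome of the delta-AIC retention rule across candidate models."""

    retained: list[int]
    reported_bmdl: float
    delta_aic: np.ndarray
    excluded_undefined: list[int]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ModelSelection(retained={self.retained}, "
            f"reported_bmdl={self.reported_bmdl:.4g})"
        )


def select_models(fits, results, max_delta_aic: float = 2.0) -> ModelSelection:
    """Retain all models within ``max_delta_aic`` of the best AIC.

    Models with an undefined BMDL are excluded from retention (and from the
    AIC reference) with a logged note; the reported BMDL is the smallest
    among the retained models.
    """
    if len(fits) != len(results):
        raise ValueError("fits and results must pair up")
    aics = np.array([float(f.aic) for f in fits])
    defined = np.array(
        [np.isfinite(r.bmdl) and np.isfinite(aics[i]) for i, r in enumerate(results)]
    )
    excluded = [i for i in range(len(fits)) if not defined[i]]
    for i in excluded:
        logger.info(
            "model %d (%s) excluded from retention: BMDL not available",
            i,
            getattr(fits[i], "family", "?"),
        )
    if not defined.any():
        raise ValueError("no candidate model has a finite AIC and a defined BMDL")
    ref = aics[defined].min()
    retained = [
        i for i in range(len(fits)) if defined[i] and aics[i] - ref <= max_delta_aic
    ]
    reported = min(float(results[i].bmdl) for i in retained)
    return ModelSelection(
        retained=retained,
        reported_bmdl=reported,
        delta_aic=aics - ref,
        excluded_undefined=excluded,
    )
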