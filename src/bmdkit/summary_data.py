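"""Grouped (decile) summary datasets and the grouping-bias diagnostic.

Under the linear outcome model the group-mean outcome satisfies

    Ybar_g = alpha + beta * dbar_g + eps_g,   eps_g ~ N(0, sigma^2 / n_g),

so regression parameters remain estimable from group means (with weight
``n_g``), at the cost of a larger variance.  For nonlinear dose-response
functions the group mean of the transformed dose differs from the transformed
group-mean dose, ``f(dbar_g) != mean_g f(d)``, which induces bias; the
:func:`mean_transform_gap` diagnostic quantifies that driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import IndividualDataset
from .models import DoseResponseSpec, evaluate_f

__all__ = ["SummaryDataset", "make_deciles", "mean_transform_gap", "read_summary_csv"]


@dataclass
class SummaryDataset:
    """Per-group summary data: mean dose, mean log outcome and group size."""

    mean_dose: np.ndarray
    mean_log_outcome: np.ndarray
    n_g: np.ndarray
    mean_covariates: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()
    boundaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_dose = np.asarray(self.mean_dose, float).ravel()
        self.mean_log_outcome = np.asarray(self.mean_log_outcome, float).ravel()
        self.n_g = np.asarray(self.n_g)
        K = self.mean_dose.size
        if self.mean_log_outcome.size != K or self.n_g.size != K:
            raise ValueError("group columns must have equal length")
        if np.any(self.n_g < 1):
            raise ValueError("group sizes must be >= 1")
        if np.any(np.diff(self.mean_dose) <= 0):
            raise ValueError("group mean doses must be strictly increasing")
        if self.mean_covariates is None:
            self.mean_covariates = np.empty((K, 0))
        self.mean_covariates = np.asarray(self.mean_covariates, float)
        if self.mean_covariates.ndim == 1:
            self.mean_covariates = self.mean_covariates[:, None]

    @property
    def K(self) -> int:
        return self.mean_dose.size

    @property
    def n(self) -> int:
        return int(self.n_g.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group": np.arange(1, self.K + 1),
                "mean_dose": self.mean_dose,
                "mean_log_outcome": self.mean_log_outcome,
                "n": self.n_g,
            }
        )
        for j, name in enumerate(self.covariate_names):
            df[f"mean_{name}"] = self.mean_covariates[:, j]
        return df


def make_deciles(data: IndividualDataset, K: int = 10) -> SummaryDataset:
    """Group subjects into ``K`` dose-quantile groups and average within groups.

    Subjects are ranked by dose (stable order, so ties are resolved by their
    original row order) and split into ``K`` groups of near-equal size; the
    per-group means of dose, log outcome and each covariate are returned.
    Boundaries are type-7 interpolation quantiles of the dose, recorded for
    reference (e.g. to place a piecewise break at a decile boundary).
    """
    if data.n_exposures != 1:
        raise ValueError("grouping requires a single dose column (use an index)")
    if K < 1:
        raise ValueError("K must be positive")
    if K > data.n / 2:
        raise ValueError(f"K={K} too large for n={data.n} (need n >= 2K)")
    dose = data.single_dose
    if np.ptp(dose) == 0:
        raise ValueError("constant dose: group boundaries are undefined")

    order = np.argsort(dose, kind="stable")
    edges = (np.arange(K + 1) * data.n) // K
    mean_dose = np.empty(K)
    mean_y = np.empty(K)
    n_g = np.empty(K, dtype=int)
    mean_z = np.empty((K, data.p))
    for g in range(K):
        idx = order[edges[g] : edges[g + 1]]
        n_g[g] = idx.size
        mean_dose[g] = dose[idx].mean()
        mean_y[g] = data.y[idx].mean()
        if data.p:
            mean_z[g] = data.covariates[idx].mean(axis=0)
    if np.any(np.diff(mean_dose) <= 0):
        raise ValueError("tied doses give non-increasing group means; reduce K")
    boundaries = np.quantile(dose, np.arange(K + 1) / K)
    return SummaryDataset(
        mean_dose=mean_dose,
        mean_log_outcome=mean_y,
        n_g=n_g,
        mean_covariates=mean_z if data.p else None,
        covariate_names=data.covariate_names,
        boundaries=boundaries,
    )


def mean_transform_gap(
    data: IndividualDataset, spec: DoseResponseSpec, K: int = 10
) -> np.ndarray:
    """Per-group gap |f(dbar_g) - mean_g f(d)| driving summary-data bias.

    Exactly zero for a linear ``f``; positive for strictly convex/concave
    families on spread-out groups (Jensen), and shrinking as ``K`` grows and
    the dose response becomes approximately linear within groups.
    """
    summary = make_deciles(data, K=K)
    dose = data.single_dose
    order = np.argsort(dose, kind="stable")
    edges = (np.arange(K + 1) * data.n) // K
    gaps = np.empty(K)
    for g in range(K):
        idx = order[edges[g] : edges[g + 1]]
        gaps[g] = abs(
            evaluate_f(spec, summary.mean_dose[g])
            - np.mean(evaluate_f(spec, dose[idx]))
        )
    return gaps


def read_summary_csv(path) -> SummaryDataset:
    """Read grouped summary data from CSV.

    Expected columns: ``group``, ``mean_dose``, ``mean_log_outcome``, ``n``;
    any column named ``mean_<name>`` is carried as a group-mean covariate.
    """
    df = pd.read_csv(path)
    required = {"mean_dose", "mean_log_outcome", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    df = df.sort_values("mean_dose")
    cov_cols = [
        c
        for c in df.columns
        if c.startswith("mean_") and c not in ("mean_dose", "mean_log_outcome")
    ]
    return SummaryDataset(
        mean_dose=df["mean_dose"].to_numpy(float),
        mean_log_outcome=df["mean_log_outcome"].to_numpy(float),
        n_g=df["n"].to_numpy(int),
        mean_covariates=df[cov_cols].to_numpy(float) if cov_cols else None,
        covariate_names=tuple(c.removeprefix("mean_") for c in cov_cols),
    )
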