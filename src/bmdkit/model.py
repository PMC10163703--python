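"""High-level Model/Results interface.

``DoseResponseModel`` is the front door of the package: construct it from a
dataset (or a DataFrame), call :meth:`fit` to obtain a
:class:`~bmdkit.fitting.DoseResponseFit` results object, and ask the results
for benchmark doses::

    model = DoseResponseModel.from_dataframe(df, outcome="outcome",
                                             dose="dose", family="linear")
    res = model.fit()
    print(res.summary())
    bench = res.benchmark(bmr=0.10, method="closed_form")
    print(bench.bmd, bench.bmdl)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import IndividualDataset, PFAS_NAMES
from .fitting import DoseResponseFit, fit as _fit
from .models import FAMILIES
from .summary_data import SummaryDataset

__all__ = ["DoseResponseModel"]


class DoseResponseModel:
    """Covariate-adjusted dose-response model for a log-normal outcome.

    Parameters
    ----------
    data : IndividualDataset or SummaryDataset
        The observations (individual subjects, or group means with sizes).
    family : str
        Dose-response family: ``linear``, ``piecewise``, ``kpower`` or
        ``hockey`` (the last two for individual data only... kpower is also
        available for summary data).
    d0 : float, optional
        Fixed break of the piecewise family; defaults to the median dose
        (individual data) or the median group boundary (summary data).
    grid_size : int
        Number of grid points for hockey-stick threshold profiling.
    """

    def __init__(self, data, family: str = "linear", d0: float | None = None,
                 grid_size: int = 200):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if not isinstance(data, (IndividualDataset, SummaryDataset)):
            raise TypeError("data must be an IndividualDataset or SummaryDataset")
        self.data = data
        self.family = family
        self.d0 = d0
        self.grid_size = grid_size

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "outcome",
        dose: str | list[str] | None = None,
        covariates: list[str] | None = None,
        log_outcome: bool = True,
        **kwargs,
    ) -> "DoseResponseModel":
        """Build a model from a tidy per-subject DataFrame.

        ``dose`` is one column name, a list of the four PFAS columns, or
        omitted to auto-detect (``dose`` column, else the four PFAS names).
        Columns not used as outcome or dose become covariates unless an
        explicit list is given.
        """
        cols = list(df.columns)
        if dose is None:
            if "dose" in cols:
                dose_cols = ["dose"]
            elif all(name in cols for name in PFAS_NAMES):
                dose_cols = list(PFAS_NAMES)
            else:
                raise ValueError(
                    "could not auto-detect dose columns; pass dose= explicitly"
                )
        else:
            dose_cols = [dose] if isinstance(dose, str) else list(dose)
        if covariates is None:
            covariates = [c for c in cols if c != outcome and c not in dose_cols]
        y = df[outcome].to_numpy(float)
        if log_outcome:
            if np.any(y <= 0):
                raise ValueError("outcome must be positive to log-transform")
            y = np.log(y)
        dose_arr = df[dose_cols].to_numpy(float)
        if dose_arr.shape[1] == 1:
            dose_arr = dose_arr[:, 0]
        data = IndividualDataset(
            y=y,
            dose=dose_arr,
            covariates=df[covariates].to_numpy(float) if covariates else None,
            covariate_names=tuple(covariates),
            dose_names=tuple(dose_cols),
        )
        return cls(data, **kwargs)

    def fit(self) -> DoseResponseFit:
        """Estimate the model; returns the results object."""
        return _fit(self.data, family=self.family, d0=self.d0,
                    grid_size=self.grid_size)
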