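"""In-memory containers and CSV readers for individual-level study data."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PFAS_NAMES", "IndividualDataset", "read_individual_csv"]

logger = logging.getLogger(__name__)

#: canonical order of the four exposure columns in mixture analyses
PFAS_NAMES = ("pfoa", "pfos", "pfhxs", "pfna")


@dataclass
class IndividualDataset:
    """Per-subject data for the covariate-adjusted log-outcome model.

    Attributes
    ----------
    y : ndarray, shape (n,)
        Log-transformed outcome (e.g. log antibody concentration).
    dose : ndarray, shape (n,) or (n, 4)
        Exposure concentrations in ng/mL.  A single column is used directly;
        four columns (PFOA, PFOS, PFHxS, PFNA) support mixture analyses, and
        single-exposure models then act on the summed concentration.
    covariates : ndarray, shape (n, p)
        Covariate matrix (may have zero columns).
    """

    y: np.ndarray
    dose: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()
    dose_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.dose = np.asarray(self.dose, dtype=float)
        n = self.y.size
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if not np.all(np.isfinite(self.y)):
            raise ValueError("log-outcome values must be finite")
        if np.any(self.dose < 0):
            raise ValueError("doses must be non-negative")
        if self.dose.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("y, dose and covariates must have the same length")
        if self.dose.ndim == 2 and self.dose.shape[1] not in (1, 4):
            raise ValueError("dose must be a single column or four (PFAS) columns")
        if not self.covariate_names:
            self.covariate_names = tuple(
                f"z{j + 1}" for j in range(self.covariates.shape[1])
            )

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_exposures(self) -> int:
        return 1 if self.dose.ndim == 1 else self.dose.shape[1]

    @property
    def exposures(self) -> np.ndarray:
        """Exposure matrix of shape (n, n_exposures)."""
        return self.dose[:, None] if self.dose.ndim == 1 else self.dose

    @property
    def single_dose(self) -> np.ndarray:
        """The dose used by single-exposure models.

        For four-column (PFAS) data this is the summed concentration, i.e.
        the equal-weight exposure index.
        """
        if self.dose.ndim == 1:
            return self.dose
        if self.dose.shape[1] == 1:
            return self.dose[:, 0]
        return self.dose.sum(axis=1)

    def replace_outcome(self, y_new: np.ndarray) -> "IndividualDataset":
        """New dataset with the same design but a different outcome vector."""
        return IndividualDataset(
            y=y_new,
            dose=self.dose,
            covariates=self.covariates,
            covariate_names=self.covariate_names,
            dose_names=self.dose_names,
        )


def read_individual_csv(
    path,
    outcome: str = "outcome",
    dose: str | None = None,
    covariates: list[str] | None = None,
    log_outcome: bool = True,
) -> IndividualDataset:
    """Read individual-level data from CSV.

    The file must have a header row with an ``outcome`` column (raw positive
    concentrations unless ``log_outcome=False``) plus either a single dose
    column (default name ``dose``) or the four PFAS columns
    ``pfoa, pfos, pfhxs, pfna``.  Remaining columns are treated as covariates
    unless an explicit ``covariates`` list is given.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if outcome.lower() not in cols:
        raise ValueError(f"missing outcome column {outcome!r} in {path}")
    y_raw = df[cols[outcome.lower()]].to_numpy(float)

    if dose is not None:
        if dose.lower() not in cols:
            raise ValueError(f"missing dose column {dose!r} in {path}")
        dose_cols = [cols[dose.lower()]]
        dose_names = (dose,)
    elif "dose" in cols:
        dose_cols = [cols["dose"]]
        dose_names = ("dose",)
    elif all(name in cols for name in PFAS_NAMES):
        dose_cols = [cols[name] for name in PFAS_NAMES]
        dose_names = PFAS_NAMES
    else:
        raise ValueError(
            f"no dose column found in {path}: expected 'dose' or the four "
            f"PFAS columns {PFAS_NAMES}"
        )

    if covariates is None:
        used = {cols[outcome.lower()], *dose_cols}
        cov_cols = [c for c in df.columns if c not in used]
    else:
        cov_cols = [cols[c.lower()] for c in covariates]

    if log_outcome:
        if np.any(y_raw <= 0):
            raise ValueError("outcome must be strictly positive to log-transform")
        y = np.log(y_raw)
        logger.info("log-transformed outcome column %r", outcome)
    else:
        y = y_raw

    dose_arr = df[dose_cols].to_numpy(float)
    if dose_arr.shape[1] == 1:
        dose_arr = dose_arr[:, 0]
    return IndividualDataset(
        y=y,
        dose=dose_arr,
        covariates=df[cov_cols].to_numpy(float) if cov_cols else None,
        covariate_names=tuple(cov_cols),
        dose_names=dose_names,
    )
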