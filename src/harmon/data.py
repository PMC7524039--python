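"""Data containers and file I/O for multi-site ROI measurement tables.

The package operates on two aligned tables:

* a wide measurement table, one row per subject and one column per ROI
  (e.g. Desikan-Killiany cortical thickness / surface area and subcortical
  volumes), with possibly missing cells;
* a covariate table with the diagnosis indicator, the acquisition site and
  any additional covariates (age, sex, ICV, ...).

Missing measurements are carried as an explicit boolean mask (``observed``)
alongside NaN-filled values, so that temporary imputations made while
fitting harmonization parameters can never leak back into the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class ROIMatrix:
    """Subject x ROI measurement matrix with explicit missingness.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_rois)
        Measurements; ``NaN`` marks an unobserved cell. Units are whatever
        the input table used (mm, mm^2, mm^3) and are never interpreted.
    roi_names : list of str
        Unique column labels.
    subject_ids : list of str
        Unique row labels.
    site : ndarray of str, shape (n_subjects,)
        Acquisition-site label per subject.
    """

    values: np.ndarray
    roi_names: list[str]
    subject_ids: list[str]
    site: np.ndarray
    observed: np.ndarray = field(default=None)  # True where measured

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.site = np.asarray(self.site, dtype=object)
        self.roi_names = list(self.roi_names)
        self.subject_ids = list(self.subject_ids)
        if self.observed is None:
            self.observed = ~np.isnan(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        n, r = self.values.shape
        if self.observed.shape != (n, r):
            raise DataValidationError("values and observed mask differ in shape")
        if len(self.roi_names) != r:
            raise DataValidationError("roi_names length does not match values")
        if len(self.subject_ids) != n or len(self.site) != n:
            raise DataValidationError("subject_ids/site length does not match values")
        if len(set(self.roi_names)) != r:
            raise DataValidationError("ROI names are not unique")
        if len(set(self.subject_ids)) != n:
            raise DataValidationError("subject IDs are not unique")
        if np.any(np.isnan(self.values[self.observed])):
            raise DataValidationError("observed cells must be finite")
        # keep NaN and mask consistent
        self.values = np.where(self.observed, self.values, np.nan)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def site_levels(self) -> list[str]:
        """Site labels in order of first appearance."""
        return list(dict.fromkeys(self.site))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.roi_names)

    def copy(self) -> "ROIMatrix":
        return ROIMatrix(
            self.values.copy(), list(self.roi_names), list(self.subject_ids),
            self.site.copy(), self.observed.copy(),
        )


@dataclass
class CovariateTable:
    """Per-subject diagnosis and covariates, row-aligned with an ROIMatrix.

    ``table`` holds one column per covariate; the diagnosis column (named by
    ``diagnosis_column``, default ``"dx"``) is a 0/1 indicator with 1 = case.
    """

    table: pd.DataFrame
    diagnosis_column: str = "dx"

    def __post_init__(self) -> None:
        t = self.table
        if self.diagnosis_column not in t.columns:
            raise DataValidationError(f"missing diagnosis column {self.diagnosis_column!r}")
        if t.isna().any().any():
            bad = t.columns[t.isna().any()].tolist()
            raise DataValidationError(f"missing covariate values in columns {bad}")
        dx = t[self.diagnosis_column]
        if not set(np.unique(dx)) <= {0, 1}:
            raise DataValidationError("diagnosis must be coded 0/1")
        if dx.nunique() < 2:
            raise DataValidationError("diagnosis must have both levels overall")
        for c in t.columns:
            if not np.issubdtype(t[c].dtype, np.number):
                raise DataValidationError(f"covariate {c!r} is not numeric (code binaries 0/1)")

    @property
    def diagnosis(self) -> np.ndarray:
        return self.table[self.diagnosis_column].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> list[str]:
        """All covariate columns, diagnosis first."""
        rest = [c for c in self.table.columns if c != self.diagnosis_column]
        return [self.diagnosis_column] + rest

    def __len__(self) -> int:
        return len(self.table)

    def replace_diagnosis(self, dx: np.ndarray) -> "CovariateTable":
        t = self.table.copy()
        t[self.diagnosis_column] = np.asarray(dx)
        return CovariateTable(t, self.diagnosis_column)


@dataclass
class DesignMatrix:
    """Fixed-effects design: intercept, then diagnosis, then covariates.

    When built with ``include_diagnosis=True`` the first non-intercept
    column is the 0/1 diagnosis indicator, whose coefficient is the
    case-control difference of interest.
    """

    matrix: np.ndarray
    names: list[str]
    has_diagnosis: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DataValidationError(
                "design matrix is rank deficient (constant or collinear covariates)"
            )

    @property
    def n_covariates(self) -> int:
        """Number of nuisance covariates (columns beyond intercept and diagnosis)."""
        return self.matrix.shape[1] - 1 - int(self.has_diagnosis)


def build_design(cov: CovariateTable, include_diagnosis: bool = True) -> DesignMatrix:
    """Assemble [intercept, diagnosis, covariates...] from a covariate table.

    Binary covariates are expected already coded 0/1; continuous covariates
    are passed through unscaled so that harmonized values stay on the
    original measurement scale. Raises on rank deficiency (e.g. a constant
    covariate such as sex in a single-sex sample).
    """
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    order = cov.covariate_names if include_diagnosis else cov.covariate_names[1:]
    for c in order:
        cols.append(cov.table[c].to_numpy(dtype=float))
        names.append(c)
    return DesignMatrix(np.column_stack(cols), names, has_diagnosis=include_diagnosis)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip parsing keeps written floats bit-identical on reload
    return pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")


def load_dataset(
    measurements_path,
    covariates_path,
    site_column: str = "site",
    subject_column: str | None = None,
    diagnosis_column: str = "dx",
) -> tuple[ROIMatrix, CovariateTable]:
    """Load and ID-align a measurement table and a covariate table.

    Both files are CSV/TSV with a header row and share one subject-ID
    column (by default the first column of each file). Subjects are matched
    by case-sensitive exact ID (inner join), so row order in the files is
    irrelevant. Empty measurement cells become missing; missing covariate
    cells are an error.
    """
    meas = _read_table(measurements_path)
    cov = _read_table(covariates_path)
    id_m = subject_column or meas.columns[0]
    id_c = subject_column or cov.columns[0]
    for df, idc, what in ((meas, id_m, "measurement"), (cov, id_c, "covariate")):
        if df[idc].duplicated().any():
            dups = df.loc[df[idc].duplicated(), idc].tolist()
            raise DataValidationError(f"duplicated subject IDs in {what} file: {dups[:5]}")
    meas = meas.set_index(id_m)
    cov = cov.set_index(id_c)
    common = meas.index.intersection(cov.index)
    if len(common) == 0:
        raise DataValidationError("no overlapping subject IDs between the two files")
    # keep the measurement file's row order for the subjects retained
    common = [s for s in meas.index if s in set(common)]
    meas = meas.loc[common]
    cov = cov.loc[common]
    if site_column not in cov.columns:
        raise DataValidationError(f"covariate file lacks site column {site_column!r}")
    site = cov[site_column].astype(str).to_numpy()
    cov = cov.drop(columns=[site_column])

    vals = np.full(meas.shape, np.nan)
    for j, c in enumerate(meas.columns):
        col = pd.to_numeric(meas[c], errors="coerce")
        bad = col.isna() & meas[c].notna() & (meas[c].astype(str).str.strip() != "")
        if bad.any():
            raise DataValidationError(
                f"non-numeric measurement in column {c!r}, subject {meas.index[bad.argmax()]!r}"
            )
        vals[:, j] = col.to_numpy(dtype=float)

    roi = ROIMatrix(vals, list(meas.columns), list(meas.index), site)
    # put diagnosis first for readability; validation happens in the constructor
    ordered = [diagnosis_column] + [c for c in cov.columns if c != diagnosis_column]
    if diagnosis_column not in cov.columns:
        raise DataValidationError(f"covariate file lacks diagnosis column {diagnosis_column!r}")
    table = CovariateTable(cov[ordered], diagnosis_column)
    return roi, table


def write_dataset(data: ROIMatrix, path, subject_column: str = "subject_id") -> None:
    """Write an ROIMatrix back to wide CSV; missing cells become empty."""
    df = data.to_frame()
    df.index.name = subject_column
    df.to_csv(path, na_rep="")
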