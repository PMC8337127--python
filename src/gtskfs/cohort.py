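"""Patient-cohort I/O, schema validation and feature standardization.

A cohort is a plain CSV with one header row and one row per patient.  The
default feature set is the clinical covariate list used for Kt/V prediction:
sex, age, ultrafiltration, pre/post-dialysis weight, pre/post systolic and
diastolic pressure, pre/post heart rate, and blood flow.  An extended set
with the additional descriptive covariates (dry weight, conductivity,
venous/transmembrane pressure, ...) is available via ``EXTENDED_FEATURES``.

Features are z-scored with a scaler fitted on training data only; the scaler
parameters travel with the :class:`FeatureMatrix` so they can be re-applied
to held-out folds or new patients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateFeatureError, ParseError, SchemaError

#: Clinical covariates entering the model by default (units in the name
#: where ambiguous; sex coded 0 = female, 1 = male).
DEFAULT_FEATURES: tuple[str, ...] = (
    "sex",
    "age",
    "uf_ml",
    "pre_bw_kg",
    "post_bw_kg",
    "sbp_pre",
    "dbp_pre",
    "sbp_post",
    "dbp_post",
    "hr_pre",
    "hr_post",
    "blood_flow_ml_min",
)

#: Additional cohort descriptors available in the extended schema.
EXTENDED_FEATURES: tuple[str, ...] = DEFAULT_FEATURES + (
    "dry_weight_kg",
    "conductivity_ms_cm",
    "venous_pressure_mmhg",
    "tmp_mmhg",
    "dialysis_hdf",
    "vascular_catheter",
)

TARGET_COLUMN = "ktv"


@dataclass
class FeatureMatrix:
    """Numeric design matrix with optional targets and scaler state.

    Attributes
    ----------
    X : (N, d) array of feature values.
    columns : feature names, one per column of ``X``.
    y : (N,) target vector (Kt/V) or ``None`` at predict time.
    scaler_mean, scaler_scale : per-column standardization parameters, set
        once :func:`standardize` has been fitted; ``None`` on raw data.
    """

    X: np.ndarray
    columns: list[str]
    y: np.ndarray | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise SchemaError(f"feature matrix must be 2-d, got shape {self.X.shape}")
        if self.X.shape[1] != len(self.columns):
            raise SchemaError(
                f"{self.X.shape[1]} columns but {len(self.columns)} column names"
            )
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != (self.X.shape[0],):
                raise SchemaError(
                    f"target length {self.y.shape} does not match N={self.X.shape[0]}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        """Row-subset view (used for CV splits); scaler state is dropped."""
        return FeatureMatrix(
            X=self.X[rows],
            columns=list(self.columns),
            y=None if self.y is None else self.y[rows],
        )


def from_dataframe(
    df: pd.DataFrame,
    features: tuple[str, ...] | list[str] = DEFAULT_FEATURES,
    target: str | None = TARGET_COLUMN,
    require_target: bool = True,
) -> FeatureMatrix:
    """Validate a DataFrame against the cohort schema and extract arrays.

    Rows with any missing configured value are rejected (mirroring the
    study-style exclusion of incomplete records); the dropped 0-based row
    indices are recorded on the returned matrix as ``rejected_rows``.
    """
    features = list(features)
    for col in features:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    want_target = target is not None and (require_target or target in df.columns)
    if want_target and target not in df.columns:
        raise SchemaError(f"missing required target column: {target!r}")

    cols = features + ([target] if want_target else [])
    numeric = pd.DataFrame(index=df.index)
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        numeric[col] = converted

    complete = numeric.notna().all(axis=1).to_numpy()
    rejected = list(np.flatnonzero(~complete))
    numeric = numeric.loc[complete]

    _validate_physiology(numeric, features)

    fm = FeatureMatrix(
        X=numeric[features].to_numpy(dtype=float),
        columns=features,
        y=numeric[target].to_numpy(dtype=float) if want_target else None,
    )
    fm.rejected_rows = rejected  # type: ignore[attr-defined]
    return fm


def _validate_physiology(numeric: pd.DataFrame, features: list[str]) -> None:
    if not np.all(np.isfinite(numeric.to_numpy(dtype=float))):
        raise ParseError("non-finite value in cohort after validation")
    for col in ("pre_bw_kg", "post_bw_kg", "dry_weight_kg"):
        if col in features and (numeric[col] <= 0).any():
            row = int(np.flatnonzero((numeric[col] <= 0).to_numpy())[0])
            raise ParseError(f"nonpositive weight in column {col!r}, row {row}")
    if "uf_ml" in features and (numeric["uf_ml"] < 0).any():
        row = int(np.flatnonzero((numeric["uf_ml"] < 0).to_numpy())[0])
        raise ParseError(f"negative ultrafiltration in row {row}")


def read_cohort(
    path,
    features: tuple[str, ...] | list[str] = DEFAULT_FEATURES,
    target: str | None = TARGET_COLUMN,
    require_target: bool = True,
) -> FeatureMatrix:
    """Read a cohort CSV, validate it and return a :class:`FeatureMatrix`."""
    df = pd.read_csv(path)
    return from_dataframe(df, features=features, target=target, require_target=require_target)


def write_cohort(fm: FeatureMatrix, path, target: str = TARGET_COLUMN) -> None:
    """Write a cohort to CSV (inverse of :func:`read_cohort`)."""
    df = pd.DataFrame(fm.X, columns=fm.columns)
    if fm.y is not None:
        df[target] = fm.y
    df.to_csv(path, index=False, float_format="%.17g")


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column; the fitted mean/SD are stored for reuse.

    Raises :class:`DegenerateFeatureError` for a zero-variance column.
    Population (ddof=0) SD is used; the choice is immaterial as long as the
    same scaler is applied to train and test folds.
    """
    if fm.n < 2:
        raise DegenerateFeatureError("need at least 2 rows to fit a scaler")
    mean = fm.X.mean(axis=0)
    scale = fm.X.std(axis=0)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise DegenerateFeatureError(
            f"zero-variance feature column: {fm.columns[zero[0]]!r}"
        )
    out = replace(fm, X=(fm.X - mean) / scale)
    out.scaler_mean = mean
    out.scaler_scale = scale
    return out


def apply_scaler(fm: FeatureMatrix, mean: np.ndarray, scale: np.ndarray) -> FeatureMatrix:
    """Apply a previously fitted scaler (e.g. train-fold) to new data."""
    out = replace(fm, X=(fm.X - mean) / scale)
    out.scaler_mean = np.asarray(mean, dtype=float)
    out.scaler_scale = np.asarray(scale, dtype=float)
    return out


def inverse_standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Undo standardization using the stored scaler."""
    if fm.scaler_mean is None or fm.scaler_scale is None:
        raise DegenerateFeatureError("matrix carries no scaler to invert")
    out = replace(fm, X=fm.X * fm.scaler_scale + fm.scaler_mean)
    out.scaler_mean = None
    out.scaler_scale = None
    return out
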