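"""Plot-level soil sample tables and z-score standardization.

A soil dataset is a :class:`pandas.DataFrame` with one row per sampled plot
and the canonical columns

    plot_id      text label, unique per dataset
    alk_N        alkaline-hydrolyzable nitrogen, mg/kg
    avail_P      available phosphorus, mg/kg
    avail_K      available potassium, mg/kg
    applied_P    phosphorus fertilizer application, kg/ha
    applied_N    nitrogen fertilizer application, kg/ha
    applied_K    potassium fertilizer application, kg/ha
    yield_actual measured yield, kg

Standardization subtracts a per-attribute location and divides by a
per-attribute scale so attributes on very different magnitudes (potassium
~100 mg/kg, phosphorus ~10 mg/kg) become comparable.  With the default
``stdev`` convention the scale is the population standard deviation and the
output has mean 0 and variance 1; a ``variance`` convention (divide by the
population variance) is kept as an explicit alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NUMERIC_COLUMNS",
    "NUTRIENT_COLUMNS",
    "APPLICATION_COLUMNS",
    "TABLE1_COLUMN_MAP",
    "SchemaError",
    "ZeroVarianceError",
    "StandardizationParams",
    "read_samples",
    "write_samples",
    "validate_samples",
    "fixture_table1",
    "standardize",
    "inverse_standardize",
]

NUTRIENT_COLUMNS = ["alk_N", "avail_P", "avail_K"]
APPLICATION_COLUMNS = ["applied_P", "applied_N", "applied_K"]
NUMERIC_COLUMNS = NUTRIENT_COLUMNS + APPLICATION_COLUMNS + ["yield_actual"]

#: Mapping from the verbose survey-table headers to canonical column names.
TABLE1_COLUMN_MAP = {
    "Plot": "plot_id",
    "Alkaline hydrolysis nitrogen N (mg/kg)": "alk_N",
    "Available phosphorus P (mg/kg)": "avail_P",
    "Available potassium K (mg/kg)": "avail_K",
    "P application amount (kg/ha)": "applied_P",
    "Amount of N application (kg/ha)": "applied_N",
    "Amount of K application (kg/ha)": "applied_K",
    "Actual output (kg)": "yield_actual",
}


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ZeroVarianceError(ValueError):
    """A column slated for standardization is constant."""


# Ten plot records from the Penang durian orchard survey (area 2).
_TABLE1_ROWS = [
    ("2-A1", 22.74, 5.23, 64.10, 162.61, 76.39, 167.05, 162.65),
    ("2-A2", 22.53, 6.40, 60.80, 170.53, 82.66, 180.97, 153.81),
    ("2-A3", 20.78, 5.95, 66.17, 188.64, 79.85, 171.99, 160.81),
    ("2-A4", 23.52, 5.62, 74.65, 170.20, 86.42, 177.48, 178.93),
    ("2-A5", 21.89, 8.59, 77.06, 170.52, 72.53, 184.26, 173.38),
    ("2-B1", 22.68, 5.92, 58.27, 177.08, 73.94, 179.42, 165.55),
    ("2-B2", 20.01, 7.18, 63.35, 158.52, 80.09, 174.23, 185.35),
    ("2-B3", 22.36, 6.08, 85.20, 165.77, 88.00, 183.21, 157.33),
    ("2-B4", 24.74, 5.92, 71.92, 161.47, 75.21, 169.92, 163.21),
    ("2-B5", 24.92, 7.64, 79.59, 182.95, 84.26, 181.62, 182.03),
]


def fixture_table1() -> pd.DataFrame:
    """Return the ten published orchard plot records as a soil dataset."""
    return pd.DataFrame(_TABLE1_ROWS, columns=["plot_id"] + NUMERIC_COLUMNS)


def validate_samples(data: pd.DataFrame) -> pd.DataFrame:
    """Check the soil-dataset invariants, returning ``data`` unchanged.

    Raises
    ------
    SchemaError
        If a canonical column is missing.
    ValueError
        If a numeric field is non-finite, a nutrient or application value is
        negative, or plot ids repeat.
    """
    for col in ["plot_id"] + NUMERIC_COLUMNS:
        if col not in data.columns:
            raise SchemaError(f"missing required column {col!r}")
    values = data[NUMERIC_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite value in numeric columns")
    nonneg = NUTRIENT_COLUMNS + APPLICATION_COLUMNS
    if (data[nonneg].to_numpy(dtype=float) < 0).any():
        raise ValueError("nutrient and application values must be >= 0")
    if data["plot_id"].duplicated().any():
        dup = data.loc[data["plot_id"].duplicated(), "plot_id"].iloc[0]
        raise ValueError(f"duplicate plot_id {dup!r}")
    return data


def read_samples(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a plot-level soil sample CSV into a validated soil dataset.

    Parameters
    ----------
    path
        CSV file with a header row.  Canonical column names are expected;
        pass ``column_map`` (for example :data:`TABLE1_COLUMN_MAP`) to rename
        verbose headers first.
    """
    raw = pd.read_csv(path, dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    for col in ["plot_id"] + NUMERIC_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    out = pd.DataFrame({"plot_id": raw["plot_id"].astype(str)})
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"non-numeric value {raw[col].iloc[row]!r} in column {col!r} at row {row}"
            )
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise SchemaError(f"empty cell in column {col!r} at row {row}")
        out[col] = parsed.astype(float)
    if len(out):
        validate_samples(out)
    return out


def write_samples(data: pd.DataFrame, path) -> None:
    """Write a soil dataset to CSV with canonical headers."""
    validate_samples(data)
    data[["plot_id"] + NUMERIC_COLUMNS].to_csv(path, index=False)


@dataclass
class StandardizationParams:
    """Per-attribute location/scale of a fitted standardization.

    ``scale`` is the population standard deviation of each column under the
    default ``stdev`` convention, or the population variance under the
    ``variance`` convention.  Either way the forward transform is
    ``(x - mean) / scale`` and the inverse is ``z * scale + mean``.
    """

    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray
    convention: str = "stdev"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.convention not in ("stdev", "variance"):
            raise ValueError(f"unknown scale convention {self.convention!r}")
        if (self.scale <= 0).any():
            raise ZeroVarianceError("all scales must be positive")

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "convention": self.convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(list(d["columns"]), d["mean"], d["scale"], d["convention"])


def _as_matrix(data, columns):
    if isinstance(data, pd.DataFrame):
        cols = list(columns) if columns is not None else [
            c for c in data.columns if c != "plot_id"
        ]
        return data[cols].to_numpy(dtype=float), cols
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = list(columns) if columns is not None else [f"x{i}" for i in range(arr.shape[1])]
    return arr, cols


def standardize(data, columns=None, convention: str = "stdev"):
    """Center and scale each column; return the matrix and the fitted params.

    Parameters
    ----------
    data
        Soil dataset (DataFrame) or plain numeric matrix.  For a DataFrame,
        ``columns`` selects which columns to standardize (default: all
        numeric canonical columns present).
    convention
        ``"stdev"`` divides by the population standard deviation (output has
        mean 0, variance 1); ``"variance"`` divides by the population
        variance.

    Raises
    ------
    ZeroVarianceError
        Naming the first constant column encountered.
    """
    X, cols = _as_matrix(data, columns)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 records")
    mean = X.mean(axis=0)
    var = X.var(axis=0)  # population (divide-by-n) variance
    for j, v in enumerate(var):
        if v == 0:
            raise ZeroVarianceError(f"column {cols[j]!r} has zero variance")
    scale = np.sqrt(var) if convention == "stdev" else var
    params = StandardizationParams(cols, mean, scale, convention)
    return (X - mean) / scale, params


def apply_standardization(data, params: StandardizationParams) -> np.ndarray:
    """Apply previously fitted standardization parameters to new data."""
    X, cols = _as_matrix(data, params.columns)
    if cols != list(params.columns):
        raise ValueError("column set does not match standardization params")
    return (X - params.mean) / params.scale


def inverse_standardize(values, params: StandardizationParams) -> np.ndarray:
    """Map standardized values back to original units (inverse transform)."""
    Z = np.asarray(values, dtype=float)
    squeeze = Z.ndim == 1
    if squeeze:
        Z = Z[:, None]
    if Z.shape[1] != len(params.columns):
        raise ValueError(
            f"expected {len(params.columns)} columns, got {Z.shape[1]}"
        )
    out = Z * params.scale + params.mean
    return out[:, 0] if squeeze else out
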