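"""Reading, validation and writing of species-occurrence tables.

Occurrence records follow the Darwin Core column conventions used by GBIF
exports (``decimalLatitude``, ``speciesKey``, ...).  Internally the table is
a pandas DataFrame with canonical snake_case columns and explicit nulls for
missing values; rows violating the coordinate contract are dropped at read
time and accounted for in a :class:`ValidationReport`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical column -> Darwin Core name used in files
DWC_COLUMNS = {
    "species_key": "speciesKey",
    "species_name": "species",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "year": "year",
    "basis_of_record": "basisOfRecord",
    "coord_uncertainty_m": "coordinateUncertaintyInMeters",
    "coord_precision": "coordinatePrecision",
    "country_code": "countryCode",
    "dataset_key": "datasetKey",
}
_DWC_TO_CANONICAL = {v: k for k, v in DWC_COLUMNS.items()}

REQUIRED = ("species_key", "latitude", "longitude")

_NUMERIC = {
    "species_key": "Int64",
    "latitude": "float64",
    "longitude": "float64",
    "year": "Int64",
    "coord_uncertainty_m": "float64",
    "coord_precision": "float64",
}
_TEXT = ("species_name", "basis_of_record", "country_code", "dataset_key")


class ConfigurationError(ValueError):
    """A required column is absent or an option is inconsistent."""


@dataclasses.dataclass
class ValidationReport:
    """Accounting of rows dropped (or flagged) while reading a table."""

    rows_read: int = 0
    rows_kept: int = 0
    dropped_missing_required: int = 0
    dropped_unparseable: int = 0
    dropped_invalid_coords: int = 0
    dropped_zero_zero: int = 0
    flagged_zero_zero: int = 0

    def dropped_total(self) -> int:
        return (
            self.dropped_missing_required
            + self.dropped_unparseable
            + self.dropped_invalid_coords
            + self.dropped_zero_zero
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class OccurrenceTable:
    """A validated occurrence table plus its read-time validation report."""

    def __init__(self, data: pd.DataFrame, report: ValidationReport | None = None):
        self.data = data.reset_index(drop=True)
        self.report = report or ValidationReport(
            rows_read=len(data), rows_kept=len(data)
        )

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"OccurrenceTable({len(self)} rows, {self.data['species_key'].nunique()} species)"

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(self.data.copy(), dataclasses.replace(self.report))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".parquet", ".pq"):
        return "parquet"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def _canonicalize(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    rename = dict(_DWC_TO_CANONICAL)
    if column_map:
        # user map: {canonical_or_dwc_name: actual file column}
        for key, actual in column_map.items():
            canon = _DWC_TO_CANONICAL.get(key, key)
            rename[actual] = canon
    df = df.rename(columns=rename)
    return df[[c for c in DWC_COLUMNS if c in df.columns]]


def read_occurrences(
    path,
    format: str | None = None,
    column_map: dict | None = None,
    drop_zero_zero: bool = False,
) -> OccurrenceTable:
    """Read an occurrence table from Parquet, CSV or TSV.

    Rows with missing or unparseable ``species_key``/``latitude``/``longitude``
    or with coordinates outside the WGS84 domain are dropped and counted in
    the attached :class:`ValidationReport`.  Records at exactly (0, 0) are
    flagged (and dropped only when ``drop_zero_zero`` is set).

    Raises :class:`ConfigurationError` when a required column is absent.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "parquet":
        df = pd.read_parquet(path)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", dtype="object")
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")

    df = _canonicalize(df, column_map)
    for col in REQUIRED:
        if col not in df.columns:
            raise ConfigurationError(
                f"required column {DWC_COLUMNS[col]!r} ({col}) not found in {path.name}"
            )

    report = ValidationReport(rows_read=len(df))

    # typed columns; unparseable numeric cells become null (tracked below)
    unparseable = np.zeros(len(df), dtype=bool)
    for col, dtype in _NUMERIC.items():
        if col not in df.columns:
            fill = pd.NA if dtype == "Int64" else np.nan
            df[col] = pd.array([fill] * len(df), dtype=dtype)
            continue
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        if col in REQUIRED:
            unparseable |= raw.notna().to_numpy() & num.isna().to_numpy()
        df[col] = num.astype(dtype)
    for col in _TEXT:
        if col not in df.columns:
            df[col] = pd.Series([pd.NA] * len(df), dtype="object")
        else:
            df[col] = df[col].where(df[col].notna(), pd.NA).astype("object")

    df = df[list(DWC_COLUMNS)]

    keep = ~unparseable
    report.dropped_unparseable = int(unparseable.sum())
    df = df[keep]

    missing = df[list(REQUIRED)].isna().any(axis=1)
    report.dropped_missing_required = int(missing.sum())
    df = df[~missing]

    bad_coord = (
        (df["latitude"] < -90)
        | (df["latitude"] > 90)
        | (df["longitude"] < -180)
        | (df["longitude"] > 180)
    )
    report.dropped_invalid_coords = int(bad_coord.sum())
    df = df[~bad_coord]

    neg_unc = df["coord_uncertainty_m"].notna() & (df["coord_uncertainty_m"] < 0)
    report.dropped_invalid_coords += int(neg_unc.sum())
    df = df[~neg_unc]

    zz = (df["latitude"] == 0.0) & (df["longitude"] == 0.0)
    if drop_zero_zero:
        report.dropped_zero_zero = int(zz.sum())
        df = df[~zz]
    else:
        report.flagged_zero_zero = int(zz.sum())

    df = df.copy()
    df["species_key"] = df["species_key"].astype("int64")
    report.rows_kept = len(df)
    assert report.rows_kept + report.dropped_total() == report.rows_read
    return OccurrenceTable(df, report)


def write_occurrences(table: OccurrenceTable, path, format: str | None = None) -> Path:
    """Write a table using Darwin Core column names.

    Missing values are encoded as nulls (Parquet) or empty fields (CSV/TSV),
    never as sentinel numbers; ``read_occurrences(write_occurrences(t))``
    reproduces the table exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    out = table.data[list(DWC_COLUMNS)].rename(columns=DWC_COLUMNS)
    if fmt == "parquet":
        out.to_parquet(path, index=False)
    elif fmt in ("csv", "tsv"):
        out.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False)
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    return path
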