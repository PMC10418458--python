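"""CSV/JSON input-output and the in-memory dataset container.

Spectra travel as a plain CSV matrix (header = descending wavenumbers, one
row per measurement keyed by measurement id) and metadata as a second CSV;
predictions and evaluation reports are CSV/JSON. Floats are serialized
with 17 significant digits so write -> read is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import WavenumberGrid

__all__ = [
    "SpectraMatrix",
    "Dataset",
    "read_spectra",
    "write_spectra",
    "read_metadata",
    "write_metadata",
    "join_metadata",
    "read_predictions",
    "write_predictions",
    "write_report",
]

METADATA_COLUMNS = ["measurement_id", "sample_id", "role", "shell_fraction",
                    "nutmeg_id", "shell_id", "replicate"]
PREDICTION_COLUMNS = ["sample_id", "repeat", "fold", "predicted_percent"]
ROLES = ("nutmeg", "shell", "mixture")


@dataclass
class SpectraMatrix:
    """Measurement x channel absorbance matrix on a validated grid."""

    grid: WavenumberGrid
    values: np.ndarray
    measurement_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("spectra matrix must be 2-D")
        if self.values.shape[1] != len(self.grid):
            raise ValidationError(
                f"matrix has {self.values.shape[1]} channels, grid has "
                f"{len(self.grid)}")
        if self.values.shape[0] != len(self.measurement_ids):
            raise ValidationError("row count does not match measurement ids")
        if len(set(self.measurement_ids)) != len(self.measurement_ids):
            dupes = pd.Index(self.measurement_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate measurement ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("spectra contain missing/non-finite values")


@dataclass
class Dataset:
    """Spectra joined with per-measurement metadata, row-aligned."""

    grid: WavenumberGrid
    X: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != len(self.meta):
            raise ValidationError("spectra rows and metadata rows differ")
        if self.X.shape[1] != len(self.grid):
            raise ValidationError("channel count does not match grid")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "Dataset":
        """Row subset; mask is boolean or integer positions."""
        mask = np.asarray(mask)
        return Dataset(grid=self.grid, X=self.X[mask],
                       meta=self.meta.iloc[mask].reset_index(drop=True))

    def sample_table(self) -> pd.DataFrame:
        """One row per sample with role, shell fraction and constituents."""
        cols = ["sample_id", "role", "shell_fraction", "nutmeg_id", "shell_id"]
        return (self.meta[cols].drop_duplicates("sample_id")
                .reset_index(drop=True))


def write_spectra(matrix: SpectraMatrix | Dataset, path: str | Path) -> None:
    """Write a spectra CSV: measurement_id column, wavenumber header."""
    if isinstance(matrix, Dataset):
        ids = matrix.meta["measurement_id"].tolist()
        grid, values = matrix.grid, matrix.X
    else:
        ids, grid, values = matrix.measurement_ids, matrix.grid, matrix.values
    header = ["measurement_id"] + [f"{w:.17g}" for w in grid.values]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for mid, row in zip(ids, values):
            fh.write(mid + "," + ",".join(f"{v:.17g}" for v in row) + "\n")


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Read a spectra CSV, validating the grid and ids.

    Raises ValidationError / GridError for ragged rows, a non-monotone or
    gapped wavenumber header, or duplicated measurement ids.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    try:
        wavenumbers = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavenumber header: {exc}") from exc
    grid = WavenumberGrid.from_values(wavenumbers)
    if df.isna().any().any():
        raise ValidationError("spectra CSV has missing values (ragged rows?)")
    return SpectraMatrix(grid=grid, values=df.to_numpy(dtype=float),
                         measurement_ids=[str(i) for i in df.index])


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False, columns=METADATA_COLUMNS)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"measurement_id": str, "sample_id": str},
                       keep_default_na=False)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    return meta


def _validate_record(row: pd.Series) -> None:
    f = row["shell_fraction"]
    role = row["role"]
    if role not in ROLES:
        raise ValidationError(
            f"measurement {row['measurement_id']}: unknown role {role!r}")
    if role == "nutmeg" and f != 0.0:
        raise ValidationError(
            f"measurement {row['measurement_id']}: nutmeg must have "
            f"shell_fraction 0, got {f}")
    if role == "shell" and f != 1.0:
        raise ValidationError(
            f"measurement {row['measurement_id']}: shell must have "
            f"shell_fraction 1, got {f}")
    if role == "mixture":
        if not 0.0 < f < 1.0:
            raise ValidationError(
                f"measurement {row['measurement_id']}: mixture shell_fraction "
                f"must be in (0, 1), got {f}")
        if not row["nutmeg_id"] or not row["shell_id"]:
            raise ValidationError(
                f"measurement {row['measurement_id']}: mixture lacks a "
                f"constituent id")


def join_metadata(matrix: SpectraMatrix, meta: pd.DataFrame) -> Dataset:
    """Join spectra with metadata into a row-aligned Dataset.

    Every measurement must map to exactly one metadata record; orphans and
    duplicate joins are rejected with the offending ids listed.
    """
    if len(meta) == 0:
        raise ValidationError("metadata table is empty")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    counts = meta["measurement_id"].value_counts()
    dupes = sorted(counts[counts > 1].index)
    if dupes:
        raise ValidationError(f"duplicate metadata for measurements: {dupes}")
    lookup = meta.set_index("measurement_id")
    orphans = [m for m in matrix.measurement_ids if m not in lookup.index]
    if orphans:
        raise ValidationError(f"measurements without metadata: {orphans}")
    aligned = lookup.loc[matrix.measurement_ids].reset_index()
    for _, row in aligned.iterrows():
        _validate_record(row)
    return Dataset(grid=matrix.grid, X=matrix.values, meta=aligned)


def write_predictions(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=PREDICTION_COLUMNS)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"predictions missing columns: {sorted(missing)}")
    return df


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an evaluation report as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
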