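"""File dialects: ASCII matrix exports, delimited spectra tables, manifests.

The image dialect is the plain whitespace-delimited ASCII matrix that SPM
software exports (optionally with ``#``-prefixed header lines); spectra travel
as a delimited table with an explicit wavenumber column and a class-label row;
the manifest is a six-column CSV tying image files to cells, classes,
biomarkers, wavelengths and replicates.  Readers are total on the writers'
output, and delimiters for the tabular formats are auto-detected among comma,
tab and whitespace.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import SpectralDataset
from .snom_signal import BIOMARKERS

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixFormatError",
    "DatasetManifest",
    "read_matrix_text",
    "write_matrix_text",
    "read_spectra_table",
    "write_spectra_table",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = (
    "file_path", "cell_id", "class_label", "biomarker", "wavelength_um", "replicate_id"
)


class MatrixFormatError(ValueError):
    """Malformed ASCII matrix or spectra file."""


@dataclass
class DatasetManifest:
    """Validated table tying each image file to its cell/class/biomarker."""

    table: pd.DataFrame
    base_dir: Path

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        bad = set(self.table["biomarker"]) - set(BIOMARKERS)
        if bad:
            raise ValueError(
                f"unknown biomarker names {sorted(bad)}; allowed: {set(BIOMARKERS)}"
            )
        key = self.table[["cell_id", "biomarker", "replicate_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (cell_id, biomarker, replicate_id): {dup}")
        for p in self.table["file_path"]:
            if not self.resolve(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")

    def resolve(self, file_path: str) -> Path:
        p = Path(file_path)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def classes(self) -> list[str]:
        return list(dict.fromkeys(self.table["class_label"]))


def read_matrix_text(path: str | os.PathLike) -> np.ndarray:
    """Parse a whitespace-delimited ASCII matrix; ``#`` lines are comments."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: non-numeric field on line {lineno}"
                ) from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise MatrixFormatError(
                    f"{path}: line {lineno} has {len(values)} fields, expected {width}"
                )
            rows.append(values)
    if not rows:
        raise MatrixFormatError(f"{path}: no data rows")
    matrix = np.asarray(rows, dtype=float)
    if not np.isfinite(matrix).all():
        raise MatrixFormatError(f"{path}: non-finite values in matrix")
    return matrix


def write_matrix_text(matrix: np.ndarray, path: str | os.PathLike) -> None:
    """Write a matrix as whitespace-delimited rows at full double precision."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.size == 0:
        raise ValueError("cannot write an empty matrix")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite values")
    np.savetxt(path, matrix, fmt="%.17g", delimiter=" ")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t ").delimiter
    except csv.Error:
        return ","


def read_spectra_table(path: str | os.PathLike) -> SpectralDataset:
    """Read a delimited spectra table into a SpectralDataset.

    Layout: header row ``wavenumber, <sample ids...>``, then a label row
    ``class, <class labels...>``, then one row per wavenumber with the axis
    value first.  A descending axis is sorted ascending (logged), carrying the
    intensity rows along.
    """
    with open(path) as fh:
        head = fh.read(4096)
    delim = _sniff_delimiter(head)
    df = pd.read_csv(path, sep=delim if delim != " " else r"\s+", header=0,
                     engine="python")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise MatrixFormatError(f"{path}: spectra table too small")
    first_col = df.columns[0]
    if str(df.iloc[0, 0]).strip().lower() != "class":
        raise MatrixFormatError(f"{path}: class-label row missing (second line)")
    labels = [str(v) for v in df.iloc[0, 1:]]
    body = df.iloc[1:].astype(float)
    axis = body[first_col].to_numpy()
    if pd.Series(axis).duplicated().any():
        raise MatrixFormatError(f"{path}: duplicate wavenumber values")
    intensities = body.drop(columns=first_col).to_numpy().T  # samples × variables
    if not np.isfinite(intensities).all():
        raise MatrixFormatError(f"{path}: non-finite intensities")
    if not (np.diff(axis) > 0).all():
        logger.info("%s: wavenumber axis not ascending; sorting", path)
        order = np.argsort(axis)
        axis = axis[order]
        intensities = intensities[:, order]
    return SpectralDataset(
        variables_axis=axis,
        intensities=intensities,
        class_labels=labels,
        sample_ids=[str(c) for c in df.columns[1:]],
    )


def write_spectra_table(
    dataset: SpectralDataset, path: str | os.PathLike, *, delimiter: str = ","
) -> None:
    """Inverse of :func:`read_spectra_table` (values at full precision)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["wavenumber", *dataset.sample_ids])
        writer.writerow(["class", *dataset.class_labels])
        for j, wn in enumerate(dataset.variables_axis):
            writer.writerow(
                [f"{wn:.17g}", *(f"{v:.17g}" for v in dataset.intensities[:, j])]
            )


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Read and validate the dataset manifest CSV."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    delim = _sniff_delimiter(head)
    table = pd.read_csv(path, sep=delim if delim != " " else r"\s+", engine="python")
    return DatasetManifest(table=table, base_dir=path.parent)


def write_manifest(table: pd.DataFrame, path: str | os.PathLike) -> None:
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"manifest table is missing columns: {sorted(missing)}")
    table.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
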