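"""Reading and writing plate data in plain CSV formats.

Two layouts are supported:

``long_csv``
    One file, one row per well, header
    ``assay,plate,row,col,value,is_control`` (comma-separated, UTF-8,
    '.' decimal, 1-based ``row``/``col``).  ``is_control`` marks wells to
    mask out; missing wells simply have no row.

``matrix_dir``
    One CSV matrix per plate in a directory, filenames
    ``plate_0001.csv`` etc.; ``NA`` (empty cell) marks a masked well.
    The matrix layout cannot distinguish controls from missing wells —
    both come back masked.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import Assay, PlateGrid
from .errors import FormatError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["assay", "plate", "row", "col", "value", "is_control"]
_PLATE_FILE_RE = re.compile(r"plate_(\d+)\.csv$")


@dataclass
class ControlSpec:
    """Which wells hold controls, by 1-based position.

    Any well in a listed column or row, or listed explicitly, is masked
    out of all statistics on load.  Mirrors the common bench layout where
    whole edge columns are reserved for positive/negative controls.
    """

    cols: tuple[int, ...] = ()
    rows: tuple[int, ...] = ()
    wells: tuple[tuple[int, int], ...] = ()

    def mask_for(self, n_rows: int, n_cols: int) -> np.ndarray:
        """Boolean matrix, True where a well is a control."""
        ctrl = np.zeros((n_rows, n_cols), dtype=bool)
        for c in self.cols:
            ctrl[:, c - 1] = True
        for r in self.rows:
            ctrl[r - 1, :] = True
        for r, c in self.wells:
            ctrl[r - 1, c - 1] = True
        return ctrl


def read_assay(
    path: str | Path,
    layout: str = "long_csv",
    control_spec: ControlSpec | None = None,
) -> Assay:
    """Load an assay from disk.

    Parameters
    ----------
    path : path
        CSV file (``long_csv``) or directory of per-plate matrices
        (``matrix_dir``).
    layout : {'long_csv', 'matrix_dir'}
    control_spec : ControlSpec, optional
        Additional wells to mask as controls (applied to every plate, on
        top of any ``is_control`` flags in the file).

    Raises
    ------
    FormatError
        Missing/duplicate wells, dimension mismatches, non-numeric values,
        or a path that does not match the layout.
    """
    path = Path(path)
    if layout == "long_csv":
        assay = _read_long(path, control_spec)
    elif layout == "matrix_dir":
        assay = _read_matrix_dir(path, control_spec)
    else:
        raise FormatError(f"unknown layout {layout!r}")
    masked = sum(p.mask.size - p.n_valid for p in assay)
    logger.info(
        "loaded %d plates of %dx%d from %s (%d masked wells)",
        assay.n_plates, assay.n_rows, assay.n_cols, path, masked,
    )
    return assay


def _read_long(path: Path, control_spec: ControlSpec | None) -> Assay:
    if not path.is_file():
        raise FormatError(f"{path}: not a file (long_csv layout expects one CSV)")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    missing_cols = [c for c in ("plate", "row", "col", "value") if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    if "is_control" not in df.columns:
        df["is_control"] = 0
    for col in ("plate", "row", "col"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} must be integer")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        loc = df.loc[bad.idxmax()]
        raise FormatError(
            f"{path}: non-numeric value {loc['value']!r} at plate "
            f"{loc['plate']} row {loc['row']} col {loc['col']}"
        )
    dup = df.duplicated(subset=["plate", "row", "col"])
    if dup.any():
        loc = df.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate well plate {loc['plate']} row {loc['row']} "
            f"col {loc['col']}"
        )
    if df.empty:
        raise FormatError(f"{path}: no wells")

    n_rows, n_cols = int(df["row"].max()), int(df["col"].max())
    if df["row"].min() < 1 or df["col"].min() < 1 or df["plate"].min() < 1:
        raise FormatError(f"{path}: plate/row/col indices are 1-based")
    n_plates = int(df["plate"].max())
    present = np.zeros((n_plates, n_rows, n_cols), dtype=bool)
    vals = np.full((n_plates, n_rows, n_cols), np.nan)
    ctrl = np.zeros((n_plates, n_rows, n_cols), dtype=bool)
    p = df["plate"].to_numpy() - 1
    r = df["row"].to_numpy() - 1
    c = df["col"].to_numpy() - 1
    present[p, r, c] = True
    vals[p, r, c] = values.to_numpy()
    ctrl[p, r, c] = df["is_control"].to_numpy().astype(bool)
    if control_spec is not None:
        ctrl |= control_spec.mask_for(n_rows, n_cols)[None, :, :]
    mask = present & ~ctrl & ~np.isnan(vals)
    vals = np.nan_to_num(vals)
    plates = [
        PlateGrid(vals[i], mask[i], plate_index=i + 1) for i in range(n_plates)
    ]
    return Assay(plates)


def _read_matrix_dir(path: Path, control_spec: ControlSpec | None) -> Assay:
    if not path.is_dir():
        raise FormatError(f"{path}: not a directory (matrix_dir layout)")
    files: dict[int, Path] = {}
    for f in path.iterdir():
        m = _PLATE_FILE_RE.search(f.name)
        if m:
            files[int(m.group(1))] = f
    if not files:
        raise FormatError(f"{path}: no plate_NNNN.csv files found")
    if sorted(files) != list(range(1, len(files) + 1)):
        raise FormatError(f"{path}: plate indices {sorted(files)} are not 1..P")
    plates = []
    shape = None
    for idx in sorted(files):
        try:
            df = pd.read_csv(files[idx], header=None,
                             float_precision="round_trip")
        except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
            raise FormatError(f"{files[idx]}: {exc}") from None
        arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        nonnum = df.notna().to_numpy() & np.isnan(arr)
        if nonnum.any():
            i, j = np.argwhere(nonnum)[0]
            raise FormatError(
                f"{files[idx]}: non-numeric value {df.iat[i, j]!r} at "
                f"row {i + 1} col {j + 1}"
            )
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"{files[idx]}: shape {arr.shape} != {shape} of plate 1"
            )
        mask = ~np.isnan(arr)
        if control_spec is not None:
            mask &= ~control_spec.mask_for(*arr.shape)
        plates.append(PlateGrid(np.nan_to_num(arr), mask, plate_index=idx))
    return Assay(plates)


def write_assay(assay: Assay, path: str | Path, layout: str = "long_csv") -> None:
    """Write an assay to disk; inverse of :func:`read_assay`.

    Round trip (write then read with the same layout) reproduces values on
    the valid mask bit-for-bit and preserves the mask.  In ``long_csv``,
    masked wells are written with ``is_control=1``; in ``matrix_dir`` they
    are written as empty cells.
    """
    path = Path(path)
    if layout == "long_csv":
        rows = []
        for plate in assay:
            for i in range(plate.n_rows):
                for j in range(plate.n_cols):
                    rows.append(
                        (
                            "assay",
                            plate.plate_index,
                            i + 1,
                            j + 1,
                            repr(float(plate.values[i, j])),
                            0 if plate.mask[i, j] else 1,
                        )
                    )
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        df.to_csv(path, index=False)
    elif layout == "matrix_dir":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(assay.n_plates)))
        for plate in assay:
            out = np.where(plate.mask, plate.values, np.nan)
            df = pd.DataFrame(out)
            df = df.map(lambda v: "" if np.isnan(v) else repr(float(v)))
            df.to_csv(
                path / f"plate_{plate.plate_index:0{width}d}.csv",
                index=False, header=False,
            )
    else:
        raise FormatError(f"unknown layout {layout!r}")
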