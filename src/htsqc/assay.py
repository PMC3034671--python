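"""Core containers for plate-format screening data.

A high-throughput screen is modelled as an ordered sequence of rectangular
*plates*.  Each plate is an ``N_R x N_C`` matrix of activity measurements
``x[i, j]`` together with a boolean validity mask: wells holding controls or
missing measurements are masked out and excluded from every statistic
computed anywhere in the package.  Masking (rather than deleting) control
wells preserves the plate geometry, which the row/column scans and the
spectral unrolling depend on.

Coordinates are 1-based throughout the public API (row ``i = 1..N_R``,
column ``j = 1..N_C``, plate ``p = 1..P``), matching the convention used in
screening laboratories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .errors import FormatError, PairingError, UndefinedStatisticError

#: Standard microtiter formats: well count -> (rows, columns).
PLATE_FORMATS: dict[int, tuple[int, int]] = {
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}


def resolve_format(plate_format: int | tuple[int, int]) -> tuple[int, int]:
    """Map a well count (96/384/1536) or an explicit ``(rows, cols)`` pair
    to plate dimensions."""
    if isinstance(plate_format, (tuple, list)):
        n_rows, n_cols = int(plate_format[0]), int(plate_format[1])
    else:
        try:
            n_rows, n_cols = PLATE_FORMATS[int(plate_format)]
        except KeyError:
            raise FormatError(
                f"unknown plate format {plate_format!r}; use 96, 384, 1536 "
                "or an explicit (rows, cols) tuple"
            ) from None
    if n_rows < 2 or n_cols < 2:
        raise FormatError("plates need at least 2 rows and 2 columns")
    return n_rows, n_cols


class WellCoordinate(NamedTuple):
    """1-based (row, column) position of a well on its plate."""

    row: int
    col: int


@dataclass
class ControlStats:
    """Summary of control wells used by control-based normalizations.

    Attributes
    ----------
    mu_pos : float or None
        Mean of positive-control wells.
    mu_neg : float or None
        Mean of negative-control wells.
    """

    mu_pos: float | None = None
    mu_neg: float | None = None


@dataclass
class PlateGrid:
    """One plate's measurement matrix plus validity mask.

    Parameters
    ----------
    values : ndarray of shape (N_R, N_C)
        Activity measurements.  Entries at masked-out wells are carried
        along but never enter any statistic.
    mask : ndarray of bool, same shape, optional
        True where the well participates in statistics (a compound well
        with a measurement).  Defaults to all-valid.
    plate_index : int
        1-based position of the plate within its assay.
    """

    values: np.ndarray
    mask: np.ndarray | None = None
    plate_index: int = 1

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("plate values must be a 2-D matrix")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise FormatError("plates need at least 2 rows and 2 columns")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.array(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise FormatError("mask shape does not match values shape")
        self.plate_index = int(self.plate_index)
        if self.plate_index < 1:
            raise FormatError("plate_index is 1-based and must be >= 1")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        """Measurements of valid wells, as a flat array (row-major)."""
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "PlateGrid":
        """New plate with the same mask/index and replaced values."""
        return PlateGrid(values, self.mask.copy(), self.plate_index)

    def copy(self) -> "PlateGrid":
        return PlateGrid(self.values.copy(), self.mask.copy(), self.plate_index)


def plate_stats(plate: PlateGrid) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) over the valid
    wells of a plate.

    Raises
    ------
    UndefinedStatisticError
        If fewer than two wells are valid.
    """
    vv = plate.valid_values
    if vv.size < 2:
        raise UndefinedStatisticError(
            f"plate {plate.plate_index}: need >= 2 valid wells for mean/SD, "
            f"have {vv.size}"
        )
    return float(vv.mean()), float(vv.std(ddof=1))


@dataclass
class Assay:
    """Ordered sequence of same-format plates, optionally replicate-paired.

    Parameters
    ----------
    plates : list of PlateGrid
        Plates in screening order; ``plates[p-1].plate_index == p``.
    replicate_of : dict, optional
        Symmetric perfect matching between plate indices that screened the
        same compounds, e.g. ``{1: 2, 2: 1}``.
    """

    plates: list[PlateGrid]
    replicate_of: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.plates:
            raise FormatError("an assay needs at least one plate")
        shape = self.plates[0].shape
        for k, plate in enumerate(self.plates, start=1):
            if plate.shape != shape:
                raise FormatError(
                    f"plate {plate.plate_index} has shape {plate.shape}, "
                    f"expected {shape}"
                )
            if plate.plate_index != k:
                raise FormatError(
                    "plate indices must run 1..P without gaps "
                    f"(position {k} holds plate_index {plate.plate_index})"
                )
        if self.replicate_of is not None:
            self._check_matching()

    def _check_matching(self) -> None:
        pairing = self.replicate_of
        indices = set(range(1, len(self.plates) + 1))
        for a, b in pairing.items():
            if a not in indices or b not in indices:
                raise PairingError(f"replicate pair ({a}, {b}) out of range")
            if a == b:
                raise PairingError(f"plate {a} paired with itself")
            if pairing.get(b) != a:
                raise PairingError(f"pairing not symmetric at plate {a}")

    # -- geometry ----------------------------------------------------------
    @property
    def n_plates(self) -> int:
        return len(self.plates)

    @property
    def shape(self) -> tuple[int, int]:
        return self.plates[0].shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    def __iter__(self) -> Iterator[PlateGrid]:
        return iter(self.plates)

    def __len__(self) -> int:
        return len(self.plates)

    # -- bulk views --------------------------------------------------------
    def values3d(self) -> np.ndarray:
        """All plate values stacked to shape (P, N_R, N_C)."""
        return np.stack([p.values for p in self.plates])

    def mask3d(self) -> np.ndarray:
        return np.stack([p.mask for p in self.plates])

    @property
    def valid_values(self) -> np.ndarray:
        """All valid measurements across all plates, flat."""
        v, m = self.values3d(), self.mask3d()
        return v[m]

    def pairs(self) -> list[tuple[int, int]]:
        """Replicate pairs as sorted (low, high) plate-index tuples."""
        if self.replicate_of is None:
            raise PairingError("assay has no replicate pairing")
        return sorted({tuple(sorted((a, b))) for a, b in self.replicate_of.items()})

    def copy(self) -> "Assay":
        rep = dict(self.replicate_of) if self.replicate_of is not None else None
        return Assay([p.copy() for p in self.plates], rep)


def assay_from_array(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    replicate_of: dict[int, int] | None = None,
) -> Assay:
    """Build an Assay from a (P, N_R, N_C) array (and optional mask)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise FormatError("expected a (P, N_R, N_C) array")
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    plates = [
        PlateGrid(values[p], mask[p], plate_index=p + 1)
        for p in range(values.shape[0])
    ]
    return Assay(plates, replicate_of)
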