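"""Plate normalization and systematic-error correction methods.

Five procedures commonly used to make screening plates comparable and to
remove positional bias:

- percent of control:              x / mu_pos
- normalized percent inhibition:   (x - mu_neg) / (mu_pos - mu_neg)
- Z-score:                         (x - mu) / sigma, per plate
- B-score:                         median-polish residuals / plate MAD
- well correction:                 per-well-location detrend + Z-score
                                   across the plate series

All statistics are computed over valid (unmasked) wells only.  The
B-score here is the per-plate variant without the optional cross-plate
smoothing step; the MAD carries no 1.4826 consistency constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import Assay, ControlStats, PlateGrid, plate_stats
from .errors import DegenerateDataError, HtsqcError, UndefinedStatisticError


def percent_of_control(plate: PlateGrid, controls: ControlStats) -> PlateGrid:
    """Divide each valid well by the positive-control mean."""
    if controls.mu_pos is None or controls.mu_pos == 0:
        raise DegenerateDataError("percent-of-control needs a nonzero mu_pos")
    out = plate.copy()
    out.values[out.mask] = out.values[out.mask] / controls.mu_pos
    return out


def normalized_percent_inhibition(
    plate: PlateGrid, controls: ControlStats
) -> PlateGrid:
    """Affine rescale anchoring mu_neg -> 0 and mu_pos -> 1."""
    if controls.mu_pos is None or controls.mu_neg is None:
        raise DegenerateDataError("normalized percent inhibition needs both controls")
    span = controls.mu_pos - controls.mu_neg
    if span == 0:
        raise DegenerateDataError("mu_pos == mu_neg: inhibition scale undefined")
    out = plate.copy()
    out.values[out.mask] = (out.values[out.mask] - controls.mu_neg) / span
    return out


def zscore_plate(plate: PlateGrid) -> PlateGrid:
    """Center and scale a plate to mean 0, sample SD 1 over valid wells."""
    mu, sd = plate_stats(plate)
    if sd == 0:
        raise DegenerateDataError(
            f"plate {plate.plate_index} is constant: Z-score undefined"
        )
    out = plate.copy()
    out.values[out.mask] = (out.values[out.mask] - mu) / sd
    return out


@dataclass
class MedianPolishResult:
    """Additive decomposition value = grand + row + col + residual.

    ``row_effects``/``col_effects`` have length N_R/N_C; ``residuals`` is
    the full matrix (entries at masked wells are meaningless).  After
    convergence the median of residuals along every row and every column
    (valid wells only) is ~0.
    """

    grand: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.grand
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


def median_polish(
    plate: PlateGrid, max_iter: int = 100, tol: float = 1e-6
) -> MedianPolishResult:
    """Tukey two-way median polish of one plate.

    Alternately sweeps row medians then column medians out of the
    residuals (masked wells excluded from every median), accumulating
    them into row/column effects, until the largest absolute adjustment
    in one full sweep is <= ``tol`` or ``max_iter`` is reached.  The
    reconstruction identity ``value = grand + row + col + residual``
    holds on valid wells regardless of convergence.
    """
    work = np.where(plate.mask, plate.values, np.nan)
    n_rows, n_cols = plate.shape
    if plate.n_valid < 4:
        raise UndefinedStatisticError("median polish needs >= 4 valid wells")
    grand = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    converged = False
    iterations = 0
    empty_row = ~plate.mask.any(axis=1)
    empty_col = ~plate.mask.any(axis=0)
    for iterations in range(1, max_iter + 1):
        delta_max = 0.0
        # rows first, per Tukey; fully masked lines carry no information
        # and keep a zero effect
        rmed = np.zeros(n_rows)
        rmed[~empty_row] = np.nanmedian(work[~empty_row], axis=1)
        work -= rmed[:, None]
        row_eff += rmed
        shift = np.median(row_eff)
        row_eff -= shift
        grand += shift
        delta_max = max(delta_max, np.abs(rmed).max(), abs(shift))
        cmed = np.zeros(n_cols)
        cmed[~empty_col] = np.nanmedian(work[:, ~empty_col], axis=0)
        work -= cmed[None, :]
        col_eff += cmed
        shift = np.median(col_eff)
        col_eff -= shift
        grand += shift
        delta_max = max(delta_max, np.abs(cmed).max(), abs(shift))
        if delta_max <= tol:
            converged = True
            break
    # recompute residuals exactly so the identity holds to machine precision
    residuals = plate.values - (grand + row_eff[:, None] + col_eff[None, :])
    residuals[~plate.mask] = 0.0
    return MedianPolishResult(
        grand=float(grand),
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=residuals,
        iterations=iterations,
        converged=converged,
    )


def bscore_plate(
    plate: PlateGrid, max_iter: int = 100, tol: float = 1e-6
) -> PlateGrid:
    """B-score: median-polish residuals divided by their plate MAD.

    ``MAD = median(|r - median(r)|)`` over valid wells, unscaled.  A zero
    MAD (e.g. an exactly additive plate) is degenerate.
    """
    polish = median_polish(plate, max_iter=max_iter, tol=tol)
    resid = polish.residuals[plate.mask]
    mad = float(np.median(np.abs(resid - np.median(resid))))
    if mad == 0:
        raise DegenerateDataError(
            f"plate {plate.plate_index}: residual MAD is 0, B-score undefined"
        )
    out = plate.copy()
    out.values = polish.residuals / mad
    out.values[~plate.mask] = plate.values[~plate.mask]
    return out


def well_correction(assay: Assay, degree: int = 1) -> Assay:
    """Detrend and standardize each well location across the plate series.

    For every well location (i, j): fit a least-squares polynomial of
    ``value`` against plate index over the plates where the well is valid
    (default degree 1), subtract the fit, then Z-score the detrended
    series.  Removes well-location biases that persist across an assay.

    Raises
    ------
    HtsqcError
        Fewer than 3 plates, or a location valid in fewer than 3 plates.
    DegenerateDataError
        A location whose series is constant after detrending (perfectly
        fit by the trend), named in the message.
    """
    if not 0 <= degree <= 2:
        raise HtsqcError("well-correction trend degree must be 0, 1 or 2")
    if assay.n_plates < 3:
        raise HtsqcError("well correction needs >= 3 plates")
    values = assay.values3d()
    mask = assay.mask3d()
    out = values.copy()
    plate_idx = np.arange(1, assay.n_plates + 1, dtype=float)
    n_rows, n_cols = assay.shape
    for i in range(n_rows):
        for j in range(n_cols):
            valid = mask[:, i, j]
            n = int(valid.sum())
            if n < 3:
                raise HtsqcError(
                    f"well ({i + 1}, {j + 1}) valid in only {n} plates; "
                    "well correction needs >= 3"
                )
            x = plate_idx[valid]
            y = values[valid, i, j]
            coeffs = np.polyfit(x, y, deg=degree)
            resid = y - np.polyval(coeffs, x)
            sd = float(resid.std(ddof=1))
            # a perfectly fit trend leaves only rounding noise behind
            if sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
                raise DegenerateDataError(
                    f"well ({i + 1}, {j + 1}): series constant after "
                    "detrending, Z-score undefined"
                )
            out[valid, i, j] = (resid - resid.mean()) / sd
    corrected = assay.copy()
    for p, plate in enumerate(corrected):
        plate.values[plate.mask] = out[p][plate.mask]
    return corrected
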