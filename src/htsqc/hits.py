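"""Hit selection, hit-distribution surfaces, and replicated-assay hits.

Hits follow the inhibition convention: a compound is a hit when its
measurement is *at or below* ``mu - c*sigma``, with ``mu``/``sigma``
taken over the plate (``plate_wise``) or the whole assay
(``assay_wise``).  A *hit-distribution surface* counts, for each well
location, in how many plates that location produced a hit; under no
positional bias the counts are uniform, so row/column structure in the
surface is evidence of systematic error.

For replicated assays the module implements the screening-lab pipeline:
scan each plate for line bias with the t-test, B-score the plates where
bias was detected, Z-score both members of a pair when only one was
corrected (so residual scores and raw values become comparable), average
the replicates, and finally derive *consensus* hits (hit in both
replicates) and *average* hits (pair mean passes the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import Assay, PlateGrid, assay_from_array, plate_stats
from .errors import HtsqcError, PairingError, UndefinedStatisticError
from .detect import scan_plate_ttest
from .normalize import bscore_plate, zscore_plate

HitKey = tuple[int, int, int]  # (pair id = lower plate index, row, col)


def _threshold(values: np.ndarray, c: float) -> float:
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise UndefinedStatisticError("zero spread: hit threshold undefined")
    return mu - c * sd


def select_hits(
    assay: Assay, c: float = 3.0, scope: str = "plate_wise"
) -> np.ndarray:
    """Boolean hit mask of shape (P, N_R, N_C).

    A valid well is a hit iff ``value <= mu - c*sigma`` with the mean and
    sample SD computed at the requested scope over valid wells only.
    """
    if scope not in ("plate_wise", "assay_wise"):
        raise HtsqcError(f"scope must be 'plate_wise' or 'assay_wise', got {scope!r}")
    values, mask = assay.values3d(), assay.mask3d()
    hit = np.zeros(values.shape, dtype=bool)
    if scope == "assay_wise":
        cut = _threshold(assay.valid_values, c)
        hit = mask & (values <= cut)
    else:
        for p, plate in enumerate(assay):
            cut = _threshold(plate.valid_values, c)
            hit[p] = plate.mask & (plate.values <= cut)
    return hit


@dataclass
class HitSurface:
    """Per-well-location hit counts aggregated across plates."""

    counts: np.ndarray
    mask: np.ndarray
    threshold_c: float
    scope: str

    @property
    def total(self) -> int:
        return int(self.counts[self.mask].sum())

    @property
    def expected(self) -> float:
        """Hits per well location under the uniform null (E)."""
        return self.total / int(self.mask.sum())

    def as_plate(self) -> PlateGrid:
        """The surface as a grid, so line tests apply to it directly."""
        return PlateGrid(self.counts.astype(float), self.mask.copy(), plate_index=1)


def hit_distribution_surface(
    assay: Assay, c: float = 3.0, scope: str = "plate_wise"
) -> HitSurface:
    """Count hits per well location across all plates of an assay.

    A location is part of the surface if it is valid (non-control) in at
    least one plate; control locations are excluded.
    """
    hit = select_hits(assay, c, scope)
    mask_any = assay.mask3d().any(axis=0)
    counts = hit.sum(axis=0)
    counts[~mask_any] = 0
    return HitSurface(
        counts=counts.astype(int), mask=mask_any, threshold_c=c, scope=scope
    )


# ---------------------------------------------------------------------------
# replicated assays


def combine_replicates(
    assay: Assay,
    alpha: float = 0.01,
    corrector: str = "bscore_if_flagged",
) -> Assay:
    """Average replicate pairs into one plate per pair.

    corrector:

    ``'bscore_if_flagged'`` (the screening-lab preset)
        t-test scan each plate at ``alpha``; B-score every plate with at
        least one flagged line.  When exactly one plate of a pair was
        B-scored, Z-score both plates first so that polish residuals and
        raw values live on a comparable scale.
    ``'zscore'``
        Z-score every plate, then average.
    ``'none'``
        Average raw values.

    The averaged assay has one plate per pair (ordered by the lower
    original index); a well is valid where both replicates are valid.
    """
    if corrector not in ("bscore_if_flagged", "zscore", "none"):
        raise HtsqcError(f"unknown corrector {corrector!r}")
    pairs = assay.pairs()
    if 2 * len(pairs) != assay.n_plates:
        raise PairingError(
            f"{assay.n_plates} plates but {len(pairs)} pairs: every plate "
            "must belong to exactly one replicate pair"
        )
    averaged = []
    for new_idx, (a, b) in enumerate(pairs, start=1):
        p1, p2 = assay.plates[a - 1], assay.plates[b - 1]
        if corrector == "zscore":
            p1, p2 = zscore_plate(p1), zscore_plate(p2)
        elif corrector == "bscore_if_flagged":
            f1 = any(r.flagged for r in scan_plate_ttest(p1, alpha))
            f2 = any(r.flagged for r in scan_plate_ttest(p2, alpha))
            if f1:
                p1 = bscore_plate(p1)
            if f2:
                p2 = bscore_plate(p2)
            if f1 != f2:
                p1, p2 = zscore_plate(p1), zscore_plate(p2)
        mask = p1.mask & p2.mask
        values = np.where(mask, (p1.values + p2.values) / 2.0, 0.0)
        averaged.append(PlateGrid(values, mask, plate_index=new_idx))
    return Assay(averaged)


def consensus_and_average_hits(
    assay: Assay, c: float = 3.0, scope: str = "assay_wise"
) -> tuple[set[HitKey], set[HitKey]]:
    """Consensus and average hit lists of a replicated assay.

    One fixed cutoff ``mu - c*sigma`` is computed at the requested scope
    (``assay_wise``: over all valid wells of the replicated assay;
    ``pair_wise``: over the pooled valid wells of each pair) and applied
    both to the individual replicate values and to their mean.  A
    compound is a *consensus* hit when both replicate measurements pass
    the cutoff, and an *average* hit when the replicate mean passes it;
    with a shared cutoff every consensus hit is necessarily an average
    hit.

    Returns two sets of ``(pair id, row, col)`` keys, where the pair id
    is the lower plate index of the pair.
    """
    if scope not in ("assay_wise", "pair_wise"):
        raise HtsqcError(f"scope must be 'assay_wise' or 'pair_wise', got {scope!r}")
    pairs = assay.pairs()
    if scope == "assay_wise":
        global_cut = _threshold(assay.valid_values, c)
    consensus: set[HitKey] = set()
    average: set[HitKey] = set()
    for a, b in pairs:
        p1, p2 = assay.plates[a - 1], assay.plates[b - 1]
        both = p1.mask & p2.mask
        if scope == "pair_wise":
            pooled = np.concatenate([p1.valid_values, p2.valid_values])
            cut = _threshold(pooled, c)
        else:
            cut = global_cut
        for i, j in np.argwhere(both):
            v1, v2 = p1.values[i, j], p2.values[i, j]
            key = (a, int(i) + 1, int(j) + 1)
            if v1 <= cut and v2 <= cut:
                consensus.add(key)
            if (v1 + v2) / 2.0 <= cut:
                average.add(key)
    return consensus, average
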