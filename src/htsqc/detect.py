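"""Statistical tests for positional (row/column/well) systematic error.

Three detectors are provided:

**Pooled-variance t-test** — for each row (column) of a plate, compare the
line's wells against all remaining wells of the same plate with a
two-sample Student's t-test assuming equal variances:

    s_p^2 = ((N1-1) s1^2 + (N2-1) s2^2) / (N1 + N2 - 2)
    t     = (m1 - m2) / (s_p * sqrt(1/N1 + 1/N2)),   df = N1 + N2 - 2

two-sided p-value, no multiple-testing adjustment (each line is judged at
the raw per-test alpha; a Bonferroni option is available in the scans).
The same test applies unchanged to a hit-distribution surface treated as
a single grid of counts.

**Chi-square goodness of fit** — for hit-distribution surfaces: under the
no-bias null, hits spread evenly over well locations with expectation
``E = total hits / number of wells``; each line (or the whole surface) is
scored by ``sum((obs - E)^2 / E)`` with df = (cells tested) - 1.

**DFT + Kolmogorov-Smirnov** — the plate is unrolled to a 1-D sequence
(row-major to expose column-periodic structure, column-major for rows),
its power density spectrum is computed by discrete Fourier transform
(DC term excluded), and a K-S-type statistic compares the running rank
distribution of the spectrum against uniformity:

    D = max_k max( F(y_k) - (k-1)/N,  k/N - F(y_k) ),  k = 1..N

where ``F(y)`` is the fraction of spectrum values strictly below ``y``
and ``k`` indexes the spectrum in frequency order.  Periodic line effects
concentrate power at low-order harmonics, pushing top ranks to early
frequencies and inflating D.  The p-value uses the asymptotic Kolmogorov
distribution of ``sqrt(N) * D``.  Note that the spectrum of a real
signal is mirror-symmetric, so even null plates violate the uniform-rank
assumption and the test rejects more often than its nominal level — a
known defect of the spectral approach that the evaluation harness
measures explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import special, stats

from .assay import Assay, PlateGrid
from .errors import HtsqcError, UndefinedStatisticError

if TYPE_CHECKING:  # pragma: no cover
    from .hits import HitSurface


@dataclass
class DetectionResult:
    """Outcome of one test on one target (a line or a whole surface).

    ``kind`` is ``'row'``, ``'col'`` or ``'surface'``; ``index`` the
    1-based line index (0 for a surface); ``plate`` the 1-based plate
    index, or None for assay-level targets.  ``flagged`` is
    ``p_value < alpha``; an undefined test yields NaN statistic/p and
    ``flagged=False``.
    """

    kind: str
    index: int
    plate: int | None
    statistic: float
    p_value: float
    alpha: float
    flagged: bool
    test: str = ""

    @property
    def ok(self) -> bool:
        return not np.isnan(self.p_value)


@dataclass
class Spectrum:
    """Power density spectrum of an unrolled plate (DC term excluded)."""

    powers: np.ndarray
    order: str  # 'row_major' or 'column_major'

    def __len__(self) -> int:
        return len(self.powers)


@dataclass
class TwoSampleSummary:
    """Sufficient statistics of a line-vs-remainder split."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float

    @property
    def pooled_var(self) -> float:
        return ((self.n1 - 1) * self.var1 + (self.n2 - 1) * self.var2) / (
            self.n1 + self.n2 - 2
        )

    @property
    def t(self) -> float:
        sp = np.sqrt(self.pooled_var * (1 / self.n1 + 1 / self.n2))
        return (self.mean1 - self.mean2) / sp

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


# ---------------------------------------------------------------------------
# t-test


def _line_split(
    values: np.ndarray, mask: np.ndarray, kind: str, index: int
) -> TwoSampleSummary:
    if kind == "row":
        line_sel = np.zeros(values.shape, dtype=bool)
        line_sel[index - 1, :] = True
    elif kind == "col":
        line_sel = np.zeros(values.shape, dtype=bool)
        line_sel[:, index - 1] = True
    else:
        raise HtsqcError(f"line kind must be 'row' or 'col', got {kind!r}")
    s1 = values[line_sel & mask]
    s2 = values[~line_sel & mask]
    if s1.size < 2 or s2.size < 2:
        raise UndefinedStatisticError(
            f"{kind} {index}: need >= 2 valid wells in line and remainder "
            f"(have {s1.size} and {s2.size})"
        )
    return TwoSampleSummary(
        n1=s1.size,
        n2=s2.size,
        mean1=float(s1.mean()),
        mean2=float(s2.mean()),
        var1=float(s1.var(ddof=1)),
        var2=float(s2.var(ddof=1)),
    )


def t_test_line(
    plate: PlateGrid, kind: str, index: int, alpha: float = 0.01
) -> DetectionResult:
    """Pooled-variance two-sample t-test of one line vs the plate remainder."""
    summ = _line_split(plate.values, plate.mask, kind, index)
    t = summ.t
    p = 2.0 * float(stats.t.sf(abs(t), summ.df))
    return DetectionResult(
        kind=kind,
        index=index,
        plate=plate.plate_index,
        statistic=float(t),
        p_value=p,
        alpha=alpha,
        flagged=p < alpha,
        test="t",
    )


def _plate_line_t(
    values: np.ndarray, mask: np.ndarray, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized t and df for every line along ``axis`` (0: rows)."""
    other = 1 - axis
    v = np.where(mask, values, 0.0)
    n1 = mask.sum(axis=other).astype(float)
    s1 = v.sum(axis=other)
    q1 = (v * v).sum(axis=other)
    n_tot, s_tot, q_tot = mask.sum(), v.sum(), (v * v).sum()
    n2 = n_tot - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = s1 / n1
        m2 = (s_tot - s1) / n2
        var1 = (q1 - n1 * m1**2) / (n1 - 1)
        var2 = (q_tot - q1 - n2 * m2**2) / (n2 - 1)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    bad = (n1 < 2) | (n2 < 2)
    t[bad] = np.nan
    return t, df


def scan_plate_ttest(plate: PlateGrid, alpha: float = 0.01) -> list[DetectionResult]:
    """t-test every row and every column of one plate."""
    results: list[DetectionResult] = []
    for kind, axis, n_lines in (("row", 0, plate.n_rows), ("col", 1, plate.n_cols)):
        t, df = _plate_line_t(plate.values, plate.mask, axis)
        with np.errstate(invalid="ignore"):
            p = 2.0 * stats.t.sf(np.abs(t), df)
        for idx in range(n_lines):
            pv = float(p[idx])
            results.append(
                DetectionResult(
                    kind=kind,
                    index=idx + 1,
                    plate=plate.plate_index,
                    statistic=float(t[idx]),
                    p_value=pv,
                    alpha=alpha,
                    flagged=bool(pv < alpha),
                    test="t",
                )
            )
    return results


def scan_assay_ttest(
    assay: Assay, alpha: float = 0.01, bonferroni: bool = False
) -> list[DetectionResult]:
    """t-test every row and column of every plate.

    Returns P x (N_R + N_C) results.  No multiple-testing adjustment by
    default (each line judged at the raw per-test alpha); with
    ``bonferroni=True`` alpha is divided by the number of tests.
    """
    n_tests = assay.n_plates * (assay.n_rows + assay.n_cols)
    eff_alpha = alpha / n_tests if bonferroni else alpha
    results: list[DetectionResult] = []
    for plate in assay:
        results.extend(scan_plate_ttest(plate, eff_alpha))
    return results


# ---------------------------------------------------------------------------
# chi-square on hit-distribution surfaces


def chi2_line(
    surface: "HitSurface", kind: str, index: int, alpha: float = 0.01
) -> DetectionResult:
    """Chi-square uniformity test of one line of a hit-distribution surface."""
    E = surface.expected
    if E <= 0:
        raise UndefinedStatisticError("surface has no hits: chi-square undefined")
    if kind == "row":
        cells = surface.counts[index - 1, :][surface.mask[index - 1, :]]
    elif kind == "col":
        cells = surface.counts[:, index - 1][surface.mask[:, index - 1]]
    else:
        raise HtsqcError(f"line kind must be 'row' or 'col', got {kind!r}")
    if cells.size < 2:
        raise UndefinedStatisticError(f"{kind} {index}: fewer than 2 surface cells")
    stat = float(((cells - E) ** 2 / E).sum())
    df = cells.size - 1
    p = float(stats.chi2.sf(stat, df))
    return DetectionResult(
        kind=kind,
        index=index,
        plate=None,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        flagged=p < alpha,
        test="chi2",
    )


def chi2_surface(surface: "HitSurface", alpha: float = 0.01) -> DetectionResult:
    """Chi-square uniformity test over all cells of a surface."""
    E = surface.expected
    if E <= 0:
        raise UndefinedStatisticError("surface has no hits: chi-square undefined")
    cells = surface.counts[surface.mask]
    stat = float(((cells - E) ** 2 / E).sum())
    df = cells.size - 1
    p = float(stats.chi2.sf(stat, df))
    return DetectionResult(
        kind="surface",
        index=0,
        plate=None,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        flagged=p < alpha,
        test="chi2",
    )


def scan_surface_chi2(
    surface: "HitSurface", alpha: float = 0.01
) -> list[DetectionResult]:
    """Chi-square test on every row and column of a surface."""
    results = []
    for kind, n_lines in (("row", surface.counts.shape[0]),
                          ("col", surface.counts.shape[1])):
        for idx in range(1, n_lines + 1):
            results.append(chi2_line(surface, kind, idx, alpha))
    return results


# ---------------------------------------------------------------------------
# DFT + K-S


def dft_power_spectrum(plate: PlateGrid, order: str = "row_major") -> Spectrum:
    """Power density spectrum of the unrolled plate.

    Valid wells are concatenated row by row (``row_major``) or column by
    column (``column_major``); masked wells are skipped, shortening the
    sequence.  Powers are squared moduli of the DFT coefficients with the
    DC (k=0) term excluded.
    """
    if order == "row_major":
        flat_mask = plate.mask.ravel(order="C")
        seq = plate.values.ravel(order="C")[flat_mask]
    elif order == "column_major":
        flat_mask = plate.mask.ravel(order="F")
        seq = plate.values.ravel(order="F")[flat_mask]
    else:
        raise HtsqcError(f"order must be 'row_major' or 'column_major', got {order!r}")
    if seq.size < 4:
        raise UndefinedStatisticError(
            f"plate {plate.plate_index}: need >= 4 valid wells for a spectrum"
        )
    coeffs = np.fft.fft(seq)
    powers = np.abs(coeffs[1:]) ** 2
    return Spectrum(powers=powers, order=order)


def ks_statistic(spectrum: Spectrum | np.ndarray) -> float:
    """K-S-type discrepancy between spectrum ranks and frequency order.

    With ``F(y)`` the fraction of spectrum values strictly below ``y``
    and ``k`` the 1-based position in the sequence as given,

        D = max_k max( F(y_k) - (k-1)/N,  k/N - F(y_k) ).

    D always lies in ``[1/N, 1]``; a sequence already in ascending order
    with distinct values attains the 1/N lower bound (rank identity),
    while power concentrated at early frequencies drives D toward 1.
    """
    powers = spectrum.powers if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
    n = powers.size
    if n == 0:
        raise UndefinedStatisticError("empty spectrum")
    f = np.searchsorted(np.sort(powers), powers, side="left") / n
    k = np.arange(1, n + 1)
    return float(np.maximum(f - (k - 1) / n, k / n - f).max())


def ks_test_plate(
    plate: PlateGrid,
    alpha: float = 0.01,
    orders: Sequence[str] = ("row_major", "column_major"),
) -> list[DetectionResult]:
    """DFT + K-S test of a plate, one result per unrolling order.

    Row-major unrolling turns a column effect into a periodic signal and
    therefore screens for *column* bias; column-major screens for rows.
    p-value from the asymptotic Kolmogorov distribution of sqrt(N)*D.
    """
    results = []
    for order in orders:
        spec = dft_power_spectrum(plate, order)
        d = ks_statistic(spec)
        n = len(spec)
        p = float(special.kolmogorov(np.sqrt(n) * d))
        results.append(
            DetectionResult(
                kind="col" if order == "row_major" else "row",
                index=0,
                plate=plate.plate_index,
                statistic=d,
                p_value=p,
                alpha=alpha,
                flagged=p < alpha,
                test="ks",
            )
        )
    return results


def scan_assay_ks(assay: Assay, alpha: float = 0.01) -> list[DetectionResult]:
    """Per-line K-S decisions for a whole assay.

    The spectral test is plate-scoped and does not localize which line is
    biased, so the plate-level decision of each unrolling order is
    attributed to *every* line of the corresponding kind: if the
    row-major spectrum rejects, all columns of that plate are flagged,
    and symmetrically for rows.  Returns P x (N_R + N_C) results.
    """
    results: list[DetectionResult] = []
    for plate in assay:
        for res in ks_test_plate(plate, alpha):
            n_lines = assay.n_cols if res.kind == "col" else assay.n_rows
            for idx in range(1, n_lines + 1):
                results.append(
                    DetectionResult(
                        kind=res.kind,
                        index=idx,
                        plate=plate.plate_index,
                        statistic=res.statistic,
                        p_value=res.p_value,
                        alpha=alpha,
                        flagged=res.flagged,
                        test="ks",
                    )
                )
    return results


def detections_to_frame(results: Iterable[DetectionResult]):
    """Detection results as a pandas DataFrame (one row per target)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "test": r.test,
            "plate": r.plate,
            "kind": r.kind,
            "index": r.index,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "alpha": r.alpha,
            "flagged": r.flagged,
        }
        for r in results
    )
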