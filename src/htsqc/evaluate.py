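"""Scoring detectors against ground truth, and the simulation campaigns.

Each scanned line (a row or column of a plate, or of a hit-distribution
surface) is one binary decision; comparing decisions with the generation
ground truth yields TP/FP/TN/FN tallies, from which Cohen's kappa

    kappa = (Pr(a) - Pr(e)) / (1 - Pr(e))
    Pr(a) = (TP + TN) / n
    Pr(e) = ((TP+FN)(TP+FP) + (TN+FN)(TN+FP)) / n^2

sensitivity TP/(TP+FN), specificity TN/(TN+FP) and the success rate
(TP+TN)/n are derived.  Undefined metrics (no positives in truth, or
Pr(e) = 1) are reported as NaN, never as 0, so campaign averages skip
them.

Two campaign drivers reproduce the benchmark protocols:

- :func:`run_simulation1` — plate-by-plate scans of raw measurements
  (t-test and DFT+K-S) across error types and error sizes;
- :func:`run_simulation2` — tests applied to the mu-3*sigma
  hit-distribution surface (t, chi-square, DFT+K-S) across hit
  percentages at a fixed error size.

Both are deterministic given their seed: per-dataset seeds derive from
the campaign seed through one master generator, so any dataset can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import (
    DetectionResult,
    chi2_surface,
    ks_test_plate,
    scan_assay_ks,
    scan_assay_ttest,
    scan_plate_ttest,
    scan_surface_chi2,
)
from .errors import EvaluationError, HtsqcError
from .hits import hit_distribution_surface
from .simulate import (
    DEFAULT_NOISE_SD,
    GroundTruth,
    apply_error,
    generate_base_assay,
    inject_hits,
    make_error_spec,
)


@dataclass
class ConfusionCounts:
    """Line-level confusion tallies against ground truth."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalMetrics:
    """Agreement metrics; NaN marks an undefined value."""

    kappa: float
    sensitivity: float
    specificity: float
    success_rate: float


def confusion_counts(
    detections: Iterable[DetectionResult], truth: GroundTruth
) -> ConfusionCounts:
    """Tally detector decisions against ground-truth line labels.

    The detections must cover exactly the rows and columns labelled in
    ``truth`` (each line once); a coverage mismatch raises
    :class:`EvaluationError`.
    """
    P = truth.n_plates
    n_rows = truth.row_flags.shape[1]
    n_cols = truth.col_flags.shape[1]
    seen: set[tuple[int, str, int]] = set()
    counts = ConfusionCounts()
    for det in detections:
        if det.kind not in ("row", "col"):
            continue
        plate = det.plate if det.plate is not None else 1
        key = (plate, det.kind, det.index)
        if key in seen:
            raise EvaluationError(f"duplicate detection for {key}")
        seen.add(key)
        if det.kind == "row":
            true_pos = bool(truth.row_flags[plate - 1, det.index - 1])
        else:
            true_pos = bool(truth.col_flags[plate - 1, det.index - 1])
        if det.flagged and true_pos:
            counts.tp += 1
        elif det.flagged and not true_pos:
            counts.fp += 1
        elif not det.flagged and true_pos:
            counts.fn += 1
        else:
            counts.tn += 1
    expected = P * (n_rows + n_cols)
    if len(seen) != expected:
        raise EvaluationError(
            f"detections cover {len(seen)} lines, truth has {expected}"
        )
    return counts


def cohens_kappa(counts: ConfusionCounts) -> float:
    """Chance-corrected agreement between detector and ground truth.

    NaN when there are no true positives *and* no false negatives (no
    positive class in the truth, agreement by chance undefined in the
    benchmark sense) or when Pr(e) = 1.
    """
    n = counts.total
    if n == 0:
        raise HtsqcError("empty confusion table")
    if counts.tp + counts.fn == 0:
        return float("nan")
    pr_a = (counts.tp + counts.tn) / n
    pr_e = (
        (counts.tp + counts.fn) * (counts.tp + counts.fp)
        + (counts.tn + counts.fn) * (counts.tn + counts.fp)
    ) / n**2
    if pr_e == 1:
        return float("nan")
    return (pr_a - pr_e) / (1 - pr_e)


def rates(counts: ConfusionCounts) -> EvalMetrics:
    """Kappa, sensitivity, specificity and success rate from one table."""
    n = counts.total
    if n == 0:
        raise HtsqcError("empty confusion table")
    sens = (
        counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else float("nan")
    )
    spec = (
        counts.tn / (counts.tn + counts.fp)
        if counts.tn + counts.fp > 0
        else float("nan")
    )
    return EvalMetrics(
        kappa=cohens_kappa(counts),
        sensitivity=sens,
        specificity=spec,
        success_rate=(counts.tp + counts.tn) / n,
    )


def evaluate_detections(
    detections: Iterable[DetectionResult], truth: GroundTruth
) -> EvalMetrics:
    return rates(confusion_counts(detections, truth))


# ---------------------------------------------------------------------------
# campaign drivers


def _surface_truth(truth: GroundTruth) -> GroundTruth:
    """Ground truth for the aggregated surface of an assay.

    Only error patterns that repeat identically across all plates leave a
    recoverable trace in the surface; per-plate or per-well patterns map
    to an all-negative truth (their line metrics come out undefined).
    """
    n_rows = truth.row_flags.shape[1]
    n_cols = truth.col_flags.shape[1]
    if truth.constant_across_plates():
        row = truth.row_flags[:1].copy()
        col = truth.col_flags[:1].copy()
    else:
        row = np.zeros((1, n_rows), dtype=bool)
        col = np.zeros((1, n_cols), dtype=bool)
    return GroundTruth(row, col, np.zeros((1, n_rows, n_cols), dtype=bool))


def _dataset_seeds(rng: np.random.Generator, n: int) -> list[int]:
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _simulate_dataset(
    error_type: str,
    plate_format,
    n_plates: int,
    h: float,
    err_sd_mult: float,
    noise_sd_mult: float,
    seed: int,
):
    rng = np.random.default_rng(seed)
    s_base, s_hits, s_err = _dataset_seeds(rng, 3)
    base = generate_base_assay(n_plates, plate_format, seed=s_base)
    sd_base = float(base.valid_values.std(ddof=1))
    assay, hits = inject_hits(base, h, seed=s_hits)
    spec = make_error_spec(
        error_type,
        plate_format,
        err_sd_mult * sd_base,
        noise_sd_mult * sd_base,
        seed=s_err,
        n_plates=n_plates,
    )
    assay, truth = apply_error(assay, spec)
    truth.hit_locations = hits
    return assay, truth


def _mean_or_nan(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    ok = ~np.isnan(arr)
    return float(arr[ok].mean()) if ok.any() else float("nan")


def run_simulation1(
    plate_format: int | tuple[int, int] = 96,
    n_plates: int = 50,
    h: float = 1.0,
    err_sds: Sequence[float] = (0.0, 0.6, 1.2, 1.8, 2.4, 3.0),
    error_types: Sequence[str] = ("A", "B", "C", "D", "E"),
    tests: Sequence[str] = ("t", "ks"),
    alpha: float = 0.01,
    n_datasets: int = 20,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed=None,
) -> pd.DataFrame:
    """Plate-by-plate detection benchmark over raw measurements.

    For every (error type, error size, test): generate ``n_datasets``
    assays (standard-normal background, ``h``% hits, the given error
    model with offsets of SD ``err_sd`` x base SD), scan every row and
    column of every plate, score against ground truth, and average the
    metrics over datasets (NaN-skipping).  ``err_sd`` and ``noise_sd``
    are multiples of the base-assay SD.

    The defaults are a desk-scale profile (50 plates, 20 datasets); pass
    ``n_plates=1250, n_datasets=500`` for the full campaign.
    """
    unknown = set(tests) - {"t", "ks"}
    if unknown:
        raise HtsqcError(f"unknown tests {sorted(unknown)}; simulation 1 uses t/ks")
    master = np.random.default_rng(seed)
    rows = []
    for etype in error_types:
        for err_sd in err_sds:
            per_test: dict[str, dict[str, list[float]]] = {
                t: {"kappa": [], "sensitivity": [], "specificity": [],
                    "success_rate": []}
                for t in tests
            }
            for ds_seed in _dataset_seeds(master, n_datasets):
                assay, truth = _simulate_dataset(
                    etype, plate_format, n_plates, h, err_sd, noise_sd, ds_seed
                )
                for test in tests:
                    if test == "t":
                        det = scan_assay_ttest(assay, alpha)
                    else:
                        det = scan_assay_ks(assay, alpha)
                    m = evaluate_detections(det, truth)
                    for name in per_test[test]:
                        per_test[test][name].append(getattr(m, name))
            for test in tests:
                agg = per_test[test]
                rows.append(
                    {
                        "error_type": etype,
                        "err_sd": err_sd,
                        "test": test,
                        "alpha": alpha,
                        "kappa": _mean_or_nan(agg["kappa"]),
                        "sensitivity": _mean_or_nan(agg["sensitivity"]),
                        "specificity": _mean_or_nan(agg["specificity"]),
                        "success_rate": _mean_or_nan(agg["success_rate"]),
                        "n_datasets": n_datasets,
                        "n_kappa_defined": int(
                            np.sum(~np.isnan(agg["kappa"]))
                        ),
                    }
                )
    return pd.DataFrame(rows)


def run_simulation2(
    plate_format: int | tuple[int, int] = 96,
    n_plates: int = 50,
    hit_pcts: Sequence[float] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
    err_sd: float = 1.2,
    error_types: Sequence[str] = ("A", "B", "C", "D", "E"),
    tests: Sequence[str] = ("t", "chi2", "ks"),
    alpha: float = 0.01,
    threshold_c: float = 3.0,
    n_datasets: int = 20,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed=None,
) -> pd.DataFrame:
    """Detection benchmark over hit-distribution surfaces.

    For each (error type, hit percentage, test): generate datasets as in
    simulation 1 but with the error size fixed at ``err_sd`` x base SD,
    build the plate-wise ``mu - c*sigma`` hit-distribution surface, run
    the row/column tests on the surface, and score against the surface
    ground truth (recoverable only for error patterns constant across
    plates; otherwise kappa/sensitivity are NaN).  The chi-square rows
    also report how often the whole-surface chi-square flagged.
    """
    unknown = set(tests) - {"t", "chi2", "ks"}
    if unknown:
        raise HtsqcError(f"unknown tests {sorted(unknown)}")
    master = np.random.default_rng(seed)
    rows = []
    for etype in error_types:
        for h in hit_pcts:
            per_test = {
                t: {"kappa": [], "sensitivity": [], "specificity": [],
                    "success_rate": []}
                for t in tests
            }
            surf_flags: list[bool] = []
            for ds_seed in _dataset_seeds(master, n_datasets):
                assay, truth = _simulate_dataset(
                    etype, plate_format, n_plates, h, err_sd, noise_sd, ds_seed
                )
                surface = hit_distribution_surface(
                    assay, threshold_c, "plate_wise"
                )
                s_truth = _surface_truth(truth)
                grid = surface.as_plate()
                for test in tests:
                    if test == "t":
                        det = scan_plate_ttest(grid, alpha)
                    elif test == "chi2":
                        det = scan_surface_chi2(surface, alpha)
                        surf_flags.append(chi2_surface(surface, alpha).flagged)
                    else:
                        det = ks_test_plate(grid, alpha)
                        det = _expand_ks(det, *grid.shape)
                    m = evaluate_detections(det, s_truth)
                    for name in per_test[test]:
                        per_test[test][name].append(getattr(m, name))
            for test in tests:
                agg = per_test[test]
                row = {
                    "error_type": etype,
                    "hit_pct": h,
                    "err_sd": err_sd,
                    "test": test,
                    "alpha": alpha,
                    "kappa": _mean_or_nan(agg["kappa"]),
                    "sensitivity": _mean_or_nan(agg["sensitivity"]),
                    "specificity": _mean_or_nan(agg["specificity"]),
                    "success_rate": _mean_or_nan(agg["success_rate"]),
                    "n_datasets": n_datasets,
                    "n_kappa_defined": int(np.sum(~np.isnan(agg["kappa"]))),
                }
                if test == "chi2":
                    row["surface_chi2_flag_rate"] = float(np.mean(surf_flags))
                rows.append(row)
    return pd.DataFrame(rows)


def _expand_ks(
    plate_results: list[DetectionResult], n_rows: int, n_cols: int
) -> list[DetectionResult]:
    """Attribute each plate-level K-S decision to every line of its kind."""
    out = []
    for res in plate_results:
        n_lines = n_cols if res.kind == "col" else n_rows
        for idx in range(1, n_lines + 1):
            out.append(
                DetectionResult(
                    kind=res.kind,
                    index=idx,
                    plate=res.plate,
                    statistic=res.statistic,
                    p_value=res.p_value,
                    alpha=res.alpha,
                    flagged=res.flagged,
                    test=res.test,
                )
            )
    return out
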