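"""Synthetic screening assays with controlled systematic error.

The generator reproduces the simulation conditions used to benchmark
positional-error detection tests: an error-free assay of i.i.d. standard
normal measurements, an inhibition-style hit population at ``N(mu - 5*SD,
SD)``, and five perturbation models:

====  ==========================================================
A     row *and* column offsets, constant across all plates
B     column offsets only, constant across all plates
C     per-well offsets, constant across all plates
D     row and column offsets redrawn independently for each plate
E     random noise only (no systematic component)
====  ==========================================================

Every model also adds i.i.d. random noise ``Rand ~ N(0, noise_sd^2)`` to
every valid well.  Systematic offsets are drawn from ``N(0, err_sd^2)``;
the number of affected lines is capped to mimic realistic assays (at most
2 rows and 2 columns on a 96-well plate, 4/4 on 384, 8/8 on 1536, and at
most 10% of wells for the per-well model).

Ground truth — which rows/columns/wells actually carry systematic error
— is returned alongside every perturbed assay so detector output can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .assay import Assay, assay_from_array, resolve_format
from .errors import FormatError, HtsqcError

ERROR_TYPES = ("A", "B", "C", "D", "E")

#: Default random-noise SD as a multiple of the base-assay SD.
DEFAULT_NOISE_SD = 0.2


def line_caps(shape: tuple[int, int]) -> tuple[int, int]:
    """Maximum numbers of rows and columns that may carry systematic error.

    Reproduces the standard-format caps (96: 2/2, 384: 4/4, 1536: 8/8) and
    scales proportionally for custom geometries.
    """
    n_rows, n_cols = shape
    return max(1, n_rows // 4), max(1, n_cols // 6)


def well_cap(shape: tuple[int, int]) -> int:
    """Maximum number of wells affected by the per-well model (10%)."""
    return max(1, int(0.10 * shape[0] * shape[1]))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# error recipe


@dataclass
class ErrorSpec:
    """A fully drawn perturbation recipe.

    ``err_sd``/``noise_sd`` are in measurement units (for the standard-
    normal base assay this equals multiples of the base SD).  For types
    A/B/C the affected sets and offsets are assay-wide; for type D they
    are per-plate lists; type E has no systematic component.
    """

    error_type: str
    n_rows: int
    n_cols: int
    err_sd: float
    noise_sd: float
    seed: int | None = None
    # assay-wide draws (types A, B, C); 1-based indices
    affected_rows: list[int] = field(default_factory=list)
    row_offsets: list[float] = field(default_factory=list)
    affected_cols: list[int] = field(default_factory=list)
    col_offsets: list[float] = field(default_factory=list)
    affected_wells: list[tuple[int, int]] = field(default_factory=list)
    well_offsets: list[float] = field(default_factory=list)
    # per-plate draws (type D): one entry per plate
    plate_rows: list[list[int]] = field(default_factory=list)
    plate_row_offsets: list[list[float]] = field(default_factory=list)
    plate_cols: list[list[int]] = field(default_factory=list)
    plate_col_offsets: list[list[float]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["affected_wells"] = [list(w) for w in self.affected_wells]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorSpec":
        d = dict(d)
        d["affected_wells"] = [tuple(w) for w in d.get("affected_wells", [])]
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the recipe as a YAML (or .json) sidecar."""
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ErrorSpec":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class GroundTruth:
    """Per-plate boolean labels of where systematic error was added.

    ``row_flags[p-1, i-1]`` is True when row ``i`` of plate ``p`` carries a
    systematic offset; likewise ``col_flags`` and (for the per-well model)
    ``well_flags``.  ``hit_locations`` holds 1-based ``(plate, row, col)``
    triples of injected hits when hits were simulated.
    """

    row_flags: np.ndarray
    col_flags: np.ndarray
    well_flags: np.ndarray
    hit_locations: set[tuple[int, int, int]] = field(default_factory=set)

    @property
    def n_plates(self) -> int:
        return self.row_flags.shape[0]

    def constant_across_plates(self) -> bool:
        """True when every plate has identical row/column labels (so the
        error pattern would survive aggregation across plates)."""
        return bool(
            np.all(self.row_flags == self.row_flags[:1])
            and np.all(self.col_flags == self.col_flags[:1])
        )

    def save(self, path: str | Path) -> None:
        d = {
            "row_flags": self.row_flags.astype(int).tolist(),
            "col_flags": self.col_flags.astype(int).tolist(),
            "well_flags": self.well_flags.astype(int).tolist(),
            "hit_locations": sorted(list(t) for t in self.hit_locations),
        }
        path = Path(path)
        text = (
            json.dumps(d)
            if path.suffix == ".json"
            else yaml.safe_dump(d, sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(
            row_flags=np.array(d["row_flags"], dtype=bool),
            col_flags=np.array(d["col_flags"], dtype=bool),
            well_flags=np.array(d["well_flags"], dtype=bool),
            hit_locations={tuple(t) for t in d["hit_locations"]},
        )


# ---------------------------------------------------------------------------
# generation


def generate_base_assay(
    n_plates: int,
    plate_format: int | tuple[int, int] = 96,
    seed=None,
) -> Assay:
    """Error-free assay: every valid well i.i.d. standard normal.

    Deterministic given ``seed``.
    """
    if n_plates < 1:
        raise HtsqcError("n_plates must be >= 1")
    shape = resolve_format(plate_format)
    rng = _rng(seed)
    values = rng.standard_normal((n_plates, *shape))
    return assay_from_array(values)


def inject_hits(
    assay: Assay, h: float, seed=None
) -> tuple[Assay, set[tuple[int, int, int]]]:
    """Replace a random h% of valid wells with hit-like low values.

    Each valid well independently becomes a hit with probability
    ``h/100``; hit values are drawn from ``N(mu - 5*SD, SD)`` where ``mu``
    and ``SD`` are the mean and sample SD of the *whole error-free assay*
    before injection (inhibition convention: hits are low).

    Returns the modified assay and the set of 1-based
    ``(plate, row, col)`` hit locations.
    """
    if not 0 <= h <= 100:
        raise HtsqcError(f"hit percentage h={h} outside [0, 100]")
    rng = _rng(seed)
    out = assay.copy()
    if h == 0:
        return out, set()
    vv = assay.valid_values
    mu, sd = float(vv.mean()), float(vv.std(ddof=1))
    locations: set[tuple[int, int, int]] = set()
    for plate in out:
        is_hit = (rng.random(plate.shape) < h / 100.0) & plate.mask
        n = int(is_hit.sum())
        if n:
            plate.values[is_hit] = rng.normal(mu - 5 * sd, sd, size=n)
            for i, j in np.argwhere(is_hit):
                locations.add((plate.plate_index, int(i) + 1, int(j) + 1))
    return out, locations


def make_error_spec(
    error_type: str,
    plate_format: int | tuple[int, int],
    err_sd: float,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed=None,
    n_plates: int | None = None,
) -> ErrorSpec:
    """Draw a perturbation recipe for one assay.

    Affected counts are uniform on ``1..cap`` (an error-containing recipe
    always contains error); locations are sampled without replacement;
    offsets are ``N(0, err_sd^2)``.  Type D redraws counts, locations and
    offsets independently for every plate and therefore needs
    ``n_plates``.
    """
    error_type = str(error_type).upper()
    if error_type not in ERROR_TYPES:
        raise HtsqcError(f"unknown error type {error_type!r}; use A..E")
    if err_sd < 0 or noise_sd < 0:
        raise HtsqcError("err_sd and noise_sd must be >= 0")
    shape = resolve_format(plate_format)
    n_rows, n_cols = shape
    cap_r, cap_c = line_caps(shape)
    rng = _rng(seed)
    spec = ErrorSpec(
        error_type=error_type,
        n_rows=n_rows,
        n_cols=n_cols,
        err_sd=float(err_sd),
        noise_sd=float(noise_sd),
        seed=seed if (seed is None or isinstance(seed, int)) else None,
    )

    def lines(n_lines: int, cap: int) -> tuple[list[int], list[float]]:
        count = int(rng.integers(1, cap + 1))
        idx = sorted(
            int(i) + 1 for i in rng.choice(n_lines, size=count, replace=False)
        )
        offs = [float(x) for x in rng.normal(0.0, err_sd, size=count)]
        return idx, offs

    if error_type == "A":
        spec.affected_rows, spec.row_offsets = lines(n_rows, cap_r)
        spec.affected_cols, spec.col_offsets = lines(n_cols, cap_c)
    elif error_type == "B":
        spec.affected_cols, spec.col_offsets = lines(n_cols, cap_c)
    elif error_type == "C":
        cap_w = well_cap(shape)
        count = int(rng.integers(1, cap_w + 1))
        flat = rng.choice(n_rows * n_cols, size=count, replace=False)
        wells = sorted((int(f) // n_cols + 1, int(f) % n_cols + 1) for f in flat)
        spec.affected_wells = wells
        spec.well_offsets = [float(x) for x in rng.normal(0.0, err_sd, size=count)]
    elif error_type == "D":
        if n_plates is None or n_plates < 1:
            raise HtsqcError("type D needs n_plates (per-plate redraws)")
        for _ in range(n_plates):
            r_idx, r_off = lines(n_rows, cap_r)
            c_idx, c_off = lines(n_cols, cap_c)
            spec.plate_rows.append(r_idx)
            spec.plate_row_offsets.append(r_off)
            spec.plate_cols.append(c_idx)
            spec.plate_col_offsets.append(c_off)
    # type E: nothing systematic
    return spec


def apply_error(assay: Assay, spec: ErrorSpec) -> tuple[Assay, GroundTruth]:
    """Perturb an assay according to a drawn recipe.

    Adds the systematic offsets of ``spec`` plus i.i.d. random noise
    ``N(0, noise_sd^2)`` to every valid well.  With ``noise_sd = 0``,
    wells outside the affected sets are bit-identical to the input.
    Deterministic given ``(assay, spec)`` — the noise stream derives from
    ``spec.seed``.
    """
    if assay.shape != spec.shape:
        raise HtsqcError(
            f"assay shape {assay.shape} does not match spec shape {spec.shape}"
        )
    if spec.error_type == "D" and len(spec.plate_rows) != assay.n_plates:
        raise HtsqcError(
            f"type-D spec drawn for {len(spec.plate_rows)} plates, assay has "
            f"{assay.n_plates}"
        )
    P, (n_rows, n_cols) = assay.n_plates, assay.shape
    noise_rng = np.random.default_rng(
        None if spec.seed is None else np.random.SeedSequence([int(spec.seed), 1])
    )
    out = assay.copy()
    row_flags = np.zeros((P, n_rows), dtype=bool)
    col_flags = np.zeros((P, n_cols), dtype=bool)
    well_flags = np.zeros((P, n_rows, n_cols), dtype=bool)

    # assay-wide offset matrix for types A/B/C
    base_off = np.zeros((n_rows, n_cols))
    for i, off in zip(spec.affected_rows, spec.row_offsets):
        base_off[i - 1, :] += off
    for j, off in zip(spec.affected_cols, spec.col_offsets):
        base_off[:, j - 1] += off
    for (i, j), off in zip(spec.affected_wells, spec.well_offsets):
        base_off[i - 1, j - 1] += off

    for p, plate in enumerate(out):
        off = base_off.copy()
        if spec.error_type == "D":
            for i, o in zip(spec.plate_rows[p], spec.plate_row_offsets[p]):
                off[i - 1, :] += o
                if o != 0.0:
                    row_flags[p, i - 1] = True
            for j, o in zip(spec.plate_cols[p], spec.plate_col_offsets[p]):
                off[:, j - 1] += o
                if o != 0.0:
                    col_flags[p, j - 1] = True
        else:
            for i, o in zip(spec.affected_rows, spec.row_offsets):
                if o != 0.0:
                    row_flags[p, i - 1] = True
            for j, o in zip(spec.affected_cols, spec.col_offsets):
                if o != 0.0:
                    col_flags[p, j - 1] = True
            for (i, j), o in zip(spec.affected_wells, spec.well_offsets):
                if o != 0.0:
                    well_flags[p, i - 1, j - 1] = True
        if spec.noise_sd > 0:
            noise = np.zeros(plate.shape)
            noise[plate.mask] = noise_rng.normal(
                0.0, spec.noise_sd, size=plate.n_valid
            )
            off = off + noise
        plate.values[plate.mask] += off[plate.mask]
    return out, GroundTruth(row_flags, col_flags, well_flags)


def simulate_assay(
    error_type: str,
    n_plates: int,
    plate_format: int | tuple[int, int] = 96,
    h: float = 1.0,
    err_sd: float = 1.2,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed=None,
) -> tuple[Assay, ErrorSpec, GroundTruth]:
    """One-call pipeline: base assay -> hit injection -> error model.

    ``err_sd`` and ``noise_sd`` are multiples of the base assay's sample
    SD (which is ~1 for the standard-normal background).  Returns the
    perturbed assay, the drawn recipe, and ground truth (including hit
    locations).
    """
    rng = _rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    base = generate_base_assay(n_plates, plate_format, seed=sub[0])
    sd_base = float(base.valid_values.std(ddof=1))
    with_hits, hits = inject_hits(base, h, seed=sub[1])
    spec = make_error_spec(
        error_type,
        plate_format,
        err_sd * sd_base,
        noise_sd * sd_base,
        seed=sub[2],
        n_plates=n_plates,
    )
    perturbed, truth = apply_error(with_hits, spec)
    truth.hit_locations = hits
    return perturbed, spec, truth
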