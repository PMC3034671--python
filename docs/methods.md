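# Methods

## Data model

An assay is an ordered sequence of `P` plates sharing an `N_R × N_C`
geometry; plate `p` holds measurements `x[i, j, p]` with 1-based row,
column and plate indices.  Every plate carries a boolean validity mask:
wells holding controls, or with missing measurements, are masked out and
excluded from *every* statistic in the package — means, SDs, medians,
polish sweeps, spectra and hit counts alike.  Controls are masked rather
than deleted so that plate geometry survives; the row/column scans and
the spectral unrolling need it.  A consequence worth knowing: a line that
is entirely controls (e.g. the classic layout with control columns 1 and
12) yields an *undefined* line test, which scans report as a NaN result
rather than an error.

Whenever a standard deviation appears it is the sample SD (n−1
denominator).  The choice is invisible for the simulated `N(0,1)`
backgrounds at these sample sizes but is applied uniformly so thresholds,
Z-scores and pooled variances agree with each other.

## Synthetic assays

The generator reproduces a benchmark design for positional-error
detection at screening scale:

- **Background**: all valid wells i.i.d. standard normal.  The reference
  campaign geometry is 1250 plates of 96 wells (8×12); 384- and
  1536-well formats are supported, and the desk-scale default used by
  the test suite and the acceptance script is 50 plates.
- **Hits**: each valid well independently becomes a hit with probability
  `h/100`; its value is *replaced* by a draw from `N(μ − 5·SD, SD)`,
  where `μ` and `SD` are computed over the whole error-free assay before
  injection.  Replacement (rather than addition) is what "hit values
  follow `N(μ − 5SD, SD)`" means literally; hits are low because the
  package adopts the inhibition convention throughout.
- **Error models**: five perturbation types, all of which also add
  i.i.d. noise `Rand ~ N(0, noise_sd²)` to every valid well —
  A: row and column offsets constant across plates; B: column offsets
  only; C: per-well offsets constant across plates; D: row/column
  offsets redrawn independently per plate; E: noise only.  Offsets are
  `N(0, err_sd²)`.  Affected-line counts are drawn uniformly from
  `1..cap` — never 0, so an "error-containing" dataset really contains
  error — with caps of 2 rows/2 columns (96-well), 4/4 (384), 8/8 (1536)
  and at most 10% of wells for type C.  For custom geometries the caps
  scale as `rows/4` and `cols/6`, which reproduces the standard-format
  values.
- **Ground truth**: per-plate boolean labels of biased rows, columns and
  wells (flagged only when the drawn offset is nonzero, so `err_sd = 0`
  yields an all-negative truth), plus the injected hit locations.

`noise_sd` defaults to 0.2× the base SD.  The random-noise term is part
of every error model but its variance is a free parameter of the design;
0.2 keeps it clearly subordinate to the systematic offsets under study
(0.6–3.0 SD) while preventing the error-free case from being a
pathological zero-noise fixture.  It is recorded in the `ErrorSpec`
sidecar and configurable everywhere.

What the generator does *not* emulate: temporal drift within an assay,
edge/evaporation gradients, batch effects, heteroscedastic backgrounds,
or correlated noise.  Passing benchmarks here therefore says how the
tests behave under clean additive positional bias on a Gaussian
background — the regime the detection theory addresses — not how they
cope with every artefact of real screens.

## Normalization and correction

- **Percent of control** `x/μ_pos` and **normalized percent inhibition**
  `(x − μ_neg)/(μ_pos − μ_neg)` rescale by control means; both are
  affine, hence rank-preserving per plate.
- **Z-score** centers and scales each plate to mean 0, sample SD 1.
- **B-score** runs Tukey's two-way median polish (rows swept first, then
  columns, the median of the accumulated effects folded into the grand
  term after each sweep; `max_iter = 100`, `tol = 1e-6` on the largest
  per-sweep adjustment; even-count medians use the midpoint) and divides
  the residuals by the plate MAD, `median(|r − median(r)|)`, with **no**
  1.4826 consistency constant and **no** cross-plate smoothing step.
  The reconstruction identity `value = grand + row + col + residual` is
  restored exactly at the end by recomputing residuals from the fitted
  effects.  Degenerate cases (MAD = 0, e.g. an exactly additive plate)
  raise.  Lines that are entirely masked carry a zero effect.

  A caveat inherent to iterated median polish: its fixed point depends
  on sweep order.  A constant added to a whole *row* is absorbed exactly
  in the first sweep; a constant column offset is usually — but not
  always — absorbed into the column effect, because it can move row
  medians and steer the iteration to a different decomposition.  The
  test suite pins the exact row-direction invariance and the
  approximate column absorption separately.
- **Well correction** fits, for each well location, a least-squares
  polynomial of value against plate order (degree 1 by default,
  configurable 0–2: the minimal model for a slow per-location drift),
  subtracts it, and Z-scores the detrended series across plates.  It
  needs at least 3 plates and 3 valid values per location; a series the
  trend fits perfectly (residual SD below 1e-12 of the data scale) is
  reported as degenerate with the offending well named.

## Detection tests

- **t-test**: each row (column) versus all remaining wells of the same
  grid, pooled-variance (homoscedastic) two-sample t with
  `df = N₁+N₂−2`, two-sided p.  Welch's variant is deliberately not
  used.  Scans apply the test to every line of every plate at the raw
  per-test α — no multiple-testing correction, matching how per-line
  detection is evaluated in the benchmark; a Bonferroni option exists
  but is off by default.  The identical machinery runs on
  hit-distribution surfaces (a surface is just a grid of counts).
- **χ² goodness of fit** (surfaces only): expected count
  `E = total/locations`; line statistic `Σ(x − E)²/E` over the cells of
  the line with `df = cells − 1` (so `N_C − 1` for a row and `N_R − 1`
  for a column — df follows the number of cells actually summed), and a
  whole-surface variant with `df = N_R·N_C − 1`.
- **DFT + K-S**: valid wells are unrolled row-major (exposing
  column-periodic structure) or column-major (rows); masked wells are
  skipped, shortening the sequence.  Powers are squared moduli of the
  DFT coefficients, DC term excluded, leaving `N − 1` values for a
  sequence of length `N`.  The statistic is
  `D = max_k max(F(y_k) − (k−1)/N, k/N − F(y_k))` with `F(y)` the
  fraction of spectrum values strictly below `y` and `k` the position in
  *frequency order*; the p-value is the asymptotic Kolmogorov tail of
  `√N·D`.  `D` always lies in `[1/N, 1]`, attaining `1/N` exactly when
  the sequence is already in ascending rank order.

  Two properties of this construction matter for interpretation.
  First, it is a *sortedness* statistic: a strong periodic line effect
  concentrates power at low-order harmonics, placing top-ranked values
  at early positions and driving `D` toward 1 — that is the detection
  mechanism.  Second, it is severely anti-conservative under the null:
  the spectrum of a real signal is mirror-symmetric and its ranks are
  far from sorted, so `D` is large for typical plate sizes and the test
  flags most error-free plates.  The evaluation harness measures this
  directly (its κ is ≈ 0 across conditions).  The test is included
  because it appears in commercial plate-QC software; the package's own
  benchmarks are the argument for preferring the t-test.

  The K-S test is plate-scoped and cannot localize the biased line, so
  in per-line scoring the plate-level decision of each unrolling order
  is attributed to every line of the corresponding kind (row-major →
  all columns, column-major → all rows).

## Hit analysis

Hits are wells with `value ≤ μ − c·σ` (the comparison is `≤`), with
`μ, σ` per plate or per assay; hit-distribution surfaces count, per well
location, the plates on which that location was a hit (control locations
excluded).  Replicate combination implements the screening-lab policy:
scan each plate with the t-test, B-score plates with at least one
flagged line, and — whenever exactly one plate of a pair was corrected —
Z-score both before averaging, since polish residuals and raw values are
not on a common scale.  Consensus hits (hit in both replicates) and
average hits (pair mean passes the cutoff) are computed against a single
shared cutoff per pair or per assay, which makes `consensus ⊆ average` a
structural guarantee, mirroring the fixed control-derived cutoffs used
in real campaigns.

## Evaluation

Each scanned line is one binary decision; confusion counts against
ground truth give `Pr(a) = (TP+TN)/n`,
`Pr(e) = ((TP+FN)(TP+FP) + (TN+FN)(TN+FP))/n²`,
`κ = (Pr(a) − Pr(e))/(1 − Pr(e))`, sensitivity `TP/(TP+FN)`,
specificity `TN/(TN+FP)` and success rate `(TP+TN)/n` (the success rate
is definitionally `Pr(a)`).  When the truth contains no positive line
(error types C and E in plate scans; C, D and E on surfaces, whose
aggregated truth is recoverable only for patterns constant across
plates), κ and sensitivity are reported as NaN — never as 0 — and
campaign averages skip them, with the count of defined values reported
alongside.

Two campaign drivers orchestrate the benchmarks.  Simulation 1 scans raw
plates with the t-test and DFT+K-S across error types and error sizes
(0–3 SD); Simulation 2 builds the plate-wise `μ − 3σ` hit-distribution
surface per dataset and applies the t, χ² and K-S tests to its rows and
columns across hit percentages (0.5–5%) at a fixed 1.2 SD error size.
Both derive per-dataset seeds from the campaign seed through a single
master generator, so every dataset is individually regenerable and all
outputs are bit-reproducible given (configuration, seed).

The package defaults run these campaigns at desk scale — 50 plates per
assay and 20 datasets per condition — which keeps the full suite in
seconds while leaving the reference scale (1250 plates, 500 datasets)
one argument away.  At desk scale the surface campaign's t-test success
rate sits at the low end of its full-scale range: with 50 plates a
surface accumulates only ~0.5 hits per location, so weakly offset lines
are often undetectable and sensitivity is modest, while specificity
stays near `1 − α`; success, dominated by the many unbiased lines,
stays at or above ~90%.

## Known limitations

- The spectral K-S test is implemented as specified by its source
  formula, including its anti-conservativeness; it is not a usable
  detector at plate sizes and is provided for benchmarking.
- Median polish invariance to line offsets is exact only in the
  first-swept (row) direction; see above.
- The matrix-per-plate CSV layout cannot distinguish controls from
  missing wells; both load as masked.
- No modelling of dose–response confirmation, structure-based triage,
  cross-plate B-score smoothing, or trimmed-mean polish variants.
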