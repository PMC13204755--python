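# Methods

## Data model

A movie is one in-memory tensor of shape `(T, H, W)` — frame, row, column.
That axis order is an internal convention fixed at the I/O boundary
(`stack.load_stack` / `save_stack`); TIFF pages map to frames in file
order, and multi-file one-frame-per-TIFF sequences are ingested in sorted
filename order. Camera data is typically unsigned integer ADU; every
arithmetic consumer first promotes to a signed wide type (`as_signed`,
int64/float64) because `|F1 − F2|` on unsigned dtypes wraps silently. The
storage dtype is preserved on save. `validate_stack` separates hard
invariant violations (non-finite or negative intensities, wrong rank) from
advisories (fewer than 3 frames: legal data, but below the detector's
window length).

## Denoising

`median_filter_stack` applies `scipy.ndimage.median_filter` with kernel
`(1, 3, 3)`: the temporal axis is held fixed and each pixel becomes the
median of its 3×3 spatial neighborhood within its own frame, so no
information crosses frames (verified by a per-frame-vs-whole-stack
equality test). The kernel is configurable but must be odd along each
axis; with odd kernels the even-count median case never arises. Default
boundary handling is scipy's `reflect` (edge sample repeated), scipy's
default and therefore the behavior of the reference tooling this filter
standardizes on; `mirror`, `nearest`, `wrap` and `constant` are accepted.
A brute-force oracle (`median_filter_oracle`) pads with the matching
`numpy.pad` mode and sorts every neighborhood explicitly; the fast path
must match it exactly, boundaries included. Median filtering is not
idempotent and is not assumed to be; the guaranteed property is that the
output range is contained in the input range.

Why a median: the detector keys on sharp temporal transients. Linear
smoothing (mean/Gaussian) blurs exactly those transients; the median
suppresses impulsive single-pixel noise while leaving a multi-pixel
emitter footprint intact. This is also the false-positive mechanism of the
pipeline: a one-pixel flash is erased (median of {v, 0×8} = 0) while a
3×3-block flash survives at its center (median of nine equal values).

## Detection

Per pixel, the trace is scanned over windows t = 1 … T−2 (1-based). With
d₁ = |F₁−F₂|, d₂ = |F₂−F₃|, the pixel is detected at the first t where
**both** differences strictly exceed τ, and the scan stops (early
termination). Strictness is deliberate: d = τ does not detect. The
criterion is symmetric in sign, so it fires on rise-then-fall,
fall-then-rise, and monotone two-step ramps alike; no up-then-down
constraint is added. The count N is the number of detected pixels; the
earliest satisfying frame (`first_hit`, 1-based, 0 = never) is kept
because it is free under early termination and useful for temporal
diagnostics. The vectorized implementation (`detect_stack`) is held
equivalent to a literal triple-loop transcription (`detect_oracle`) over
seeded random stacks and thresholds.

Consequences used as test invariants: N(τ) is non-increasing in τ with
nested masks; a constant trace never detects; τ→∞ gives N = 0; spatial
transposition transposes the mask and preserves N; appending constant
frames cannot remove detections and prepending one shifts `first_hit` by
one.

## Threshold screening and selection

`sweep_thresholds` filters each movie once and detects at every τ on the
grid (detection is cheap next to filtering); the sweep table asserts
per-movie monotonicity on construction. The operating threshold must
preserve the assay's concentration response: thresholds too low let
background noise dominate the count, thresholds too high miss true
events. `select_threshold` makes that narrative criterion an explicit
lexicographic score per τ: (a) Spearman rank correlation between
concentration and count (a strictly increasing response scores 1), then
(b) R² of the log-linear calibration fit, then (c) fewest counts on the
lowest-concentration movie. Ties resolve to the smallest τ (first in grid
order), making the selector a pure function of its inputs. If no τ gives
a strictly monotone response the best-ranked τ is still returned, with an
explicit warning flag in the diagnostics — never silently.

## Density and calibration

`grid_density` reproduces the manual-counting convention: tile the field
with non-overlapping squares of nominal area 36 µm² (side =
`round(sqrt(area)/pixel_size)` pixels), origin at the top-left, partial
edge squares discarded; density = square count / nominal area. The mean
can use all squares, an explicit index list, or a seeded random choice of
k squares (the analog of the protocol's three analyst-chosen regions;
seeded random is the default form of choice because the selection should
not be data-dependent). Summed per-grid counts equal the mask total
exactly when the field is a multiple of the square side, otherwise they
are a lower bound.

`fit_log_linear` is ordinary least squares of response on
x = log10(concentration in pg/mL), computed with explicit normal
equations so the degenerate constant-response case (SS_tot = 0) can be
flagged as "R² undefined" rather than silently reported as 0 or 1; tests
cross-check slope/intercept/R² against both the raw Σx/Σy/Σxy/Σx² formulas
and `scipy.stats.linregress` to 1e-10 relative tolerance. The intercept is
the predicted response at 1 pg/mL. `compare_methods` fits a manual-density
series and an automated-count series on the same concentrations and
reports both triples side by side; the two series need not share a scale
(density per µm² vs raw pixel count), so slopes differ by a scale factor
while R² compares linearity.

## Simulator

The generator is the minimal model that produces the temporal signature
the detector exploits:

- **Kinetics**: each emitter's ON/OFF trace is an independent two-state
  Markov chain with per-frame probabilities p_on (OFF→ON) and p_off
  (ON→OFF); the initial state draws from the stationary distribution
  p_on/(p_on+p_off) unless overridden. Richer photophysics (triplet
  shelving, power-law dark times, photobleaching) is out of scope, but the
  state generator is a separable function (`simulate_states`) and can be
  swapped.
- **Optics**: an ON emitter adds a 2-D Gaussian PSF of σ `psf_sigma`
  pixels and peak `amplitude`, sampled at pixel centers (not integrated
  over pixel area — the detector responds to temporal contrast, not
  photometry); σ = 0 deposits the whole amplitude in one pixel. Emitters
  have real-valued subpixel centers with a minimum pairwise separation
  (default 4σ + 2 px) enforced by dart throwing with a bounded retry
  budget (`SeparationError` on failure).
- **Noise**: Poisson shot noise on the noiseless image, then additive
  Gaussian read noise, then clipping at 0; integer casts saturate at the
  dtype maximum and log a warning. One seeded generator drives placement,
  kinetics and noise, so a fixed config reproduces movie and ground truth
  bit-exactly.

Defaults are the package's reference study conditions: T = 60 frames (a
typical acquisition length for these assays) of 256×256 px at 0.1 µm/px,
50 emitters, σ = 1.5 px, amplitude 200 ADU on background 10 ADU, read
noise 2 ADU, p_on = 0.2, p_off = 0.5, uint16 output. The blinking rates
are generic placeholders chosen to produce frequent one-frame transients
(the geometric ON-run length makes an isolated ON frame likely within 60
frames); they are not calibrated to any specific dye.

**Dose–response mapping.** `concentration_for_emitters` assigns a movie's
analyte concentration as c = 10^(n/90) pg/mL for n bound emitters, i.e.
the bound-emitter number grows linearly with log10 concentration (90
emitters per decade by default). This encodes the saturating, wide-dynamic-
range binding behavior under which single-molecule counts calibrate
linearly against log concentration — the regime the counting method is
designed for. Under a strictly proportional mapping (n ∝ c) the count
would be exponential in log10 c and no linear fit could exceed R² ≈ 0.84
on a geometric series; the log-linear mapping is therefore a modeling
choice, stated here once, not a tuning knob.

**Scoring.** `evaluate_detection` matches the rounded emitter center
pixels against the detected-pixel set: recall is the fraction of
*blinking* emitters (at least one ON↔OFF transition in the movie) with a
detected pixel within `match_radius` (Euclidean, default 1 px — the
detector is pixel-level); the false-positive rate is the fraction of all
field pixels detected farther than `match_radius` from every emitter
center. Note the default radius makes PSF shoulder pixels count as false
positives, so the metric is conservative; at the reference conditions
τ ≈ 120–130 still achieves recall ≥ 0.95 with false-positive rate ≤ 10⁻³.

## What the simulation does and does not show

Passing the simulation-based tests demonstrates that the algorithm
recovers isolated blinking point emitters over stationary flat background
with independent telegraph kinetics. Real assay movies add structured and
drifting background, emitter density beyond the separation assumption,
dye-specific brightness and kinetics, photobleaching, and detector
artifacts — none of which the generator emulates. Operating thresholds
found here do not transfer to real data; the screening procedure
(sweep + selection) is the transferable object.

## Numerical and design choices

- All differences computed after signed promotion; masks are boolean
  arrays; N is asserted equal to the mask popcount on result construction.
- 1-based frame indices on every external surface (CLI, JSON, CSV);
  internal arrays are 0-based with conversion at the result boundary.
- Threshold grids accepted as explicit lists or `start:stop:step` ranges
  (inclusive of stop when the step lands on it).
- End-to-end runs stamp outputs with the package version and a SHA-256
  hash of the canonical manifest; no output embeds wall-clock time, so a
  rerun with identical manifest and seed is byte-identical, and the
  structured log orders events by sequence number.
- Problem sizes in tests and the acceptance script (random stacks up to
  32×32×16 for oracle equivalence, 256×256×60 movies, 10–20 seeds for the
  concentration series) were chosen as the smallest sizes at which the
  statistical checks are stable.

## Known limitations

- No clustering of detected pixels into molecules, no subpixel
  localization, no PSF fitting: N is a pixel count and scales with PSF
  area as well as emitter number.
- A single global τ per movie; no adaptive or per-pixel thresholds.
- The whole stack is held in memory; no chunked/streaming processing.
- Grayscale single-channel TIFF only; no proprietary microscope formats.
- `select_threshold` assumes one movie per concentration when ranking;
  replicate handling is limited to distinct labels sharing a
  concentration (ties lower the Spearman score).
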