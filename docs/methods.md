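# Methods

## The model of the data

The package analyses single-channel fluorescence micrographs of single
cells, one cell per image, with a known physical pixel size. All images are
first interpolated (bilinear) to a common pixel size of 112 nm so that
filter radii and annulus geometry have a fixed physical meaning. The image
vertical (row) axis is the strain axis and defines angle 0°; angles
increase counterclockwise and are reported in [0°, 180°), exploiting the
point symmetry of autocorrelograms.

## Segmentation

**Cell mask.** The triangle threshold draws a line in the gray-value
histogram from the absolute maximum (the background mode in fluorescence)
to the highest occupied gray value and thresholds at the level whose
histogram point is farthest from that line. The histogram uses 256 bins
spanning the observed intensity range; pixels strictly above the threshold
level are foreground. Ties in the histogram maximum break to the lowest
gray value. A constant image raises a degenerate-histogram error.

**Fiber mask.** Fibrous structures are thin, so they carry high local
intensity variance in at least one direction. A pixel is foreground iff
`G > m + s/2`, where `m` and `s` are the *weighted* mean and population
standard deviation of gray values in a circular region of radius 7 px
around the pixel. The weight of each pixel in the kernel is the fraction of
its unit area inside the circle (computed by 1-D midpoint quadrature of the
clipped circle height, 257 nodes, then symmetrized); this area weighting
suppresses the orientation-dependent response a binary kernel shows on a
square grid. At image borders the kernel is truncated to in-image pixels
and renormalized by the in-image weight sum. The strict inequality is
evaluated with a relative tolerance of 1e−9 so that constant regions
(where `G = m` and `s = 0` up to round-off) are never foreground.

The radius 7 px default follows the principle that the kernel must be wider
than a fiber but small against the cell; masks for radii 6–8 agree with
Jaccard similarity above 0.6 on synthetic fibers. Note an inherent property
of the criterion: it adapts to the local noise scale, so pure-noise regions
segment into ~30 % speckle at *any* noise amplitude. The cell mask (AND
combination) and the deletion of isolated single pixels (8-connectivity, so
1-px diagonal fibers survive) remove most of it; what remains raises the
correlogram noise floor but carries no orientational structure. A related
artifact is a dark halo flanking fibers and a spurious band along the cell
boundary, both visible in segmented images and reflected as depressions in
the correlogram perpendicular to fibers.

## Correlograms

For an `N × M` binary mask (the bounding box of the cell mask), the
correlogram at signed lag `(i, j)` is the number of coincident set-pixel
pairs divided by the overlap area `(N−|i|)(M−|j|)` of the two shifted
grids. For boolean inputs this is the joint probability that two positions
separated by the lag are both set; the zero-lag value is the area
coverage. Although the printed summation formula covers nonnegative shifts,
signed lags are computed with the `|·|` normalization, consistent with the
centered, point-symmetric correlograms analysed downstream.

Computation is via real FFTs zero-padded to at least `(2N−1) × (2M−1)`
(rounded up to fast transform lengths, which does not change values);
negative round-off values are clamped to zero. A direct-summation
implementation with the identical contract serves as the independent oracle
in tests; the two agree to better than 1e−10 on random masks. The default
maximum lag is 40 px — beyond the 21 px annulus and the background ring —
and larger lags are used where a profile must reach past the fiber length.
Per-correlogram statistical errors are not computed; uncertainty is always
estimated from the variance between cells.

## Orientational order

The radial orientation function averages the origin-normalized
autocorrelation in 1°-wide slices of the annulus 9 ≤ r ≤ 21 px (inclusive;
1.01–2.35 µm at 112 nm/px — the inner radius clears the Niblack kernel).
Each annulus pixel is assigned to the slice containing its angle from the
vertical axis; antipodal slices are pooled (half-circle averaging). At
this annulus size a few of the 180 slices contain no pixel center; they
are filled by circular linear interpolation between the nearest occupied
slices and the event is logged. The alternative — subpixel supersampling
of the annulus — was rejected to keep the slice statistic a plain mean of
measured correlogram values.

The **preferred direction** is the angle (slice index, so 1° resolution) of
the ROF's absolute maximum; ties break to the smallest angle and a flat ROF
(range < 1e−6) returns 0° with a logged warning. Offset subtraction (the
0° slice value) is applied to averaged ROFs for reporting only, after
population averaging — the order of mean and subtraction is immaterial for
the mean, and SEM is reported unsubtracted — and never before extracting
the preferred direction.

## Translational order and fiber length

Line profiles sample the correlogram at unit-lag steps along a given
direction (bilinear interpolation). For straight fibers of length L the
along-fiber autocorrelation decays linearly and meets the background at
lag L. The length estimator fits

    v(u) = A · (1 − u/L)₊ + (b₀ + b₁u + b₂u²),   u ≥ 15 px,

grid-searching the kink L at 1 px resolution with the other coefficients
solved by least squares, and requires the triangle term to explain at least
1 % of the residual variance beyond the background alone. The quadratic
background absorbs the slowly varying contribution of distinct,
near-collinear fibers and of the inhomogeneous fiber density across the
frame; with a constant or linear background the estimator is biased high
by ~8 % because that contribution is convex. The first 15 px are excluded
(segmentation speckle and the filter halo distort the profile near the
origin).

Because even a fraction of a degree of misalignment walks a 200-px profile
off the correlation ridge (sin 1° × 200 px ≈ 3.5 px, comparable to the
fiber width), profile directions may be refined from the 1° preferred
direction by maximising the mean profile value over mid-range lags on a
0.25° grid within ±1.5°.

## Intrinsic order

Population averages mix two effects: order within cells and alignment of
whole cells. To isolate the former, each cell's correlogram is rotated
(bilinear, about zero lag) so its preferred direction sits at 90°; samples
rotated in from outside the grid are marked missing and excluded through
per-element valid counts. Averages are always unweighted across cells with
SEM from the between-cell variance. Rotating the correlogram rather than
the mask is equivalent for this statistic and avoids re-segmentation.

## Cross-correlation of two networks

Two pixel-registered masks of the same cell are cross-correlated over the
smallest rectangle enclosing both. The central peak height is the maximum
within a centered window of half-width 9 px (~1 µm) minus the background,
taken as the median in the annulus 27–36 px (~3–4 µm); the median is robust
to residual central structure, and the recipe is deliberately explicit
because "background" admits many definitions. A window maximum is
positively biased on a noisy field, so for null comparisons the package
also provides the central-window excess over identically sized off-center
control windows, which is unbiased when no true peak exists.

Two controls accompany the measurement. First, the analysis can be
restricted to the largest circle inscribed in the cell (distance-transform
center and radius, both channels clipped identically), removing
periphery-driven contributions. Second, the random-pairing null: a seeded
uniform random derangement pairs each cell's channel-1 mask with a
*different* cell's channel-2 mask; each mask is clipped to a disc of the
smaller of the two inscribed radii centered on its own incenter
(center-to-center registration, the only canonical choice), the discs are
cross-correlated, and the correlograms averaged. Networks from different
cells cannot resemble each other on short length scales, so any central
peak in the null is artifactual.

Disc regions correlated on their square bounding grids with the rectangle
normalization `(N−|i|)(M−|j|)` show a faint cross-shaped background
artifact, because the true overlap of two shifted discs is smaller than
the rectangle factor along the diagonals. The package reproduces this
(default) and also offers the corrected normalization by the exact
lens-shaped overlap area of two discs, which restores isotropy to within
5 % on isotropic inputs.

## Statistics

Per-cell summaries (by convention the ROF value at 90°, where strain
effects concentrate, raw and intrinsic) are compared across conditions
with the two-sample Kolmogorov–Smirnov test (exact for small samples) and
Hedges' g with pooled SD

    s_p = sqrt(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)),
    b   = 1 − 3/(4(n₁+n₂)−9),    g = b (⟨x₁⟩−⟨x₂⟩)/s_p,

with `s₁, s₂` the n−1-denominator sample SDs (forced by the pooled-variance
weights). Raw p-values are reported without multiple-testing correction;
the output table carries everything needed to adjust.

## Synthetic data

The generator renders fibers as rotated filled rectangles at uniformly
random positions and angles drawn from a weighted mode mixture with
optional Gaussian jitter; overlapping fibers add, as fluorescence does.
The image is background (default 10) plus amplitude (default 100) times
the fiber count map, blurred with a Gaussian PSF (default σ 1.5 px), with
Poisson shot noise (default scale 1 photon per intensity unit) and additive
Gaussian read noise (default SD 5). These noise defaults are a generic
confocal-like model chosen once; the validation preset (100 rectangles of
5 × 200 px at 34° in a 600 × 600 px frame) inherits them. The ground truth
is the un-blurred, un-noised occupancy mask plus per-fiber angles, and a
fixed seed makes the realization bit-identical.

By default whole fibers are kept inside the frame (centers uniform over
the inset region) so the rendered rectangles have their nominal length;
with `clip_at_borders=True` centers are uniform over the full frame and
fibers are truncated, which lowers the mean visible length by ~25 % in the
validation geometry and shifts the length estimate accordingly. An
elliptical cell-support mask is available so the inscribed-circle logic is
exercised on non-rectangular supports, and paired generation shares a
tunable fraction of fibers (with positional jitter) between two
independently rendered channels.

What the generator does *not* emulate — curved or branching fibers,
intensity variation along fibers, out-of-focus haze, uneven illumination,
cytoplasmic autofluorescence texture — bounds what passing tests show:
they validate the estimators' geometry and statistics, not robustness to
every property of real stained cells.

## Problem sizes and determinism

The test suite and the acceptance script run the full validation image at
its native 600 × 600 px size; population-level checks use 256 × 256 px
cells with 35–40 fibers (30 cells for the intrinsic-order property, 20
seeds for the null models), sizes at which every statistic under test is
comfortably resolved. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical inputs and seeds reproduce outputs
bit-identically.

## Known limitations

- The preferred direction is quantized to 1°; sub-degree work must use the
  ridge refinement.
- The Niblack speckle floor makes absolute correlogram values depend on
  the noise level; comparisons should always be within-pipeline.
- Fiber width is not recoverable from segmented masks (the filter halo
  obscures it) — this is a documented property of the method, not a bug.
- The random-pairing null requires ≥ 2 cells and assumes cells are
  exchangeable within a condition.
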