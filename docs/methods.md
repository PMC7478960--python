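# Methods

This note documents the models, conventions, numerical choices, and
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and calibration conventions

Images are arrays indexed `[row, col]`. Pixel `(r, c)` has its **centre** at
physical position `x = (c + 0.5)·pixel_size`, `y = (r + 0.5)·pixel_size`;
all distances are nm and all times seconds. Point and track tables store nm,
not pixels, so they survive resampling. Sub-pixel image values are obtained
by bilinear interpolation; an operation whose sample points leave the
interpolable area `[0, N−1]` in pixel indices is rejected with a bounds
error rather than extrapolated.

Fixed analysis constants live in `mck.constants`, each defined once:
32-nm shift step, 0.95 confidence, 1-µm proximity radius, 120-s transport
window, 200-nm thin/thick boundary, 1-µm enlarged-nucleoid cutoff, 42-nm
default PSF sigma (97-nm FWHM).

## Synthetic scenes (`mck.simulate`)

The generator emulates two-channel/three-channel live-cell super-resolution
acquisitions: a 32 nm/pixel grid (one colocalization shift increment per
pixel, making shift tests exact), 1 s frame interval for dynamics and 30 s
for contact stability runs, an isotropic Gaussian PSF of sigma 42 nm
(~97-nm FWHM, the lateral resolution of grazing-incidence SIM), and an
sCMOS-style Poisson–Gaussian noise model (shot noise on
`photon_scale · intensity` plus Gaussian read noise). No noise level is a
claim about any particular instrument: the noiseless sentinel is the
default, and `photon_scale` / `read_noise_sd` are calibration knobs.

- **Tubes** are rasterized exactly: a pixel is occupied when its centre
  lies within `diameter/2` of the axis polyline. The unblurred occupancy is
  the ground truth; the rendered channel is that occupancy convolved with
  the PSF. Rasterization quantizes apparent widths to the 32-nm grid.
- **Spot pairs**: channel-A positions uniform in the field (with a margin
  keeping the PSF inside), channel-B at A plus isotropic Gaussian offsets of
  sd `offset_sd`. When the mean nearest-neighbour spacing of A drops below
  `4·offset_sd`, pair identity becomes ambiguous and a warning is written
  to the event log.
- **Motion models**: Brownian (independent Gaussian increments, per-axis
  variance `2·D·Δt`), ballistic (constant speed, straight line), and
  anomalous via fractional Gaussian increments with Hurst `α/2` (exact
  Cholesky factor of the fGn covariance, cached per `(n, H)`), scaled so the
  2D MSD is `4·D·τ^α` exactly. `H = 1` degenerates to a Gaussian-speed
  ballistic track and is handled specially.
- **Scripted tubule-extension events**: a tubule grows from an initiation
  site on a mitochondrial body at a scripted tip speed, optionally with a
  deterministic sinusoidal speed modulation (fraction `speed_modulation`,
  period `modulation_period_s`). The nucleoid is locked to the tip
  (*coupled*), follows a lag → 1.5× burst → match script without passing the
  tip (*unsynchronized*, with an optional stop a fixed gap behind the final
  tip), or stays at the initiation site (*retained*). The modulation default
  is 0; it exists because a strictly constant-speed pair has no defined
  speed correlation (zero variance), and real tip speeds fluctuate.
- **Determinism**: one integer seed in `SceneSpec` feeds deterministic
  per-purpose sub-streams (`SeedSequence(seed, spawn_key=(stream,))`);
  identical spec + seed gives bit-identical images and ground truth.

What the generator does **not** emulate: 3D structure and defocus,
photobleaching, motion blur within a frame, structured-illumination
reconstruction artifacts, organelle deformation, and background
autofluorescence. Tests passing on these scenes therefore demonstrate the
correctness of the measurement chain, not robustness to every property of
real data.

## Linescan shift correlation (`mck.linescan`)

Profiles are sampled at evenly spaced arc positions along polylines. For
shift `s` (a multiple of the 32-nm step, which must be an integer multiple
of the sampling step), the channel-B profile is displaced by `s` along the
arc and the Pearson correlation with channel A is computed on the
overlapping support of each linescan, then averaged across linescans; the
dispersion is the SEM across linescans. Conventions and choices:

- Shift 0 is computed by the same code path as every other shift, so it
  equals the plain Pearson average bit-for-bit.
- Shifts are evaluated for both signs; the threshold rule scans them
  symmetrically because the analysis is about distance, not direction. A
  channel displaced forward by `k` steps peaks at `+k·step`.
- A linescan with a zero-variance profile on an overlap is excluded from
  that shift's average and the exclusion is logged; if all are excluded the
  shift is flagged undefined.
- **Threshold rule**: the largest `d` such that for every shift `|s| ≤ d`
  the normal-approximation CI lower bound `mean − z·SEM` exceeds 0
  (`z` the two-sided normal quantile of the confidence level, default
  0.95). Contiguity from zero prevents spurious far-shift crossings. A
  zero-shift CI that already includes 0 raises a distinct
  `ThresholdUndefinedError` — this is not a threshold of 0.
- Colocalization frequency uses a **strict** `<` against the threshold;
  the randomized null redraws the B-points uniformly within the supplied
  organelle mask (count preserved, uniform within each mask pixel) rather
  than permuting labels, preserving the organelle constraint. Significance
  is a two-tailed unpaired Student's t-test between per-image observed
  fractions and per-permutation null fractions; with a single image the
  two-sample test is degenerate and a one-sample t-test of the null
  fractions against the observed value is used instead.
- The SEM-based CI matches mean ± SEM reporting practice; a bootstrap CI is
  deliberately not the default (it would change the threshold semantics).

## Contact index and stability (`mck.contact`)

Binarization subtracts a rolling-ball-style background (greyscale
morphological opening with a flat disk, default radius 15 px) and
thresholds by Otsu (or a fixed cutoff). A constant image yields an empty
mask with a warning. The mitochondrial perimeter is the set of foreground
pixels 4-adjacent to background, with the image border counting as
background — a reproducible stand-in for isophote-contour extraction on
binary images. `R` is the pixel-exact intersection of perimeter and ER mask
over the perimeter count (an optional ER dilation radius exists, default
0). `ΔR = R[i+1] − R[i]` per consecutive frame pair, each pair normalized
by its own first-frame `R₀`; the instability statistic averages `|ΔR|/R₀`
over pairs with `R₀ > 0` (excluded pairs are counted and reported), and the
signed mean is emitted alongside for transparency. The magnitude is used
because instability is a spread, not a drift.

## Tracking and MSD (`mck.tracking`)

Detection is scale-normalized Laplacian-of-Gaussian filtering at the
expected spot scale, local maxima with non-maximum suppression, and
per-axis three-point quadratic sub-pixel refinement; quality is the peak
response relative to the frame's strongest peak. Linking is greedy
nearest-neighbour frame-to-frame under `max_disp` (ties broken by smaller
distance, then lower index), no gap closing — a deliberately simple,
fully documented contract appropriate for sparse, manually-checkable data;
Kalman or multi-hypothesis tracking is out of scope.

Speeds are per-interval Euclidean displacements over elapsed time. The
tip–nucleoid coupling statistic is the zero-lag Pearson correlation of the
two speed sequences on common frames (the `corrcoef` convention); a
companion position correlation (mean of per-axis coordinate correlations,
skipping spread-free axes) is always reported alongside, since either
variant is defensible.

MSD is time-averaged per track (all sample pairs at each lag), with the
ensemble mean across tracks when several are given — the appropriate
estimator for single-particle data. The anomalous exponent α is the
least-squares slope on log–log axes over the first 25% of lags (at least
4), limiting the large estimator variance of time-averaged MSD at long
lags; any non-positive MSD in the fit range is rejected as degenerate.
Kymographs sample the line per frame (rows = time, top to bottom), averaged
across an odd number of one-pixel perpendicular offsets.

## Morphometrics (`mck.morphology`)

Tubule diameters: a Gaussian plus constant baseline is fitted to a
cross-section profile; `FWHM = 2√(2 ln 2)·σ` and the PSF is removed in
quadrature, `d = √(max(0, FWHM² − FWHM_PSF²))`. Fits with R² below 0.8, a
non-positive amplitude, or a flat profile are flagged invalid rather than
raising. The Gaussian-fit width of a flat-topped (thick-tube) profile
depends on how much background the cross-section spans: cross-sections
should be short lines drawn across the tubule (±400 nm works well at these
scales), as one draws them in practice, not field-spanning scans. Diameter
classification is thin for ≤ 200 nm (the nanotunnel size range is quoted
as 40–200 nm, so the boundary is inclusive-thin) and thick above.

Transport scoring: an event needs a ≥ 120-s window (2 min), otherwise it is
unscorable and labels are withheld. A nucleoid starting within the 1-µm
proximity radius of the initiation site is *transported* if its
displacement from the initiation site, projected on the tubule axis
(initiation → final tip), exceeds `travel_min` at any time, else
*retained*; a transported nucleoid is *tip located* if its final distance
to the final tip position is at most `tip_tolerance`. The source analysis
scored both visually, so `travel_min` (default 500 nm, half the proximity
radius) and `tip_tolerance` (default 250 nm, ~2.5 nucleoid diameters) are
explicit, documented knobs, not measured constants. Boundary conventions:
proximity inclusive (≤), transported-travel strict (>), enlarged-nucleoid
strict (> 1 µm), thin/thick inclusive-thin at 200 nm.

Nucleoid density is the in-zone point count over the zone-mask area in µm²;
perinuclear/peripheral zones are user-supplied masks, since zone boundaries
are drawn by hand in practice.

## Pipeline, I/O, determinism

Stacks are multi-page TIFF (TCYX) carrying pixel size, frame interval, and
channel names in a JSON ImageDescription; plain TIFFs require explicit
calibration overrides. Tabular outputs are CSV, summaries JSON, image
outputs TIFF; every artifact set carries a provenance sidecar with a hash
of the scientific configuration (output paths excluded) and the seed, so a
rerun with the same config and seed is byte-identical. `run_pipeline`
executes stages in dependency order and reports the failing stage without
corrupting earlier artifacts.

## Problem sizes used by the verification scripts

The test suite and acceptance script choose fixture sizes that make each
statistic's sampling error small relative to its tolerance while staying
desk-scale: 100 spot pairs per scene and 5 seeds for threshold recovery;
1000 permutations for the randomized null (Monte-Carlo SE ≲ 0.002); 100
tracks of 500 frames per exponent for MSD recovery (mean α stable to
±0.05); 10 scripted events for transport fractions; 121-frame (2-min)
windows at 1 s for event scoring. Threshold-recovery monotonicity in the
pair offset is asserted on the mean over seeds: the per-seed threshold is
an integer multiple of 32 nm and its CI-based definition makes single-seed
values non-monotone at large offsets, where the per-linescan dispersion
legitimately grows.

## Known limitations

- The 2D analysis ignores axial structure; diameters and distances are
  lateral projections.
- Greedy linking without gap closing splits tracks across detection
  dropouts; statistics that need long tracks should filter by length.
- The quadrature PSF correction assumes a Gaussian PSF and a roughly
  Gaussian apparent profile; for tubes much wider than the PSF the fitted
  FWHM (and hence the corrected diameter) is biased a few percent low.
- The randomized null redraws positions uniformly within the mask; it does
  not preserve higher-order spatial structure (clustering) of the original
  point set.
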