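# Methods

This note records the modelling conventions, parameter defaults and
design choices behind `cellpeer`, and what the synthetic benchmark does
and does not demonstrate.

## Trajectory preprocessing

Tracks shorter than 50 points (50 min at 1 frame/min) are discarded:
below that, per-track moment and entropy statistics are dominated by
sampling noise.  Remaining tracks are smoothed with a penalized cubic
spline fitted independently to x(t) and y(t), minimizing
p·Σ(y−f)² + (1−p)·∫f″², with the smoothing weight p = 0.99 by default
(p = 1 interpolates exactly).  The default suppresses single-frame
localization jumps — a tracker occasionally re-uses the previous
position or snaps to the wrong cell — while leaving the path shape
intact.  Unsupervised outlier-track removal then flags tracks whose
median/MAD z-score exceeds 3.5 on either per-track mean speed or the
fraction of zero-displacement frames, the two signatures of tracking
failure (false localizations, frozen positions).

Coordinates are 0-based pixels, x rightward, y downward; time is in
minutes.  Physical units enter through a single `pixel_size`
(default 0.66 µm/px, configurable — plausible values for small-scale
inverted microscopes range over at least a factor of two, and nothing
downstream depends on the absolute scale).

## Motility descriptors

Speed uses forward differences; curvature uses central differences with
endpoints dropped — curvature is second-order sensitive and one-sided
stencils inflate endpoint noise.  The turning angle is the four-quadrant
`atan2(v_y, v_x)`; a principal-value arctangent of a component ratio
would fold quadrants together and make the angle's spread and entropy
ill-behaved (`printed_axis_order=True` swaps the arguments for the
ratio-axis convention).  Angular velocity is ω = v/R with R the distance
from the track's time-averaged center.  Samples where a quantity is
undefined (zero speed for χ and ϑ, R = 0 for ω) are emitted as NaN and
excluded from summaries; a series more than 50% missing yields missing
descriptors and the track is dropped with a logged reason.

The diffusion coefficient comes from ordinary least squares of
ln MSD(τ) on ln τ with the time-averaged (overlapping-window) MSD
estimator, reported as D = e^{y₀}/4.  The fit range is
lags 1..min(⌊N/4⌋, 20).  The short-lag cap matters: beyond a small
fraction of the track length the time-averaged MSD rests on a handful of
effectively independent segments, and its scatter leaks into the
intercept — fitting all lags up to N/4 on 2000-frame Brownian tracks
overestimates the mean D by ~20%, while the capped range recovers it to
within 1%.  The range is configurable.

Directional persistence p = ‖x(t_f) − x(t_i)‖ / L with L the summed step
lengths; p ∈ [0, 1] by the triangle inequality, and is NaN (with a flag)
for an immobile track.

The motility vector has 22 entries: 5 statistics (mean, SD, skewness,
kurtosis, Shannon entropy) for each of v, χ, ϑ, ω, plus D and p.  The
count is fixed by this composition, is introspectable via
`MOTILITY_DESCRIPTOR_NAMES`, and never varies between tracks.

## Shape descriptors

Eccentricity (foci distance over major-axis length of the
equivalent-second-moment ellipse), area, perimeter and solidity
(area over convex-hull area) are computed per frame.  Polygon mode is
the default — exact shoelace/arc-length/moment formulas on the contour —
because it is resolution-independent and testable against closed forms;
raster mode rasterizes the contour and applies the pixelwise
definitions (area = pixel count, perimeter = count of region pixels with
at least one zero 8-neighbor), matching binary-mask implementations.
The two agree on area to within 5% for convex shapes above ~15 px
diameter.  Each scalar's time series is summarized by 6 statistics
(the 5 above plus a spectral signal entropy), giving 24 descriptors.

## Series statistics conventions

Standard deviation is the population SD; skewness is adjusted
Fisher–Pearson; kurtosis is Pearson (non-excess).  Shannon entropy uses
a 16-equal-width-bin histogram over the series' own range, log base 2 —
a fixed binning makes tests exact (two equally occupied bins give
exactly 1 bit).  "Signal entropy" is the normalized spectral entropy of
the periodogram with the DC bin excluded (0 for a constant series, ~1
for white noise); unlike the other five statistics it depends on sample
order by construction.  Numerically constant series are flagged
degenerate: skewness and kurtosis are reported as 0 and both entropies
as 0, rather than amplifying catastrophic cancellation.

## Cluster identification

Every track point is stamped as a disk of the mean cell radius
(default 15 px ≈ the radius of a 600–800 px² cell); the per-pixel sum
over all frames, normalized by its maximum, is thresholded with Otsu's
criterion on a 256-level quantization (so an exhaustive 256-level search
is an exact oracle), refined by morphological closing then opening with
a disk of the same radius, and 8-connected components become clusters.
Closing first bridges the per-cell blobs of one cluster; opening then
removes isolated specks.  Tracks are assigned to the cluster covering
the plurality of their points (ties to the lower label; label 0 =
unclustered, excluded from cooperative decisions).  On default synthetic
geometry this recovers the generating cluster structure with mean
adjusted Rand index ≈ 0.9 and >90% of canonical tracks matched.

## Selection stages

Descriptors are ranked by pairwise class-separation AUC (rank-sum
estimator, ties counted half), direction-corrected as max(AUC, 1−AUC)
and averaged over class pairs.  The retained set F̃ keeps descriptors
scoring ≥ 0.75, **capped at 2** (floor: top-2 by rank).  The small cap
is deliberate: sample filtering is a *conjunction* over the selected
descriptors, and measured on 30%-contaminated synthetic experiments a
cap of 8 removes 70–88% of canonical training tracks — starving model
construction — while a cap of 2 keeps the filter selective
(contaminated tracks are removed at ~1.7× the canonical rate) without
gutting the training set.  The cap is configurable.

Good-teacher selection retains training rows whose selected descriptors
all lie within the closed per-video percentile interval [0.2, 0.8]
(linear-interpolation quantiles); test-sample selection applies
[0.1, 0.9] on the held-out video's own quantiles.  Retained sets nest
as the bounds tighten.  If filtering would eliminate a class from the
training set entirely, the unfiltered training set is kept for that fold
(logged).

## Dynamic feature selection

A forward-only stepwise pre-selection on the training set (OLS on the
numeric class code, partial F-test entry at p < 0.3, removal disabled,
ties by column order) caps the candidate pool.  Each test row then keeps
the descriptors passing all three of:

* Fisher ratio Σ n_c(μ_c−μ)² / Σ n_c σ_c², normalized by the maximum
  over candidates (best descriptor scores exactly 1) — threshold 1.0
  (shape) / 0.9 (motility);
* univariate standardized distance |x−μ|/σ from the pooled training
  distribution, normalized per row by its maximum — threshold 0.1;
* maximum class posterior from per-class univariate Gaussians with equal
  priors (computed in log space so extreme outliers resolve to the
  nearest class's limit) — threshold 1.0 (shape) / 0.2 (motility).

The [0, 1] normalizations make those conventional thresholds meaningful
— a raw-scale Mahalanobis threshold of 0.1 SD would reject nearly
everything; raw-scale mode remains available.  An empty intersection
falls back to the Fisher-passing set, then to the full pool, so the
subset is never empty.  The classifier is retrained per distinct subset
and cached, so rows sharing a subset share one fitted model.

## Classification and cooperative decision

LDA posteriors are used as scores directly (singular pooled covariance
triggers an automatic shrinkage refit).  The linear SVM's margins are
calibrated by a multinomial logistic fit on the training decision
values — a deliberate in-sample calibration, since per-row DFS retrains
on subsets too small for cross-validated calibration.  KNN (K = 5,
Euclidean, z-scored inputs) scores by neighbor vote fractions.  All
score vectors are non-negative and sum to 1.

Majority voting takes the plurality label, resolving ties by maximum
trustiness restricted to the tied labels, then by lowest label index;
maximum trustiness takes the largest per-class score sum, ties to the
lowest label.  Clusters with no surviving member abstain and are
counted separately from the cluster-level confusion matrix.

Standardization (z-score) parameters are computed on the refined
training set only and applied to the test rows, per fold.

## The synthetic generator

Motility is a discrete Ornstein–Uhlenbeck velocity process: relaxation
time = the configured persistence time, stationary speed Rayleigh with
the configured mean (the velocity scale is calibrated so the empirical
per-frame mean speed matches even when diffusive positional jitter is
added; the pure OU walk's long-time diffusivity is σ_v²·P/2).  Cells
are tethered to jittered-grid cluster centers by a spring that engages
only beyond a per-cell free radius (40 px; a configurable fraction of
"boundary" cells get twice that), so clusters stay compact without
distorting per-frame speeds.  Contours are 64-vertex noisy ellipses
with class-specific area and eccentricity; pseudopod events add a
one-sided radial bump whose flanks indent the convex hull, lowering
solidity.  Contaminated tracks re-use the same generator with speed ×3
and persistence ×0.2 by default.

The canonical benchmark is 3 classes × 4 videos × (4 clusters × 6
cells), 360 frames at 1 frame/min, mean speeds (0.3, 0.8, 1.6) px/min,
persistence times (2, 6, 15) min, 20% contamination — deliberately
well-separated classes at a desk-scale problem size (a few minutes per
replicate on one core).

What the generator does **not** emulate: cell division and death,
cell–cell collisions and contact inhibition, drift and stage jitter,
segmentation noise correlated with motion, class-conditional track
lengths, or any calibration to a particular cell line's motility
distributions.  Passing
benchmarks therefore demonstrate internal correctness and the
qualitative behavior of the selection/cooperation machinery — cluster
decisions at least as accurate as single-track decisions, selection
never hurting — not field performance on real microscopy.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics, closed
  interval bounds.
* AUC of a globally constant descriptor: exactly 0.5, logged.
* Otsu on a constant map: error (threshold undefined).
* Videos with fewer than 5 feature rows: percentile filter passes them
  through with a warning; outlier flagging requires ≥ 5 tracks.
* Stepwise selection entering nothing: full descriptor set with a
  warning.
* All ties (labels, cluster assignment, subset ordering) break
  deterministically, so identical config + seed reproduces a run
  bit for bit.

## Known limitations

* The per-test-row retraining cost grows with the number of distinct
  DFS subsets; caching bounds it in practice but worst case is one fit
  per test row.
* The stepwise pre-selection regresses the numeric class code, which
  assumes an ordering among classes; with well-separated classes the
  selected pool is insensitive to the coding, but an ANOVA-based entry
  test would be cleaner for many-class problems.
* Raster-mode shape scalars depend on rasterization resolution;
  sub-pixel contours should use polygon mode.
* Cluster segmentation assumes clusters are separated by at least a few
  cell radii; overlapping clusters merge and their cooperative decision
  pools the member tracks.
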