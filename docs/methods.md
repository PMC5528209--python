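# Methods

This note records the models, parameter choices, numerical details and known
limitations behind `foragescale`. It documents what the code computes and
why; every number quoted here is produced by the package's own tests or
scripts.

## Telemetry handling

Tracks are time-ordered GPS fixes per deployment. Gaps longer than one week
(strictly greater than 7 × 86 400 s) split a track into independent pieces,
suffixed `a`, `b`, … in temporal order; the boundary case of exactly seven
days does not split. Duplicate timestamps keep the first fix
(deterministic, logged). All metric computation uses planar coordinates from
a per-track spherical azimuthal-equidistant projection centered on the track
centroid (mean Earth radius 6 371 008.8 m). Centering per track avoids
projection-zone seams for wide-ranging birds; distances from the center are
exact great-circle distances and the residual distortion of inter-fix
distances is negligible at foraging-trip extents. The projection center is
recorded in `crs_note`, and the exact inverse restores lon/lat for export
(GeoJSON, WGS84 convention). Deployment summaries report the tracking span
in fractional days internally, rounded to integer days only in the
reporting schema.

## First-passage time

FPT(i, r) is the time the path spends crossing the circle of radius r
centered on fix i: the interval between the last entry crossing before the
fix and the first exit crossing after it. The path is modeled as piecewise
linear between fixes, under which crossings are located exactly by solving
the quadratic for where a step meets the circle — no resampling resolution
parameter. Because distance-to-center is convex along a linear step, the
first step whose far endpoint reaches r contains the crossing, which lets
each fix's whole radius column be located with one sorted search over the
running maximum of vertex distances. FPT is undefined (NaN) when the track
ends before crossing in either direction; undefined values are excluded
per-radius from all statistics (listwise exclusion was considered and
rejected as needlessly data-hungry; the flag structure would admit it).

The radius grid realizes "r_min to r_max in fixed steps" as the arithmetic
progression r_min, r_min + step, … ≤ r_max (with the 100/10 000/80 default,
the last radius is 9 940 m). The variance of log FPT uses the natural log
and the sample variance (ddof = 1), needs ≥ 2 defined values per radius, and
the population curve averages individuals per radius, omitting individuals
undefined there. The population peak r_pop is the global maximum of the mean
curve, ties broken toward the smaller radius. Per-species r_pop is computed
separately, and each species' downstream pipeline runs at its own radius.

## Segmentation

The FPT series at r_pop (raw FPT by default; a log option exists) is
partitioned into K contiguous bouts minimizing the within-segment sum of
squares about segment means ("mean" contrast; a Gaussian mean+variance
contrast is available). The minimizer is exact: dynamic programming over
(position, segment count), implemented as K min-plus products of the running
best vector with the O(n²) precomputed single-segment cost matrix, with ties
broken toward the earliest breakpoint. J(K) is therefore nonincreasing in K
by construction, which the tests verify against exhaustive enumeration for
small n.

K_opt uses the second-derivative rule on the standardized contrast
J̃(K) = (J(Kmax) − J(K)) / (J(Kmax) − J(1)) · (Kmax − 1) + 1: the largest K
with D(K) = J̃(K−1) − 2 J̃(K) + J̃(K+1) > S, defaulting to S = 0.75, and
K_opt = 1 when nothing qualifies (including the flat-contrast degenerate
case of a constant series). Kmax defaults to min(⌊n / (2 L_min)⌋, 40) as a
deterministic stand-in for per-individual visual assessment, and is
overridable. L_min is a per-species setting chosen so L_min × fix interval
is a fixed bout duration — 24 h for both study species (12 fixes at 2 h; 6
fixes at 4 h) — and the framework config enforces that equal-duration policy
across species by default.

A practical caveat measured during development: on homogeneous (white-noise)
series the curvature statistic is noisy, and with S = 0.75 the rule returns
spurious K_opt > 1 for a substantial fraction of short series; the null
stabilizes (majority K_opt = 1) only for long series relative to Kmax
(the test suite uses n = 2000, L_min = 100, Kmax = 8). This matches the
known sensitivity of S for series under ~500 fixes, about which the code
warns. Fixes whose FPT is undefined at r_pop (track edges) are imputed from
the nearest defined neighbor in time so indices stay aligned with fixes;
if the whole series is undefined (r_pop beyond a short track's extent) the
pipeline keeps that track as a single bout and logs it.

## Movement-based kernel UD and patches

Each bout yields one utilization distribution. Steps with duration
T ≤ T_max are lined with interpolation points every τ seconds (midpoints of
equal time slices); the point at relative position p carries an isotropic
Gaussian kernel with bridge variance h²(p) = h²_min + 4 p (1 − p) D T —
minimal at the fixes, maximal mid-step — and a weight making each step's
total weight proportional to T (a time-weighted UD). Steps longer than
T_max are treated as track interruptions and contribute nothing. Kernels
are discretely normalized on the raster before accumulation, so total mass
is exactly 1 up to float rounding.

Defaults: h_min = 100 m (≈ 5 × the 10–20-m GPS accuracy class of these
tags), T_max = 3 × the nominal fix interval, τ = fix interval / 10, cell
size 50 m, raster padded to 5 kernel standard deviations (3 sd would clip
~1% of a Gaussian's mass and bias the 95% isopleth area low by ~6%; 5 sd
makes the truncation negligible). The diffusion coefficient D is estimated
per bout as the median over steps of d²/(4T) — for planar Brownian motion
d²/(4T) is exponentially distributed with mean D, so the raw median is a
robust estimator concentrated at D ln 2; the tests check it against that
constant. A fixed D can be supplied instead.

The 95% isopleth is taken cell-wise: cells sorted by density (ties by
row-major index), the smallest prefix reaching 95% of mass selected. Its
8-connected components are the patches; patch area is cell count × cell
area, exactly reproducible, with the polygon outline (union of cell
squares) as export cosmetics. On a fine-grid Gaussian UD the single patch's
area matches the closed form π · 5.991 · σ² within 5% (χ²₂ 95% quantile),
which the tests assert, along with grid-convergence under cell halving and
rigid-motion invariance.

When species are compared across very different movement scales, h_min and
the cell size should scale with the movement scale; a fixed 100-m h_min
under-smooths trajectories whose steps are kilometers long and fragments
their isopleths.

## Modality statistics

All statistics operate on natural-log patch areas (areas are strongly
right-skewed). The two-sample KS test is scipy's, with the asymptotic
two-sided p-value; the D statistic is invariant under common monotone
transforms, so testing areas or log areas is equivalent (asserted).

Silverman's test: the critical bandwidth h_crit(k) is the smallest Gaussian
KDE bandwidth at which the sample shows ≤ k modes, found by bisection to
relative tolerance 1e-4 (valid because the Gaussian-kernel mode count is
nonincreasing in h). Modes are strict local maxima of the KDE on a
512-point grid spanning [min − 3h, max + 3h], plateaus counted once. The
smoothed bootstrap resamples the data, adds N(0, h²_crit) noise and
rescales by 1/√(1 + h²_crit/s²) so replicate variance matches the sample
variance; p(k) = (1 + #{replicates with > k modes at h_crit}) / (B + 1)
with B = 999 by default. We report both p(k) and the multimodality support
m(k) = 1 − p(k), declared at m ≥ 0.95, so large values support "more than k
modes" in the same direction as the declaration cut-off. Under a unimodal
null the k = 1 p-values are conservative (rejection at 5% stays below
nominal over 200 seeded datasets in the tests). The scan runs k = 1…30 by
default and reports the k with maximal support.

Cell quantization matters at small sample sizes: patch areas are integer
multiples of the cell area, so samples dominated by few-cell patches are
genuinely discrete on the log scale and Silverman's test can support
multimodality for that reason alone. With the ~50-patch samples of the
default synthetic runs this effect is visible; it fades as patch counts and
patch sizes grow.

## Sensitivity analysis

The shift constant is applied on the log-area scale (a shift δ multiplies
areas by e^δ): detectable differences are reported as differences in mean
log area, which is the scale on which they are commensurate across the two
procedures. Raw-scale shifting is available by flag. The KS procedure scans
δ = 0.01, 0.02, … and returns the smallest δ with p < α (α = 0.05 default;
deterministic, no resampling). The pooled-bimodality procedure pools the
sample with its shifted copy and runs Silverman's k = 1 test per δ; because
each step costs a bootstrap, the grid is walked coarsely (5 × increment)
and refined at the fine increment inside the bracketing interval, returning
a δ on the fine grid. Detection monotonicity in δ holds only stochastically
and is tested as a majority-of-seeds property. The KS detection threshold
decreases with sample size, asserted at n ∈ {100, 457, 1269} on one
lognormal family.

## Synthetic data

`simulate_forager` is a two-mode composite correlated random walk sampled
once per fix interval: lognormal step lengths (CV 0.5) and wrapped-normal
turning noise, with mean resultant length ρ parameterizing persistence.
Intensive (area-restricted search) mode: short steps (default 150 m per 2-h
fix), weak persistence (ρ = 0.2), radial reflection at the patch boundary.
After a geometric residence (mean 40 fixes) the walker commutes: long steps
(1 500 m), strong persistence (ρ = 0.9), heading aimed at another patch's
center, switching back on arrival. Patch centers sit on a jittered ring
sized so adjacent spacing is at least the configured spacing (default
5 000 m for 500-m patches). Defaults mirror the study system: 2-h fixes,
patches a few hundred meters to a kilometer across, commutes of several
kilometers, residences of a few days, 600 fixes ≈ 50 days.

What the simulator does not emulate: location error, irregular fix
schedules, resource-driven (landscape-correlated) patch choice, diel
rhythms, or annual-cycle phases. Passing the recovery tests therefore shows
the pipeline resolves clean two-mode movement at the right scale — not that
it is robust to every property of real telemetry.

The recovery experiments run at reduced problem sizes chosen to exercise the
science: 5 individuals × 600 fixes for scale recovery (population peak
within a factor of 2 of the 500–1000-m radius–diameter band across 10
seeds), 3 × 3 individuals × 400 fixes for the pipeline null and 10×-scale
positive controls, and B = 499 bootstrap replicates where a full scan is
not needed.

## Limitations

- The second-derivative K_opt rule is noisy on short homogeneous series
  (see above); treat K_opt from series ≪ 500 fixes with caution.
- The bridge-variance UD is a reconstruction of the movement-based KDE
  family from its defining assumptions; boundary-constrained variants and
  habitat weighting are out of scope.
- Patch areas inherit raster quantization; choose cell sizes ≤ h_min/2 and
  interpret modality tests on small patch samples accordingly.
- The KS p-value is asymptotic; at very small patch counts (< ~20 per
  group) exact methods would be preferable.
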