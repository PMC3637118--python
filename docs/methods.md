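# Methods

## Problem and track model

A raw GPS track is an ordered sequence of timestamped fixes. The task is to
reduce it to *stops* — places where the device dwelt for at least a minimal
stay duration — together with a timetable of visits, so that downstream
exposure analyses can attach environments to discrete activity locations
rather than to every raw fix.

All detection runs on planar coordinates in meters; geographic input is
projected at the I/O boundary with a spherical azimuthal-equidistant
projection centered near the data (exact in distance from the center,
inter-point distortion below 0.1% at the few-kilometer scales involved;
input farther than 100 km from the reference is rejected). Timestamps are
POSIX seconds internally and ISO-8601 in files.

## Kernel-density detector

1. **Density surface.** The quartic (biweight) kernel
   K(d) = 3/(πh²)·(1 − d²/h²)² for d ≤ h (0 beyond) is summed over all fixes
   of the track and evaluated at the centers of a square grid. The kernel
   integrates to one, so the surface integrates to the fix count — checked
   in tests to 1%. The bandwidth h is the single spatial parameter.
2. **Peaks.** Cells that are positive, not exceeded by any 8-neighbor, and
   strictly above at least one neighbor are local maxima; 8-connected
   plateaus of equal density collapse to one peak at the plateau's cell
   centroid. Peaks are ordered by descending density (ties: row-major cell
   order) and numbered in that order — the ordering fixes all later
   tie-breaks, making runs deterministic.
3. **Allocation.** Every fix joins its nearest peak if that distance is at
   most the allocation radius (1.5·h by default, see below), else it is a
   trip fix. Exact distance ties (within 1 nm) go to the lowest peak id.
4. **Timetable.** Maximal runs of consecutive fixes sharing a peak become
   visits; consecutive visits to the same peak separated by at most
   `merge_gap` (60 s) merge across the gap, so a single noisy excursion
   does not split a stay.
5. **Stops.** A peak is reported as a stop when at least one of its visits
   reaches the minimal stay duration (300 s) and at least
   `min_peak_support` (2) fixes were allocated to it. The reported duration
   is the total over all its visits; the reported location is computed
   off-grid (below). Stops are returned in order of first visit.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `bandwidth` h | — | kernel radius (m); the scale of smoothing |
| `min_stop_duration` | 300 s | minimal stay to qualify as a stop |
| `cell_size` c | max(h/10, 2 m) | density grid resolution |
| `merge_gap` | 60 s | maximal bridged gap between same-peak visits |
| `min_peak_support` | 2 fixes | suppresses single-fix artifacts |
| `allocation_radius_factor` | 1.5 | allocation radius as a multiple of h |
| `qualify` | `visit` | stay test per visit (vs summed `total`) |
| `refine` | `kernel_centroid` | off-grid location estimator |

### Design choices that were genuinely open

- **Kernel.** Quartic/biweight, the convention of GIS kernel-density tools;
  compact support is also what makes the stamped-grid construction linear
  in the fix count (each fix touches ~(2h/c)² cells).
- **Allocation radius 1.5·h.** With Gaussian positional noise of per-axis
  SD ν, a fix lies within r of the stop center with probability
  1 − exp(−r²/2ν²). At the hardest operating point ν ≈ h, radius h keeps
  only ~39% of a stay's fixes and clips its visits (mean duration errors of
  10% and more at high noise); radius 1.5·h keeps ~68% and brings the mean
  absolute duration error below ~3% in every noise stratum at h = 200 m,
  at the cost of admitting a little more trip traffic near the peaks.
- **Per-visit qualification.** The minimal stay is a property of a *stay*:
  a single visit must reach it (exactly as the sequential comparator
  requires of a cluster). Requiring only the per-peak *sum* lets satellite
  peaks of a noisy stop accumulate many short fragments past the threshold
  and show up as false positives.
- **Location refinement.** The grid peak is at best accurate to the cell
  size, so stop locations are re-estimated off-grid as the quartic-weighted
  centroid of the peak's allocated fixes (weights centered on the peak
  cell). One smoothing step is deliberate: iterating mean-shift to full
  convergence finds the exact mode of the *sampled* surface, which chases
  sampling bumps once noise exceeds the bandwidth and roughly doubles the
  location error there; a plain unweighted centroid is instead dragged by
  allocated trip fixes at kilometer bandwidths. Both alternatives remain
  available (`refine="mode"`, `"centroid"`).
- **No density floor on peaks.** Spurious trip-side peaks are eliminated by
  the duration filter: at travel speed v a trip stream can occupy a peak's
  allocation disk for at most ~2·1.5h/v seconds (90 s at h = 300 m and
  10 m/s), well under the 5-minute threshold for all tested bandwidths.

### Numerical notes

- The grid is padded by at least one bandwidth beyond the fixes' bounding
  box (so all kernel mass is on-grid) and anchored so the bounding-box
  minimum falls on a cell center; translating a track by whole cells
  therefore translates its detected stops exactly (tested).
- Kernel stamping is chunked so the per-chunk stamp tensor stays near
  4·10⁶ entries; accumulation uses `bincount` on flat indices. A brute-force
  per-cell reference implementation is kept in the package and the two are
  asserted equal to 1e-9 relative on 500-fix instances.
- Grids above 4·10⁸ cells are refused (pathological cell sizes).
- Degenerate inputs: an empty fix set is an error; an all-zero surface
  yields no peaks; a track whose every peak fails the duration filter
  yields an empty stop list.

## Fixed-threshold comparator

The sequential baseline scans fixes in time order and grows a cluster while
each fix remains within the roaming radius d of a reference point, emitting
the cluster as a stop (at its centroid, with one visit spanning first to
last fix) when its time span reaches the minimal stay duration.

The reference point is genuinely underdetermined in the classical
literature, so three disciplines are implemented: against the cluster's
**first fix** (default), against the **running centroid**, and a **sliding
window** that advances the start fix by one whenever a candidate window
fails the duration test. On the synthetic benchmark the first-fix reading
reproduces the known failure profile of this algorithm class most
faithfully across the whole bandwidth range — total blindness when d sits
below the noise level, massive stay fragmentation (false positives) when
d is within a small multiple of it, and stop merging at kilometer radii;
the centroid reading is noticeably more robust at large d (its centroid
converges to the stay center, so clusters essentially never fragment), and
the sliding window over-fragments trips at large d. No outlier buffer is
kept (a single excursion splits a stay — the documented
duration-underestimation failure mode) and nearby successive stops are not
merged.

## Synthetic-track generator

Each track: `n_stops` (3) centers drawn uniformly in a 6 km × 6 km square
with no minimum separation; a stay duration per stop drawn by first picking
one of three categories uniformly — [6, 20], [20, 120], [120, 360] minutes —
then uniformly within it; straight-line trips between consecutive stops at
36 km/h; fixes every 10 s; finally every fix displaced by independent
bivariate Gaussian noise whose per-axis SD ν is drawn once per track,
uniformly on [0, 200] m.

Rationale for the non-obvious constants: the short-stay lower bound (6 min)
sits just above the 5-minute detection threshold so that every simulated
stop is in principle detectable and "three detected stops" is always the
correct answer; the long category is capped at 6 h so it can be sampled;
uniform placement in the 6 km square yields a ~12% incidence of tracks with
two stops within 800 m — the close-stop discrimination subset — and trip
legs of ~3 km on average. Track i draws from an RNG substream keyed by
(master seed, i), so tracks are individually reproducible and the whole set
is byte-stable under a seed (tested).

What the generator does **not** emulate, and what that means for the
benchmark: no signal dropouts or gaps (real urban tracks lose fixes
indoors; density-based detection then needs gap interpolation first), no
speed variation or transport-mode changes, no autocorrelated or systematic
(urban-canyon) positional error — noise is i.i.d. Gaussian per fix, which
is kind to both detectors but especially to density smoothing, and no
revisits of the same place within a track. Passing this benchmark
demonstrates noise resilience and parameter sensitivity under controlled
conditions, not performance on real-world tracks.

## Evaluation

Per processed track: *on target* if exactly the true number of stops was
detected, *false negative*/*false positive* if fewer/more; a track with the
right count but some detected stop farther than 1,000 m from every true
stop is an *outlier* (a false positive canceling a false negative) and
discarded from the on-target group. Spatial accuracy (Euclidean distance to
the closest true stop) and temporal accuracy (signed relative duration
error against that stop) are aggregated over on-target tracks only, where
the correspondence is unambiguous; matching is detected→closest-true, with
an optimal one-to-one (Hungarian) option off by default. Noise strata are
[0,50), [50,100), [100,150), [150,200] m (half-open, last closed — the
brackets partition the drawn range). Close-stop discrimination counts
on-target tracks among those whose truth has two stops within 800 m.
Bandwidth sensitivity records, per track and detector, the smallest and
largest bandwidth achieving on-target, averaged per noise stratum; tracks
that never succeed are excluded from those averages. Duration-stratified
tables are computed at stop level alongside.

## Problem sizes

The shipped benchmark is 750 tracks × 6 bandwidths [10, 50, 100, 200, 500,
1000 m] × 2 detectors = 4,500 runs per detector (~1.5 million fixes), which
completes in a few minutes on one CPU; unit and property tests run on
purpose-built tracks of tens to thousands of fixes.

## Known limitations

- The kernel detector cannot separate true stops closer than roughly the
  bandwidth (mass-dependent, up to ~1.3·h for unequal stays): at h = 1 km
  a substantial share of uniformly placed stop pairs merge, which is the
  dominant failure mode at the largest bandwidth.
- Stop locations at high noise are limited by the ν/√N sampling floor of
  the stay's fix cloud; short stays at ν ≈ 200 m carry ~30 m of
  irreducible location error.
- Global (whole-track) density computation is not streaming-friendly;
  re-running on a sliding data window is the natural adaptation for
  near-real-time use.
- The comparator implements minimal classical readings only; buffered
  variants that tolerate brief excursions would underestimate durations
  less but blur the baseline the benchmark is meant to characterize.
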