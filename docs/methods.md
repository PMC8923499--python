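# Methods

`swimtel` estimates in situ swim velocities of acoustically tagged fish in
a river channel by combining TDOA multilateration of tag pings with a
gridded 3-D hydrodynamic velocity field, and summarizes the resulting
behavior with weighted distributional statistics. Every stage can be
exercised against synthetic scenarios with known ground truth, so the
package is validated by parameter recovery rather than against field data.

## Coordinate conventions

All modules share a local planar Cartesian frame in meters: `x`
along-channel (positive downstream), `y` cross-channel, `z` positive up
with the undisturbed water surface near `z = 0`. Times are seconds from an
arbitrary scenario epoch. Flow-frame swim components follow the rotation
`u_long = u_s · f̂`, `v_lat = u_s · (f̂_y, −f̂_x)` where `f̂` is the unit
vector of the *depth-averaged* water velocity. With `x` downstream this
makes positive `v_lat` point toward −y; all lateral analyses use the
unsigned lateral speed `|v_s|`, so the handedness convention does not
affect any reported quantity.

## Clock synchronization

Receiver clock offsets are modeled as continuous piecewise-linear
functions on a shared regular knot grid (default spacing 1 h; the
granularity is a compromise between tracking slow drift and conditioning —
each knot must be constrained by many beacon detections). Each beacon
detection contributes one linear equation

    raw − d/c = T_k + Σ_j w_j(t) θ_{r,j}

in the unknown per-ping emission times `T_k` and offset knot values `θ`.
One designated reference receiver (a clock-disciplined, cabled unit) is
the gauge: its offsets are fixed at zero, and all recovered offsets are
relative to it. The emission times are eliminated exactly by within-ping
centering, leaving a small sparse normal system in `θ` alone; removal
iterations then *downdate* this system rather than rebuilding it, so a
day of ~340k detections solves in seconds.

**Erroneous-ping removal.** The solver iteratively removes the single
detection with the largest absolute residual and re-solves. The iteration
continues while the RMS residual exceeds `rms_threshold` (default 1 ms)
*or* the worst residual exceeds an outlier cutoff (default 3× the RMS
threshold). The second clause is a deliberate design choice: when the
corrupted fraction is small (≲0.1%) and delays are tens of milliseconds,
gross outliers can hide below a 1 ms *RMS* while individually standing
~20σ above the arrival noise; the worst-residual cutoff flags them without
touching clean detections (the expected maximum of ~3×10⁵ Gaussian
residuals at 0.2 ms noise is ≈1 ms, comfortably under the 3 ms cutoff).
RMS is non-increasing across removals, and a removal cap
(max(0.5%, 100)) guarantees termination, flagging the window unsuccessful.
Receivers not connected to the reference through shared pings are reported
unsolvable rather than silently extrapolated. Long deployments are solved
in consecutive windows (default five days) and concatenated.

## Multilateration

Multipath echoes are removed per (receiver, source) by dropping any
detection closer than 2.5 s (half the 5 s pulse-rate interval) to the
previously retained one. Corrected detections are clustered into
transmission events by splitting at gaps larger than the array's maximum
propagation delay (×1.5 slack for residual clock error). Each event with
≥3 distinct receivers is located by Gauss–Newton least squares over
(x, y, T); two-receiver events are counted but not located — resolving
them requires a whole-track motion prior, which this per-ping solver
deliberately omits in favor of transparency and testability. The tag is
held at a fixed depth (default 1 m below the surface) for slant ranges,
since the shallow array geometry cannot resolve the vertical coordinate.
Initialization uses the previous fix of the same tag when less than 60 s
old, else the array centroid; non-convergence in 50 iterations or a
solution >1 km from the array rejects the fix.

The reported positional uncertainty is
`sd = sqrt(trace(Σ_xy))` — the root of the summed position variances
(DRMS) from the linearized covariance `σ̂² (JᵀJ)⁻¹`, with `σ̂²` the residual
variance floored at a configurable arrival-noise scale for low-redundancy
fixes. DRMS was chosen over the per-axis mean variance because it yields
conservative coverage (P(|error| < 2·sd) ≳ 0.95 for any error anisotropy),
which the Monte-Carlo coverage test checks directly.

## Quality screening

Fix-level filters (sd > 10 m, <2 receivers), endpoint truncation to ≥3
receivers, clipping to the analysis polygon plus a 30 m upstream buffer,
a ≥10-position minimum, and a 60 min residence bound (transit should take
15–30 min; lingerers are likely predators) are applied in that fixed
order; residence is measured within the clipped region. After swim
velocities exist, tracks whose mean swim speed exceeds 0.5 m/s are also
dropped as predators. The cascade is idempotent, monotone in its
thresholds, and logs exactly one rejection rule per dropped track.

## Field extraction and swim velocity

The velocity field lives on a regular (t, z, y, x) grid with bed and
water-surface elevations. Vertical averaging integrates the
piecewise-linear-in-z profile exactly over a slab measured down from the
*instantaneous* surface — top 1 m, top 2 m, or bed-to-surface — the three
assumptions about the unobserved vertical distribution of fish; slabs
thicker than the local water column truncate at the bed. Horizontal and
temporal lookups are trilinear. Vorticity ω_xy = ∂v/∂x − ∂u/∂y uses
central differences with default spacing h = 2 m (the lateral grid scale)
over the slab-averaged field; any dry stencil point rejects the sample
(no one-sided fallback).

Tracks become segments between consecutive fixes no more than 4 pulse
intervals (20 s) apart — longer gaps would smear velocities across missed
pings. Velocity over ground is displacement over time; the water velocity
is extracted at the segment's space–time midpoint; swim velocity is
`u_s = u_og − u_h`. Rotation into the flow frame always uses the
depth-averaged flow direction, for all three vertical ranges. Where the
depth-averaged flow is below 1 mm/s the frame is undefined and the record
is excluded from flow-frame statistics rather than assigned an arbitrary
axis.

Model-skill metrics follow the standard decomposition: bias
`b = <m − o>` per component and unbiased RMSE
`uRMSE = sqrt(<‖m − o − b‖²>)`, with `<‖m−o‖²> = uRMSE² + ‖b‖²` exactly.
The target-diagram abscissa is the total uRMSE signed by whether the
modeled speeds have more or less variance than the observed speeds (the
sign convention is on total variance; signing by the longitudinal
component alone would also be defensible). The mean river velocity is the
reach-scale `u_river = Q·L_a/V(stage)` with `L_a = 234 m` by default and a
monotone stage→volume table supplied externally.

## Behavioral statistics

Records are weighted by the inverse of each individual's segment count, so
a fish that lingered contributes no more than one that transited quickly;
pooling the three vertical ranges as replicates multiplies weights by 1/3,
keeping each individual's total weight at 1. The weighted median is the
smallest value whose cumulative normalized weight reaches 0.5; its 5–95%
confidence interval comes from 1000 bootstrap resamples drawn with
probability proportional to weight (count and scheme are package choices;
seeds are explicit everywhere). Kernel density estimates use a Gaussian
kernel with Silverman's rule on the weighted standard deviation and
effective sample size; a single-valued sample is accepted only with an
explicit bandwidth (the density is then the kernel itself). Occurrence of
positive rheotaxis is the weighted fraction of records with `u_long < 0`
(the unweighted fraction is reported alongside).

Stride analysis rebuilds segments from fix pairs (i, i+k): uncorrelated
position noise inflates *speeds* (not velocities) at short strides, so the
decline of the median speed from stride 1 to stride 8 (5 s → 40 s)
measures the noise contribution. The ground-vs-river comparison averages
each fish's downstream velocity over ground across its in-region segments,
pairs it with the time-averaged `u_river` over the same interval, and
applies a two-sided paired t-test (closed-form t CDF) with a 90% CI.
The behavior classifier (median `u_long` / median `|v_s|` against 0.05 m/s
thresholds) is a declared heuristic for labeling synthetic cohorts, not a
field-calibrated instrument.

## Synthetic scenarios

The generator emulates the study conditions: 13 receivers nominally 70 m
apart on a staggered two-row grid (exact spacing when jitter is zero),
5 s pulse-rate interval with 0.1 s Gaussian jitter, beacons every 30 s, a
separable sheared channel flow `u = U(t)·f_lat(y)·f_log(z)` (parabolic
lateral profile vanishing at the banks, log-law vertical profile over
roughness z₀ = 3 mm, optional sinusoidal tidal modulation of U), fish
integrated by fixed-step Euler at dt = 0.5 s (well under the 5 s ping
interval, keeping integration error below telemetry noise scale) with
prescribed behaviors — passive, positive/negative rheotaxis, lateral
(bank-bouncing), optionally diel-modulated — and detections built as
emission + travel time + clock offset + Gaussian noise. Sound speed
defaults to 1470 m/s (fresh water at ~15–20 °C). Arrival noise defaults
to 0.2 ms — chosen so the 1 ms RMS stopping rule is meaningful, as the
field value is not known. Clock-drift truths are piecewise linear with
knots aligned to the solver's hourly grid (model-matched recovery); real
clock drifts are smooth, so on field data the representation error would
add to the residuals. Corruption is an in-place positive delay of
5–50 ms on 0.1% of detections (undetected multipath — the case the solver
must catch); detected multipath echoes (duplicate rows) are generated
separately via `dup_frac` for the dedupe rule. Detection probability is a
flat 0.7 per receiver per ping, a plausible figure for a noisy shallow
channel; the generator does not model range-dependent detectability,
correlated noise, position-dependent multipath, or receiver outages, so
passing recovery tests demonstrate algorithmic correctness, not robustness
to every field pathology.

## Problem sizes and determinism

The standard verification scenarios are one simulated day of beacon
traffic (~340k detections, ~340 corrupted) for synchronization and a
90-minute, 30-fish cohort (10 passive, 10 rheotaxis at 0.10 m/s, 10
lateral at 0.09 m/s) for full-pipeline recovery; both complete in well
under a minute each on a single core. All stochastic outputs are
bit-reproducible under a fixed seed: generators derive every draw from
`numpy.random.default_rng(seed)`.

## Known limitations

- Per-ping multilateration discards the track-continuity information a
  whole-track maximum-likelihood solver would exploit; two-receiver pings
  are therefore never located.
- The vertical coordinate of fish is assumed, not estimated; the three
  vertical-range variants bracket, but do not resolve, the resulting
  uncertainty in swim velocity.
- The synthetic flow field is separable and single-channel; junction
  hydraulics, secondary circulation, and wetting/drying are not modeled.
- GAM fitting on the exported covariate table is intentionally external;
  the package stops at the covariate/weight table.
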