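# Methods

This note documents the models, conventions, and design decisions behind
`ofmap`, in the order the pipeline runs.

## Session model

A session is habituation (no shocks) followed by conditioning (one 2-s
shock per 10-s cycle). Defaults: 300 s + 600 s, behavior video at 7.5 Hz
(6750 frames), calcium imaging at 25 Hz (22,500 frames), a 320 × 240 px
arena. All freezing, event-rate, and indicator signals live on a shared 2-s
grid (450 chunks; 300 in conditioning). The shock indicator concatenates
one 1 and four 0s per cycle — 60 ones in 300 conditioning chunks. The first
shock fires at the first second of conditioning; the pre-shock window of
cycle 1 therefore uses the last 2 s of habituation (configurable exclusion
of cycle 1 is deliberate future work, not implemented: the window exists in
every session the layout admits).

## Pose post-processing (`tracking`)

Coordinates follow the video-pixel convention: origin top-left, y grows
downward, frames 0-based. The chain is (1) temporal median filter (default
window 5 frames — the filter is named by the upstream tracking convention
but its width is not; 5 is the smallest window that kills single-frame
glitches without rounding 2-s-scale motion), (2) linear interpolation of
samples with tracking likelihood < 0.999 between nearest confident frames
(edges hold the nearest confident value; a point confident in zero frames
is an error), (3) a geometric restriction: the tail root cannot render
below the back center, so tail-root y is clamped to back-center y where it
exceeds it. Filter-then-interpolate is the default order; the alternative
is exposed because the upstream order is unknowable from the data.

Per-bout speed sums *absolute* frame-to-frame back-center x-differences: a
signed sum cancels under oscillation and cannot represent speed. The signed
variant remains available as a flag.

The freezing proxy (mean 13-point inter-frame displacement thresholded,
with a minimum-duration rule, expressed as per-2-s-chunk rates) exists only
so sessions without an external freezing trace run end-to-end. An external
trace always takes precedence.

## Behavioral atlas (`mapping`)

Bout features are raw allocentric coordinates, not egocentric ones: the
behavioral categories of interest include *where* the animal is (near or
far from the demonstrator), which egocentric features destroy. Feature
dimensionality obeys D = 26 × frame rate × bout duration (1950 / 390 for
10-s / 2-s bouts at 7.5 Hz).

Embedding: Barnes–Hut t-SNE, perplexity 30, angle 0.5, random
initialization under a fixed seed, no PCA pre-reduction. At least
3 × perplexity bouts are required. Iteration count (1000) and learning rate
("auto") are exposed; they are implementation details the method does not
pin down.

Clustering: a Gaussian KDE (Scott's rule × a configurable multiplier,
default 1.0) is rasterized on a 512 × 512 grid over the 5%-padded bounding
box; density below 10⁻⁶ of the maximum is flattened to zero so
floating-point noise in the empty background cannot seed basins; the
watershed transform of the negated density floods from connected plateaus
of density maxima. With `watershed_line=False` every grid cell belongs to
exactly one region, so no ridge-cell tie-break is needed. Cluster count is
bandwidth-dependent by nature; the default multiplier 1.0 recovers the
eight planted modes of the synthetic reference cohort most faithfully
(adjusted Rand index against ground truth, 8–11 regions across seeds).

2-s bouts are split at a 50% freezing threshold into mobile and immobile
sets before embedding; a bout exactly at 50% counts as mobile (strictly
greater means immobile).

Atlas positioning: per new bout, Pearson correlation against every
reference bout; the k = 10 highest (ties at rank k all included) vote by
coordinate-wise median of their embedding positions; the label is the
watershed region containing that median, which always lies inside the
neighbors' bounding box. Constant feature vectors have undefined
correlation and are labeled unassignable (0).

## Sequence statistics (`stats`)

Permutation conventions, used everywhere: one-sided
p = (1 + #{null ≥ obs}) / (n_perm + 1); two-tailed
p = 2 · min(P(null ≥ obs), P(null ≤ obs)) with the same smoothing, clipped
at 1. P-values therefore live in [1/(n_perm+1), 1]. On small discrete
counts the two-tailed convention is conservative (ties inflate both tails);
measured false-positive rates of the transition and proportion tests on
null data are ≈ 0.02 at nominal 0.05. This is a property of the convention,
not a defect; the calibration suite asserts validity (FPR ≤ nominal + 3
binomial SD) for these two and the full two-sided band for the
continuous-statistic tests.

Transition test: the null shuffles each mouse's within-period sequence
(composition preserved, order destroyed). A degenerate sequence (constant
labels) is invariant under this null, so its p is 1 — correctly
unrejectable. Because planted persistence *depletes* off-diagonal
transitions, directional summaries use enrichment = significant AND
observed > null mean.

Markov orders: order-m predictors use maximum-likelihood transition
frequencies with modal prediction (ties → smallest label); unseen histories
fall back to order m−1 recursively. Default evaluation is in-sample — the
comparative convention, whose accuracy is non-decreasing in order by
construction — with `evaluation="loo"` (tables pooled over the other mice)
available when out-of-sample calibration matters: under LOO, IID sequences
show no spurious order gains. Adjacent orders are compared by paired
t-tests across mice at 0.025/5 = 0.005.

Side preference: near/far are the closest and farthest of five equal
x-divisions of the arena; adjusted count = conditioning − 2 × habituation
frames, which is exactly zero in expectation for any time-homogeneous
occupancy (600 s = 2 × 300 s). The perspective "pseudo-length" floor
correction used with real camera geometry is out of scope for synthetic
arenas and not implemented; compartments are computed on back-center x.

## Calcium events (`events`)

An event is one peak per contiguous excursion of the ΔF/F trace strictly
above mean + 2.5 SD of the cell's full-session trace (peak-per-excursion
resolves the ambiguity between amplitude crossings and discrete events in
favor of events, which is what the downstream counts mean). SD is computed
over the whole session, events included; a median/MAD alternative exists
but is off by default since no baseline rule is given by the method.
Thresholding in per-cell SD units makes detection invariant to affine
rescaling of a trace. Bins are half-open [2k, 2k+2) s, so binning conserves
total event counts exactly. Z-scored traces (per-cell mean 0, SD 1) feed
only shock-triggered averages; all correlation statistics use event rates.

## Neuron annotation (`annotation`)

Circular-shift null: each permutation draws ONE frame-resolution shift
uniform on [1, n_frames−1] and rotates every cell's event train by it (the
cells of a session share the recording, hence the shared shift). Rotation
preserves each cell's event count exactly. The statistic is the cell's
event count inside the target cluster's bouts; clusters occupying ≤ 1% of
bouts are untested; Holm–Bonferroni runs within cell across its tested
clusters (at most 8), one-sided at 0.05 — only activation is tested, since
that is what the statistic measures. Zero-event cells are untestable.

Shock response: per cell, paired two-sided t-test across the 60 (pre,
post) window means; sign of the mean difference sets activated/suppressed
at p < 0.05. Freezing correlation: Pearson, two-sided, classes at p < 0.01.
Shock correlation: Pearson r of the 300 conditioning-chunk event rate
against the indicator; cells with zero conditioning events are excluded
rather than given a degenerate r.

Spatial clustering: observed mean pairwise centroid distance of an
annotated group vs equally sized random subsets (10,000 draws), one-sided
toward small distances; across mice, a paired t-test of observed vs
null-mean distances.

## Decoding (`decoding`)

Feature rows are bout-major, cell-major within a row (cell 0's five bins,
then cell 1's, …). Median-split freezing labels break ties by stable bout
order so the split is always 45/45. Cross-validation draws a fresh random
partition of the 90 bouts into 10 folds of 9 per repeat; features are
standardized on each training split only; the base learner is an
L2-regularized linear SVM with C = 1 (unstated upstream; exposed).
Multiclass uses one-vs-all coding with highest-margin aggregation. The
label null circularly shifts the bout-label sequence by a random offset in
[1, 89] — the stricter null that preserves label autocorrelation — and
re-runs cross-validation with a reduced repeat count per shuffle (default
10, configurable; re-running the full repeat budget inside every shuffle is
quadratic cost for no inferential gain).

## Synthetic sessions (`synthetic`)

The generator's defaults are the study conditions. Latent modes: 8, two
locomotor (4 px/frame random-walk scale) and six near-stationary (0.5
px/frame) anchored at distinct arena positions; self-transition 0.5 in
habituation and 0.9 in conditioning (repetition increases under threat);
modes operate on the 2-s grid so that 10-s bouts mix components, as the
finer-grain analysis expects. Pose: a rigid 13-point skeleton rides a
mean-reverting random walk toward the active mode's anchor, plus 1.5 px
Gaussian jitter per point per frame; during the 2-s shock phase the step
scale is boosted 3×, so motion rises and freezing dips at shock timing (the
observer's startle/escape response; the response latency is exposed as a
parameter since it is not a measured constant). Freezing is a deterministic
decreasing map of 2-s motion energy, freezing = exp(−motion/1 px·frame⁻¹),
computed on a 5-frame boxcar-smoothed back-center path so tracking jitter
does not mask true locomotion — behavior and freezing are mutually
consistent by construction, as they are when freezing comes from video
motion.

Calcium: per cell, an inhomogeneous Poisson event train at 0.2 events/s,
multiplied by the modulation depth (default 5) when the cell's class
covariate is active — the shock chunk (shock-activated; divided instead for
shock-suppressed), the freezing rate (freezing-positive; its complement for
freezing-negative), or occupancy of one latent mode (cluster-specific) —
convolved with a 1-s exponential kernel and summed with 0.05 SD Gaussian
noise. Classes are disjoint (10% each by default, remainder background)
and recorded as ground truth, along with planted event times and latent
modes. Centroids are uniform over a 300-px field of view, optionally
contiguous per class for spatial-clustering tests.

What the generator does **not** emulate: real posture dynamics within a
mode (the skeleton is rigid), tracking failures (likelihoods are 1, so the
interpolation path is exercised by dedicated fixtures instead), slow
calcium drift and neuropil contamination, demonstrator behavior beyond the
shock indicator, and overlap between tuning classes (real populations
overlap; disjoint classes make sensitivity attributable). Passing tests
therefore certify the *analysis machinery* — calibration, recovery,
conventions — not biological realism of the inputs.

Detectability notes, measured by forward simulation: at the default depth
5 the planted classes are recovered at ≥ 0.95 sensitivity except
shock-suppressed cells (0.70), whose detection is information-limited —
silencing a 0.2 events/s baseline leaves ~0.4 expected pre-window events to
lose; depth 8 (rate × 1/8) brings suppression recovery above 0.95, and the
large-amplitude recovery checks use that condition.

## Numerical conventions and degenerate inputs

Zero-variance traces yield no events; zero-SD cells are excluded from
z-scoring; constant pre/post differences give "ns" rather than an undefined
t; zero-variance rate vectors give undefined (NaN) correlations and "ns"
classes; degenerate permutation nulls give p = 1. All stochastic stages
draw seeds deterministically from a single global seed via SHA-256 of
(seed, stage name), keeping every derived seed below 2³¹.

## Problem sizes used in tests

The test and acceptance runs use the full 900-s session layout throughout;
cohort sizes are 13 mice for the reference atlas (1170 bouts, the study
scale) and 2–4 mice elsewhere; permutation counts are reduced to 200 in
calibration suites (with p-value granularity accounted for) and 100–500 in
planted-effect checks; decoder calibrations use 19–100 shuffles with 1–2
cross-validation repeats per shuffle. These sizes were chosen so the whole
suite certifies calibration at useful precision while remaining a
desk-scale computation.
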