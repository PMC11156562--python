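# Methods

`gazerf` analyzes feature-selective neuronal responses recorded while a
subject freely views natural images: it detects fixations and saccades
from the eye trace, measures how consistently single units respond when
gaze returns to the same image location, estimates response latencies from
those consistency curves, quantifies face selectivity with saccade-matched
controls, and infers spatiotemporal receptive fields (RFs) with
image-computable encoding models. A synthetic-session generator with
ground-truth retinotopic responses closes the loop: every estimator is
validated by recovering known parameters end to end.

## The self-consistency readout

During free viewing each fixation is a single trial. If a unit responds
selectively to the retinotopic stimulus, two fixations that land within a
small distance of the same image location ("return fixations") should
evoke similar responses. Self-consistency is the Pearson correlation *r*
between the earlier and later member of each return-fixation pair, taken
across pairs, using per-fixation (non-averaged) firing rates. All
between-fixation geometry is computed in image coordinates (screen
position minus the presentation's image center), because the image is
shifted on the screen between presentations.

* Pairing rules: `current_return` (same image, centroid distance ≤ 1 dva
  by default, within or across presentations), `previous_return` (the
  immediately preceding fixations form a current-return pair),
  `same_image` (any same-image pair), `distant` (> 8 dva apart).
* Decorrelation: consecutive fixations are close in space, so a pair can
  inherit correlation from its neighbors. Pairs whose *nonpaired*
  neighboring fixations (preceding fixations for current-return pairs,
  following fixations for previous-return) are within 4 dva of each other
  are flagged out. Pairs whose member is a zeroth fixation (image onset to
  first saccade) have no preceding fixation and are kept.
* Windows and bins: fixed windows use the 150–200 ms following each
  unit's latency; time courses use 50-ms bins in 25-ms steps (−200..300 ms
  around fixation onset; −375..375 ms around saccade onset);
  presentation-time curves use 200-ms bins in 50-ms steps, pairing two
  repeats in a bin whenever any two fixations overlapping that bin satisfy
  the rule.
* A unit counts as visually selective when current-return *r* ≥ 0.1 with
  permutation *p* < 0.01.
* An *r* is invalid with fewer than two pairs or a zero-variance margin;
  invalid values propagate as NaN, never as errors.

## Event detection

Detection follows the ClusterFix recipe: the within-presentation trace is
averaged into 30-Hz frames; distance, velocity, acceleration and angular
velocity per frame are clipped at 3 s.d., standardized, and clustered with
k-means (k = 2, fixed); the lower-velocity cluster is "fixation".
Because 33-ms frames are coarse relative to 50-ms saccades, each detected
saccade's boundaries are then refined at the native rate: within the
saccade's frames ± 1, the saccade spans the contiguous run of smoothed
speed above 25% of the local peak, expanded outward from the peak sample.
On simulated sessions this recovers every non-truncated fixation with a
median onset error under 5 ms. A trace whose total excursion is below
0.1 dva is a single fixation (k-means is undefined on pure noise). Valid
fixations last ≥ 100 ms and have centroids inside the image.

k = 2 is a deliberate simplification of ClusterFix's adaptive cluster
count; it is adequate for fixation/saccade segmentation without smooth
pursuit or blinks, which the generator does not produce.

## Latency estimation

The fixation-onset latency is the bin center nearest a central time
(default 0) at which the current-return self-consistency curve first
exceeds the previous-return curve (both decorrelated), scanning upward
crossings of the difference; no sign change anywhere means no estimate. A
crossing seeds lower levels of the recording hierarchy (array → bank →
electrode → unit) as their central time, but only when no other crossing
lies within 100 ms. Uncertainty comes from 200 bootstrap resamples of the
pairs; even-indexed replicates drive selection (s.d. < 25 ms), odd-indexed
replicates provide the reported s.d. The bootstrap split by replicate
parity is our choice; the selection/report split itself is part of the
procedure. Image-onset latency uses zeroth fixations only, paired under
the current-return rule (1-dva threshold by default, relaxable — zeroth
fixations are scarce in short sessions), anchored to image onset, with
latency at the half-peak upward crossing nearest the central time;
zero-variance bins (before any visual drive) count as r = 0 in that scan.

Missing estimates are imputed down a cascade — same electrode, same array
within session, same array across sessions, then per-area defaults
(40/40/50/65/80/100 ms for V1/V2/V4/PIT/CIT/AIT) — and all latencies are
floored at 40 ms. Imputed, default and clipped values carry provenance
labels and are excluded from distribution summaries.

## Face selectivity

A fixation is a face fixation for a unit when the disc of radius one RF
s.d., centered at fixation + RF-center offset, intersects a face ROI
(axis-aligned rectangles; the disc–rectangle test is exact). Nonface
fixations are counted only on images containing at least one face. The
face-selectivity index is FSI = (a − b)/(a + b) over mean face and nonface
responses in the 150-ms window after the unit's latency; face fixations
that are targets of face-to-face saccades are excluded from *a*
(adaptation). Face neurons have zeroth-fixation FSI ≥ 0.2, i.e., at least
50% higher face responses. Saccade-category time courses
(face→face … nonface→nonface) are min–max normalized per unit across the
four curves jointly. Matched-saccade tests pair each nonface→face template
with an unused nonface→nonface saccade on the same image starting ≤ 1 dva
away and ending ≥ 4 dva away (greedy in template time order, smallest
start distance first, ties to the earlier candidate): rank-sum for the
unmatched comparison, signed-rank for the matched pairs, FDR-corrected
across units and bins jointly.

## Encoding models and RF inference

Responses are modeled as a ridge readout (α = 10⁵ by default, the value
appropriate for high-dimensional feature banks) of a fixed patch
representation, fit with five-fold cross-validation grouped by image so no
return-fixation pair straddles train and test. Features are z-scored per
dimension on the training folds. Model performance is the Pearson
correlation between predicted and held-out responses, **averaged over
folds**: at the sample sizes this package targets, pooling predictions
across folds before correlating is dominated by anti-correlated
fold means (image-level rate differences), to the point of reporting
r ≈ −0.36 on fits whose per-fold r is +0.85. Ceiling normalization
divides model performance by the same-window return-fixation
self-consistency (excluded when ≤ 0), clips to [0, 1] and squares.

RF mapping proceeds in two stages on a fixation-anchored 15 × 15 offset
grid (−7..7 dva, 1-dva steps, 2 × 2-dva patches at 0.5-dva spacing,
gray-padded beyond the image). Stage 1 fits an independent readout per
offset per split. Stage 2 regularizes: per split, the weights from the
peak-performance offset (peak of the *training-side* performance, keeping
CV hygiene) project every offset's features to a scalar preference per
held-out fixation, and the map value is the correlation of that scalar
with held-out responses — a reverse-correlation-style map. Maps are
clipped at 0 and squared before an elliptical-Gaussian least-squares fit
(analytic Jacobian; two starts, at the map peak with moment-based widths
and at the grid center; a ≥ b enforced by axis swap). RF size is
FWHM = 2.355·√(ab). Coverage is the fitted density's mass inside the
mapping window (numeric integration on a 141² grid). Reliable fits
require peak unnormalized performance ≥ 0.2, goodness-of-fit ≥ 0.7 and
coverage ≥ 0.5. Cross-split RF evidence fits the Gaussian on one split's
processed map and correlates its surface with each other split's map,
averaged over all directed pairs.

Saccade-aligned analyses repeat the chain with features anchored to the
pre-saccadic fixation point (FP1), the post-saccadic point (FP2) or their
Euclidean midpoint, each 50-ms bin modeled independently. The joint
("normalized-saccade") map instead samples single patches at relative
positions −0.5..1.5 along each saccade (≥ 2 dva amplitude), **offset by
the unit's RF center** so positions 0 and 1 sit on RF1 and RF2, and
reports stage-1 performance per (position, time). Match-saccade controls
predict match-saccade responses from features along the original
(template) saccade; the residual RF1 mismatch is corrected by linearly
mapping the match-RF1 grand-average curve onto the original-RF1 curve and
applying the same slope/intercept to match-RF2.

## Statistics

Population tests weight monkeys equally: statistics (real or permuted)
average over neurons per monkey, then over monkeys. The permutation unit
is the fixation pair for self-consistency statistics (partners
reassigned) and the values otherwise; p-values use the add-one
convention, p = (1 + #{permuted ≥ observed})/(1 + n), with 10,000
permutations by default. FDR control is the two-stage
Benjamini–Krieger–Yekutieli step-up procedure (stage 1 BH at q/(1+q),
stage 2 BH at q/(1+q)·m/m̂₀), implemented literally and cross-checked in
the tests against an independent reference implementation. Spread of
population centers comes from a hierarchical bootstrap: monkeys resampled
with replacement, then neurons within each sampled monkey (1,000
replicates). Monkeys contributing fewer than 5% of the median neuron
count in a region are excluded from that region's summaries. Rank tests
are Mann–Whitney U (unpaired) and Wilcoxon signed-rank (paired), exact
for small tie-free samples.

## The synthetic-session generator

The generator is first-class, tested code that defines the conditions the
validation suite runs under.

* Gaze: fixation durations lognormal with mean 276 ms, s.d. 49 ms;
  saccade durations normal 50 ± 5 ms and amplitudes normal 5.4 ± 0.9 dva
  (resampled at the positive support); minimum-jerk saccade trajectories;
  1.5-s presentations of 16 × 16-dva images in reshuffled blocks; image
  center shifted uniformly within ± 2 dva per presentation; 250-ms
  inter-trial travel; white tracker noise of 0.02 dva s.d. Lognormal and
  truncated-normal families are our choice (positive support matching the
  stated mean ± s.d.); so are the shift range, interval and noise level,
  picked once as typical for this preparation.
* Return fixations: with probability `p_return` = 0.3 a saccade targets a
  previously visited location on the current image (any repeat), chosen
  as the visited location whose distance best matches the drawn saccade
  amplitude (keeping amplitude statistics honest), plus Gaussian jitter
  of 0.3 dva s.d. Zeroth-fixation targets are always fresh.
* Images: mixtures of band-passed noise with smoothly varying mixing
  weights, so local patch statistics differ across locations; a fraction
  carry one or two ring-and-dots "face" patterns with stored bounding
  boxes, drawn at contrast comparable to the texture so they do not stand
  out to low-level statistics.
* Responses: the RF is discretized into 2-dva offsets with Gaussian
  weights truncated at 2σ and normalized to sum 1; the drive at each
  1-kHz eye sample is the weighted sum of cached patch features
  (one channel of a seeded random-projection extractor) at
  eye + RF center + offset, sampled **bilinearly** so the response is
  continuous in eye position — a nearest-cell lookup would make the
  ground truth a step function of gaze, which no neuron is. The output is
  delayed by the response lag. Optional: min–max drive normalization
  (used by presets that need non-negative rates), rectification,
  within-presentation exponential adaptation (off by default — the
  reference condition is deterministic and adaptation-free), Poisson
  spiking, and a face gain boost (× 3) applied whenever a face ROI
  intersects the 1-σ RF disc.
* The simulation extractor (random projection of downsampled patch
  pixels) is deliberately different from the analysis extractor (Gabor
  bank with local luminance structure), so encoding models cannot fit
  trivially. Projection weights are point-symmetrized within the patch;
  otherwise each channel's spatial weight centroid sits up to ± 1 dva off
  patch center and displaces cross-extractor RF estimates by up to
  ~2.5 dva — an effect pretrained-network channels share, but which RF
  validation must not conflate with estimator error.
* Presets: `noiseless-retinotopic` (lag 0, deterministic rate traces),
  `lagged-L` (e.g. `lagged-100`), `poisson` (lag 100 ms, spiking),
  `face-selective` (lag 50 ms, half the units boosted). Default scale:
  30 images, 150 presentations, 8 units spread over 2 arrays × 2 banks,
  RF centers within ± 2 dva and σ ∈ {1, 2} dva, one feature channel per
  unit. A 150-presentation session yields roughly 750 valid fixations and
  600 usable saccades; validation problem sizes (e.g., 100 presentations
  for latency recovery, 500–1,000 replicates for calibration checks) were
  chosen so the full suite runs on a single CPU in a few minutes.

What the generator does **not** emulate: microsaccades, smooth pursuit,
blinks, eye-tracker lag, firing-rate drift and adaptation across a
session, correlated noise between units, and natural-image statistics
beyond second-order texture. Passing tests therefore demonstrate that the
estimators recover the quantities they claim under the model's own
assumptions — retinotopic, feature-selective, lag-delayed responses — not
that real cortical data satisfy those assumptions.

## Numerical choices and degenerate inputs

* Pearson computations guard zero variance and < 2 samples by returning
  NaN with a validity flag.
* Ridge solves are direct batched linear solves on standardized features
  (float32 accumulation, float64 solve); equivalent to scikit-learn's
  ridge on the same standardization (checked in tests).
* α = 10⁵ is kept as the default for fidelity to its published use with
  3,072-dimensional features; with the built-in low-dimensional banks it
  acts as strong shrinkage, which correlation-based performance measures
  tolerate. The realizable-target test passes a smaller α through the
  documented config.
* Pair ordering is chronological (earlier fixation first); pairs are
  unique and unordered.
* Greedy saccade matching breaks ties by earlier candidate onset.
* Gaussian-fit failures, empty bins, and windows beyond the recording all
  degrade to flagged-invalid values rather than exceptions.

## Known limitations

* Single-session focus: multi-session imputation stages collapse when a
  `session` column is absent.
* ROI geometry supports rectangles only; polygon ROIs would need a
  rasterized intersection.
* The NWB read adapter mentioned as optional in the session layout is not
  included; the text + HDF5 session layout is the supported interchange.
* The presentation-time self-consistency pairs bins across repeats only;
  within-presentation bin pairing is not implemented.
* FDR families are per analysis call; callers combining analyses must
  manage the family themselves.
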