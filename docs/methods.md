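# Methods

This note documents the models, estimators, and numerical choices behind
`rampfix`, what the synthetic-data generators do and do not emulate, and the
known limitations of the procedures.

## Behavior segmentation

Eye position is median-filtered with a centered window corresponding to
500 ms at the native sampling rate (order forced odd).  Velocity is the
forward difference of the filtered position divided by the sample interval;
no resampling happens before detection.  The saccade threshold is
`max(mean(|v|) + 3·SD(v), 10°/s)`: the literal reading of the mixed
mean-absolute/standard-deviation rule, with the 10°/s floor dominating on
quiet traces.  A run of consecutive supra-threshold samples is one event,
timed at its first sample; its amplitude is the filtered-position change
across the run.  Events within 1.4 s of the previously accepted event are
discarded — the *later* event of a close pair, since the first threshold
crossing of a movement is the saccade and trailing crossings are
body-movement artifacts.

Two small biases follow from these definitions and are visible in the
synthetic runs: the run-based amplitude slightly underestimates the true
step size (edge samples of the transition can fall below threshold; the
bias is ≈5–8% at 13 Hz), and detected onsets are quantized to one sample.
Both affect the printed amplitude medians but not fixation durations.

The PSD uses Welch's method after linear-interpolation resampling to the
median sampling interval; the summary reports the frequency below which a
given fraction (default 95%) of non-DC power lies.

## Imaging preprocessing

Frames register to the per-pixel temporal median of the stack by the peak of
the Fourier-domain cross-correlation (integer shifts by default; subpixel
refinement is available via the upsample factor but off, since integer
precision suffices for the QC rule).  The per-frame error is
`sqrt(1 − r)` with `r` the normalized correlation of the registered frame
against the reference; a zero-variance frame gets the maximal error 1.  A
frame is corrupted iff its error strictly exceeds `median + 5·MAD`, where
the MAD is the raw median absolute deviation without the 1.4826 consistency
factor — the rule as stated, not a calibrated Gaussian test.

Nuclei detection opens the time-averaged image with a 4-px disk, finds
regional maxima (connected equal-intensity plateaus exceeding all boundary
neighbors, 8-connectivity, one detection per plateau at its center of mass),
and discards plateaus larger than 144 px², the upper bound on typical
nucleus area.  The rule has no intensity-prominence criterion, so on noisy
integer images small background plateaus can be reported; scoring against
ground truth therefore uses matched pairing.  Note the opening erases
bright regions that cannot contain the structuring element, so detectable
nuclei must be at least as large as the 4-px disk.

The exponential-decay fit `A·exp(−t/τ) + b` fixes `b` to the mean of the
1–2 s pre-saccade baseline and minimizes squared error over the post-saccade
samples with bounds `τ > 0`, `A > b` (L-BFGS-B).  Cells are accepted at
`r² > 0.8` and the kernel time constant is the median τ over accepted cells;
the default generator value is τ = 1.3 s.  Affine point registration solves
`y = T·x + T₀` by least squares on homogeneous coordinates and requires at
least four non-coplanar correspondences.

## Saccade-triggered averages and the functional map

STAs live on a fixed grid of 31 bins, 1/3 s apart, spanning ±5 s around the
saccade.  A saccade qualifies only when both flanking fixations last at
least 5 s; trials whose window leaves the recording or touches masked
samples are dropped, and a direction needs at least five trials to be
eligible.  Confidence intervals are a 100-resample bootstrap over trials
(0.025/0.975 quantiles), seeded.

Screening runs a one-way ANOVA per direction with the 31 bins as groups and
trials as replicates.  This deliberately ignores within-trial
autocorrelation — the bins of one trial are not independent — so the
nominal p-values are approximate; the family-wise simulation in the test
suite shows the Holm-corrected decision is nevertheless conservative at the
1% level on white-noise nulls.  Holm–Bonferroni uses thresholds
`α/(N − j + 1)` on ascending p-values with `N = 2 × n_cells` and stops at
the first failure; untestable (NaN) members count toward `N` but are never
rejected.  Before testing, cells whose peak |STA| falls in the dataset's
bottom 1% are dropped as near-silent; datasets with fewer than 100 eligible
cells fall back to an absolute floor (default 0.14 dF/F, the scale of the
original recordings; pass 0 to disable on other scales).

PCA operates on L2-normalized STA rows.  Component signs are fixed so each
component's largest-magnitude element is positive, making the downstream
angles reproducible across runs.  The first three coefficients,
renormalized to the unit sphere, map to latitude `Θ = arcsin(c₃′)` and
longitude `Φ = atan2(c₂′, c₁′)` in (−180°, 180°]; the two-argument
arctangent is required for the anchor cases ((1,0,0) → (0°, 0°),
(0,1,0) → (90°, 0°), (0,0,1) → Θ = 90°) to hold in all quadrants.
Φ-binned population averages use *non-normalized* STAs and half-open 15°
bins.  K-means runs for K = 2…10 (best of `restarts` initializations) and
selects K by mean silhouette `(b−a)/max(a,b)`.

## SR cells and the ramp-to-threshold model

SR selection correlates dF/F with time relative to the upcoming saccade
(negative, increasing to zero) per direction, one-sided for rho > 0, over
all samples of pre-saccadic fixations excluding the first 2 s after the
previous saccade (post-saccadic decays would otherwise mimic negative
correlations).  Ties get average ranks; p-values use the large-sample
approximation, adequate at the hundreds of samples involved.  Holm runs
over `2 × n_cells` comparisons at α = 0.01; cells significant in both
directions are flagged bidirectional and excluded downstream.

Rise onset within a fixation is the last sample before deconvolved activity
first exceeds a near-zero threshold.  On the original recording scale that
threshold is 0.1 (arbitrary units); for generator-scale data, thresholds
are expressed as fractions of the ramp bound κ (0.05·κ in the tests).  The
slope is the ordinary least-squares line from onset to saccade; events
whose fit correlation is ≤ 0.4 are excluded.  The activity "reached at the
saccade" is the last sample at or before it — interpolating across the
post-saccadic reset would bias κ low.  At ~1 Hz calcium sampling the onset
is quantized to about one sample, which slightly inflates measured rise
durations; slope estimates are unaffected because the regression points lie
on the ramp.

Choice probability at a given time before the saccade is the ROC area
(equivalently the normalized rank-sum statistic, ties counted one half)
between activity preceding preferred-direction and opposite-direction
saccades.  Pooled variants average randomly formed, disjoint groups of
`pool_size` cells with a common preferred direction per fixation, resampled
100 times; this grouping assumes the pooled cells share the fixation set,
which holds for simultaneously simulated (or recorded) populations.  The
reported SEM is across CP curves conditioned on fixation duration
(2–20 s, within ±0.5 s).

The ramp model predicts the time until saccade from population activity on
the 1/3-s grid: the rise onset (time 0) is the first finite-difference
derivative above the onset threshold; the running slope `D̃(t)` is the
median of derivatives on (0, t]; the prediction is `κ/D̃(t) − t`, reported
from one bin after onset to one bin before the saccade, undefined where
`D̃(t) ≤ 0`.  The onset threshold on the original scale is 35 (arbitrary
units per second) — about one tenth of the mean single-event slope there —
and `derivative_threshold_from_slopes` transfers exactly that ratio to any
recording by using the measured mean slope, avoiding unit assumptions.
The timing-error metric is the median of |predicted − actual| / actual in
percent; this is a convention of this package, chosen because it is
scale-free and robust to the large early-rise over-predictions that a
convex population average produces.

Ideal-observer baselines: for direction, always guessing the opposite of
the previous saccade is correct with probability `1 − p_same` (77% at the
default 23% repeat probability); for timing, the optimal guess of the
remaining time given the elapsed time is the conditional mean (MSE cost),
conditional median (MAD), or the representative value (median) of the modal
0.5-s histogram bin (all-or-none) — the last choice makes a degenerate
duration distribution predicted exactly.

## Ablation statistics

The behavioral effect of an ablation is the fractional change in median
fixation duration, computed on repeated equal-size resamples: `N_min` is
the smallest fixation count over all animals and both conditions, each
animal contributes `round(min_i n_ij / N_min)` repeats (round half away
from zero, minimum one — an included animal must contribute at least one
measurement), and each repeat draws `N_min` durations per condition without
replacement.  With `N_min` equal to the full sample size this reduces
exactly to the plain fractional-change formula.  Animals whose post-ablation
saccade rate never strictly exceeds one saccade per direction per minute
are excluded first.

The fraction of SR cells removed by a lesion counts mapped SR positions
inside an axis-aligned cylinder (30 µm radius in the rostral–caudal /
medial–lateral plane, 60 µm along the dorsal–ventral axis) after
subsampling each map point with probability 3 / (fish sampled at that
location), correcting for unequal regional coverage.

Effect-vs-fraction correlation repeats the whole resampling 100 times per
sample-size floor (55…175 by 10, recomputing `N_min` after dropping animals
below the floor), compares the resulting Pearson coefficients against
shuffled-effect controls with a one-sided two-sample KS test, and applies
Holm over floors at α = 0.001; the summary is the mean over floors of the
per-floor median correlation.  A caveat discovered in null simulations: the
bootstrap coefficients concentrate around the *realized* chance correlation
between per-animal effects and fractions rather than around zero, so the
KS-vs-shuffle call is anticonservative under a true null (its flag rate can
far exceed the nominal level at modest animal counts).  The procedure is
provided as specified; its p-values should be read as descriptive, and the
test suite asserts only that null correlations are centered on zero.

Targeted-group comparison resamples effects per run (default `N_min` = 33
for single-cell experiments), applies one-sided Wilcoxon rank-sum tests (SR
effects greater than control) across 100 runs, reporting the min/median/max
p, and compares each targeted group against a sham built from non-ablated
animals whose fixations are split 50/50 into pseudo before/after halves
(the split ratio is a package choice), with two-sided t tests and a
Bonferroni factor of 2.

## Synthetic data: what it emulates, and what it does not

The behavior generator produces a Markov direction sequence with repeat
probability 0.23, fixation durations from a log-normal with median 11.4 s
and shape σ = 0.636 — chosen so the 1st/99th percentiles fall near 2/50 s —
truncated to [1.5, 60] s by rejection, and amplitudes from truncated
log-normals with medians 8° (repeat) and 13° (switch), σ = 0.3, bounded to
[2°, 28°].  The log-normal family itself is a modeling choice; only the
median and extreme quantiles of the real durations are constrained.
Saccades render as linear ramps over 150 ms — sufficient for a
velocity-transient detector, with no attempt at realistic saccade
kinematics.  Eye position performs an unconstrained random walk across
saccades, so the long-run position range is broader than in a real,
mean-reverting oculomotor range.

SR cells ramp linearly within each fixation that ends in their preferred
direction, from an onset at a Beta(2, 2.5)-distributed fraction of the
fixation (median fraction ≈ 0.44, reproducing a broad normalized-rise-time
distribution and a median rise near 5 s at the default behavior), with
slope κ / rise-duration up to multiplicative noise of the configured CV, so
slope × rise-duration = κ(1 ± cv) per event by construction.  The onset law
is a stand-in: the true generative relation between rise onset and fixation
duration is unknown, and only its qualitative breadth is reproduced.
Fluorescence is the deconvolved trace passed through the discrete AR(1)
equivalent of an exponential kernel (τ = 1.3 s) plus a baseline and white
Gaussian noise; real indicator nonlinearities, bleaching, and neuropil
contamination are not modeled, so passing tests demonstrate estimator
correctness under the assumed forward model, not robustness to those
effects.  Archetype cells are idealized templates (step, impulse,
impulse+step); frame stacks are rigid translations of a base image with
optional per-row shear "corruption"; intensity images contain hard-disk
nuclei (default radius 5 px) on a constant background, rounded to integer
gray levels as TIFF averaging would produce.

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each take
well under a minute of compute: behavioral sessions of 2,000–20,000 s
(hundreds to ~1,500 fixations), 8-cell SR populations, 200 traces per
fixation duration for the ramp analysis (comparable to the per-duration
fixation counts in real datasets), 400–1,000 null families for the
screening calibration, and 100 resampling runs for the ablation statistics.
All randomness flows through explicit integer seeds, and every generator is
bit-reproducible given its configuration and seed.
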