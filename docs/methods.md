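# Methods

This note documents the models, conventions and numerical choices behind
`retrogaze`, in the order data flow through the pipeline.

## Task model and coordinate conventions

Two memory items are encoded on one axis (vertical or horizontal) at 4°
eccentricity and tested on the orthogonal axis. A session-wise *future
rule* maps each encoded location to its test location; four rules
counterbalance the geometry (rule 1: top→right, bottom→left; rule 2:
top→left, bottom→right; rules 3/4 mirror this for horizontal encoding,
fixed here as left→top/right→bottom and left→bottom/right→top — the
horizontal assignments are a design choice and are configurable, since
only the counterbalancing matters). Gaze is expressed in visual degrees
with the fixation dot at the origin, x rightward and y upward; saccade
direction is the planar angle of the displacement, 0° = rightward,
counter-clockwise positive. Pixel-to-degree calibration is an input
preparation step outside the pipeline.

## Preprocessing

Blinks are recorded by the tracker as clusters of exactly-zero samples on
both channels; every maximal zero cluster, expanded by 100 ms on each
side, is set to missing (a `zero_tol` flag covers re-quantised data).
Padding is applied on the continuous recording before epoching, so a
blink near an epoch edge masks into the epoch regardless of trial
boundaries. Epochs run from −1000 to +2000 ms around cue onset,
endpoints inclusive. The per-trial fixation reference is the
component-wise median of non-missing gaze in −800…−200 ms; trials
without a usable reference are dropped with a logged reason, never
imputed.

## Gaze-shift detection

Speed is the Euclidean distance between successive samples (deg/sample);
the threshold is 5× the per-trial median of the smoothed speed, so the
deg/sample vs deg/s choice cancels. Smoothing is a Gaussian-weighted
moving average over 7 samples with kernel sd = window/5, truncated and
renormalised — the default convention of the common smoothing routines —
and omits missing samples by renormalising over valid neighbours. An
onset is the first sample after an upward threshold crossing; crossings
within 100 ms of the previously accepted onset are discarded
(onset-to-onset; the offset-to-onset reading is configurable).
Magnitude and direction come from mean gaze in [−50, 0) ms vs
[50, 100) ms around onset; events whose windows leave the epoch or touch
missing data are discarded rather than interpolated. A shift is a
*start* saccade when its post-window gaze is strictly farther from the
fixation reference than its pre-window gaze (ties, a measure-zero event,
count as returns). Trials with fewer than 500 valid samples are excluded
from every denominator.

## Rate time courses

Start-saccade rates use a 50 ms window advanced in 1 ms steps,
`rate(t) = count of onsets in [t − 25, t + 25) / (n_trials × 0.05 s)`;
window centres are placed so windows lie fully inside the epoch (no
partial-window edge rates). Toward/away classification is the sign of
the displacement's projection on the fixation→target axis (hemifield
rule); exactly perpendicular shifts are excluded, not split. The
time × magnitude decomposition uses overlapping magnitude bins of 0.2°
stepped by 0.04° with lower edges up to 2.0° − 0.2° (the microsaccade
range; ceiling configurable). The pre-cue future-axis check reuses the
same machinery on the −1000…0 ms window.

## Single-saccade analysis

Per trial, the first start saccade with onset in 200–600 ms (inclusive)
enters the analysis. Its displacement is mapped by the unique orthogonal
transform taking the unit past axis to (1, 0) and the unit future axis
to (0, 1). For two of the four rules this transform contains a
reflection; it is applied silently because the analysis concerns
toward/away components, not handedness, and no pure rotation maps all
four rules to one frame. The transform uses the task-defined axes about
the screen centre (the axes of the rule geometry), not the measured
fixation reference — with a measured reference the axes would no longer
be exactly orthogonal.

Angular distributions use overlapping 20° bins stepped by 1°: a saccade
contributes to every centre within 10° circular distance (inclusive), so
proportions sum to ≈ 20 for off-boundary directions. The conditional
bias profiles are a reconstruction (only the axis assignments are fixed
by the design): the bias toward the past at angle ψ from the future axis
is `p(90° − ψ) − p(90° + ψ)`, i.e. the distribution minus its reflection
across the future axis, antisymmetric in ψ and positive toward the past;
the future profile mirrors across the past axis (`p(ψ) − p(−ψ)`).
Summed over one half-turn and divided by the bin overlap factor (20),
the profile recovers the binarised quadrant difference exactly when no
saccade lies within half a bin of the reflection axis.

The quadrant table binarises each first saccade by the sign of its
common-frame components (x > 0 toward past, y > 0 toward future);
exactly axis-aligned saccades are excluded and logged. Percentages are
computed per participant; group display is mean ± SEM.

## Statistics

*Cluster-based sign-permutation test.* Pointwise one-sample t-tests vs
zero, two-sided cluster-forming α = 0.05; clusters are maximal runs of
same-signed supra-threshold t with mass = sum of t-values. The null is
the maximum absolute cluster mass over per-participant whole-series sign
flips (equivalent to swapping toward/away labels within participant);
10 000 permutations by default, p = (b + 1)/(n + 1) so p is never zero,
and the two-sided null covers observed clusters of either sign. The
generator is seeded from the config and results are bit-reproducible.
The permutation count, not the data, limits the smallest attainable p
(with n participants only 2ⁿ distinct flips exist; group sizes below ~6
cannot reach p < 0.05).

*2×2 repeated-measures ANOVA.* Factors past (toward/away) × future
(toward/away) on the quadrant percentages; df (1, n − 1); partial
η² = SS_effect/(SS_effect + SS_error). The fit is delegated to
`pingouin.rm_anova`; the test suite checks it against an explicit
sums-of-squares decomposition and the identity interaction-F = t² of the
paired t on double-differences. Zero-variance contrasts yield a
degenerate result (F = 0, p = 1) with a warning instead of an error.
Follow-up paired t-tests (future toward vs away within each past level)
are Bonferroni-corrected (p × m capped at 1) with Cohen's
d = mean(Δ)/sd(Δ).

## Synthetic data

The generator reproduces the study structure (default 25 participants ×
4 sessions × 5 blocks × 32 trials, rules counterbalanced across sessions
with the starting rule rotated across participants) and raw-like traces:

- **Fixational jitter**: white noise low-passed by a triple box-filter
  cascade (≈ Gaussian, sd = `jitter_timescale` = 20 ms), RMS
  `noise_sd` = 0.01°. Band-limited noise is the physically correct model
  at 1000 Hz — tracker noise and tremor are correlated sample-to-sample —
  and it is what makes a median-multiple velocity threshold workable:
  i.i.d. position noise would put the median speed above microsaccadic
  peak speeds.
- **Drift**: a random walk with 0.001°/sample increments, continuous
  across each session's recording (~0.05° excursion within a trial).
- **Saccades**: raised-cosine displacement ramps over 20 ms, so peak
  velocity scales with amplitude (main-sequence-like); amplitudes
  log-normal around 0.5° (σ_log = 0.35). Baseline shifts are a 0.3 Hz
  Poisson process with uniform directions; each outgoing saccade is
  followed by a return after 150–400 ms so the start/return classifier
  has both classes. With probability 0.9 one attentional saccade occurs
  uniformly in 200–600 ms; its direction is drawn *in the common frame*
  from the mixture w = (joint 0.5, past 0.15, future 0.15, uniform 0.2)
  with von Mises concentration κ = 8 (means 45°/0°/90°), then mapped back
  through the trial's rule geometry — the ground-truth joint-bias
  structure is therefore identical across rules by construction.
- **Blinks**: 0.05 Hz, 100–300 ms, written as exact zeros, as trackers
  emit them.
- **Behaviour**: correctness Bernoulli(0.70); RTs log-normal with the
  log-mean chosen so the mean is ≈ 1218 ms (σ_log = 0.35).

`expected_first_saccade_quadrants` replays the event-level model
(baseline starts, returns, refractory, response window) without traces to
give the exact expected quadrant distribution of the first start saccade
under ideal detection; a closed-form first-order version
(`first_saccade_quadrant_probabilities`) ignores refractory
interactions. Direction-independent losses (refractory suppression,
blink-masked windows, occasional misses) do not bias the quadrant
*proportions*, which is why the recovery checks compare proportions, not
counts.

What the simulator does **not** emulate: pupil dynamics, tremor spectra,
calibration error, saccadic curvature, main-sequence duration scaling,
or any dependence of behaviour on the gaze signal. Passing tests
therefore validate the pipeline's computations and calibration, not
claims about real oculomotor data.

## Validation benchmarks and problem sizes

`retrogaze.evaluation` fixes the study conditions of each check: the
detector benchmark uses 30 quiet trials (jitter RMS 0.02°, drift off)
with 11 injected shifts each, magnitudes 0.1–1.0° at 250 ms spacing;
cluster-test calibration uses 1000 null datasets of 25 participants ×
500 time points with 1000 permutations each; the ANOVA identities use
100 random small datasets; end-to-end recovery uses scaled-down studies
of 10 participants × 160 trials (4 sessions × 40 trials), 100 studies
for the joint-bias power check and 50 for the independent-bias null.
The quadrant comparison uses per-cell t-statistics across participants
(the participant is the sampling unit of a group mean) with Bonferroni
correction over the four cells.

## Known limitations

- The conditional bias profiles (reconstruction above) have no canonical
  normalisation; only the binarised quadrant analysis feeds the
  statistics.
- The ASC reader covers sample lines only (no tracker event grammar, no
  EDF binary).
- Cluster inference is one-dimensional (time); no TFCE, no
  Greenhouse–Geisser (df are (1, n − 1) in a 2×2).
- The simulator's attentional model injects at most one cue-driven
  saccade per trial; sequences of corrective saccades are out of scope.
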