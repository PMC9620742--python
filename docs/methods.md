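# Methods

`motorpop` analyses trial-structured two-photon calcium-imaging recordings
from a head-fixed push/pull lever task: a fluorescence matrix (neurons ×
frames), a trial table (cue, movement initiation, movement completion,
outcome), ROI centroids, and a behavioural motion index.  Every stage is
driven end-to-end by a synthetic-session generator with known ground
truth, which is how the statistical procedures are validated.

## Synthetic sessions

The generator emulates the recording the analysis assumes, not pixels:

- **Task structure.** Cued push and pull trials alternate with randomised
  4–6 s inter-trial intervals; reaction times are 0.2–0.5 s, movement
  durations 0.3–0.5 s; reward follows completion after a 1 s delay.
- **Transients.** Difference-of-exponentials kernel with 0.5 s rise
  (GCaMP6s-like) and 1.5 s decay, normalised to unit peak.  The decay is
  a generator choice calibrated to typical GCaMP6s half-decay; it is
  configurable.  Per-trial onsets jitter around movement initiation
  (SD 0.05 s).
- **Classes.** `invariant_up`/`invariant_down` (equal push/pull
  responses, ±amplitude); movement-bias types per side — type 1 (both
  movements up, preferred 2×), type 2 (preferred movement up only),
  type 3 (preferred movement down only), type 4 (both down, preferred
  2×); `reward_phase` (transients 1.1 s after completion, i.e. just after
  the reward delay); `non_responsive`.  The 2-vs-3 sign convention
  (selective increase vs selective decrease) is this package's
  convention and is stamped in the class names themselves.
- **Default conditions.** 100 neurons — 60% invariant (85/15
  up/down), 15% push bias, 15% pull bias (type mix 75.1/13.8/8.3/2.8%
  within each side), 10% non-responsive — 40 trials per movement, 40 Hz,
  effect amplitude 0.5 ΔF/F₀ on noise SD 0.1 (5× noise).  These are the
  study conditions every calibration below is quoted at.
- **Signals.** Raw fluorescence is `F0·(1 + ΔF/F₀) + noise`; the motion
  index is a half-sine bump spanning initiation → completion plus
  squared-Gaussian noise (a motion index is a sum of squares, hence
  nonnegative).  Centroids are uniform over a 320 × 320 µm field of view;
  with spatial clustering enabled, bias neurons gather around
  movement-specific cluster centres (Gaussian radius 40 µm).

What the generator does **not** model: neuropil contamination, motion
artifacts, baseline drift, bursty or correlated noise, overlapping ROIs.
Passing recovery tests therefore demonstrate that the procedures are
correctly implemented and calibrated under their own assumptions, not
that they are robust to every artifact of real recordings.

The ramp calibration set for onset detection is separate: flat baseline,
linear rise of 0.5 s to a plateau, known onsets, i.i.d. noise; standard
design 100 cells × 30 trials.

## Preprocessing

- **Motion index.** Per consecutive frame pair, the sum over the forelimb
  ROI of squared grayscale differences.  Smoothing is a 1 s LOESS filter:
  locally weighted linear regression with tricube weights; windows are
  truncated at the series boundaries, never padded.  On a uniform grid
  the interior fit reduces to a fixed convolution.
- **ΔF/F₀.** F₀ is the 5th percentile of the 1 Hz low-pass filtered raw
  trace per neuron; the filter is a zero-phase second-order Butterworth
  (the cutoff is the method's defining constant, the filter family is a
  numerical choice).  ΔF/F₀ = (F − F₀)/F₀.
- **Motion-index onsets (imaging).** Threshold = upper bound of the 95%
  percentile-bootstrap CI (10,000 resamples) of the mean motion index in
  the 1.5 s pre-cue baseline; the onset is the first point of the
  supra-threshold run leading into the lever movement.  The baseline
  window is a documented choice (the ITI segment before the cue).  Note
  the 1 s LOESS smoothing leaks the movement bump backwards, so detected
  onsets lead the generator's initiation times by ~0.3 s at the default
  noise level; the lead is consistent across trials and all downstream
  epochs are defined relative to the detected onset, exactly as they
  would be on real data.  In the electrophysiology variant the threshold
  is baseline mean + 2 SD and trials whose crossing precedes the cue are
  excluded.
- **Alignment.** Slices are copied without interpolation, time zero at
  the event; trials whose window leaves the recording are flagged, not
  dropped.  Frames are 0-based, windows half-open, all times in seconds.

## Response classification

Epochs relative to motion-index onset: baseline −500…−150 ms;
peri-movement −150 ms … median completion + 40 ms (the 40 ms allows for
indicator rise).  Two independent bootstrap tests (10,000 trial
resamples):

1. **Baseline-to-peak.** For each resample, the mean of the 100 ms
   centred on the largest *absolute* deviation of the mean trace from
   baseline within the peri epoch, minus the baseline mean.  Significant
   if the 95% CI excludes 0.  Absolute deviation makes suppressed
   responses detectable; the statistic's sign identifies the direction.
2. **Binwise.** For each full 250 ms bin tiling the peri epoch, the
   bootstrap distribution of the bin mean versus the bootstrap
   distribution of the baseline mean; significant if the two 95% CIs do
   not overlap.

A neuron is responsive if either fires.  CI *non-overlap* in test 2 is a
deliberate design choice: with 2–4 bins and no multiplicity correction, a
difference-CI rule has a ~16% null false-positive rate for the combined
procedure, while the non-overlap rule keeps it near 2–5% (measured on
synthetic null neurons; the package re-measures it in its acceptance
checks).  It matches the comparison rule the electrophysiology variant
states explicitly (bias "if confidence intervals did not overlap").

Responsiveness: non-responsive if neither movement fires; reward-phase if
responsive but the median ΔF/F₀ onset falls after median completion +
40 ms; otherwise movement-related.  Bias: the same two statistics on the
push-vs-pull contrast of baseline-corrected responses (difference CI for
the peak statistic, CI non-overlap for bins); a significant contrast
assigns bias to the movement with the larger absolute response.  Bias
types: 1 both-up, 2 one-up, 3 one-down, 4 both-down; a neuron with
significant opposite signs in the two movements falls outside the
taxonomy and gets no type.  Fewer than 5 trials per movement →
unclassifiable, never guessed.

Spiking units: rates from 50 ms Gaussian-kernel convolution aligned to
the motion-index onset, baseline 1 s pre-cue, 250 ms bins to the longest
completion; responsive if any bin's bootstrap CI of the mean rate change
excludes 0; bias when push and pull CIs are disjoint in a responsive
bin.  Putative pyramidal: median spike width strictly greater than
0.4 ms.

## Onset detection (SSF)

Savitzky–Golay smoothing (27 frames, order 2), positive first
differences summed over a trailing 375 ms window.  The onset is the start
of the supra-threshold run (threshold = 10% of the SSF peak) that
culminates in the peak, walked back to the local SSF minimum.  Anchoring
at the peak's run rather than the globally earliest crossing matters:
smoothed baseline noise crosses 10%-of-peak routinely, and the position
of the earliest such crossing depends on how much baseline the trace
contains, which would make the calibration non-transferable.  The peak
search is restricted to the peri-movement window.  A trial is "missing"
when the peak fails a noise gate (baseline SSF mean + 3 SD); missing
trials are excluded from the neuron median, never imputed.  Per-neuron
onsets are the median of 10,000 bootstrap medians over trials.

The detector is biased early by the smoothing and the decision rule, so
it is calibrated on the ramp set with noise matched to the data:
correction = median(detected − true) over cells, subsequently subtracted.
At the standard design the correction is ≈ −0.1 to −0.2 s and the median
absolute error on a held-out seed is below one frame at 30 Hz.  In the
pipeline, suppressed neurons are detected on the sign-flipped trace
(the SSF tracks rising activity; on the raw trace it would date the end
of the suppression and trip the reward-phase rule).

## Decoding

**Single neurons.** At each frame of a 5 s peri-movement window,
leave-one-out Gaussian naive Bayes on that frame's ΔF/F₀: per-class
training mean and variance (variance floor 1e-6 ΔF/F₀² for degenerate
sets) and a 50:50 class prior — the task's balanced design; empirical
LOO priors would systematically penalise the held-out trial's own class
and drag null accuracy below chance.  The per-neuron epoch for
significance runs from −0.15 s to the later of the two movements' median
ΔF/F₀ peak times (peak of the across-trial median trace).  The session
threshold is the mean + 2 SD of the same LOO accuracy on 1000 simulated
label-free Gaussian datasets with the session's trial counts.  A neuron
is HDA when any 250 ms bin in its epoch has a bootstrap accuracy CI whose
lower bound exceeds the threshold (10,000 resamples, consistent with the
other bootstrap counts).

**Population.** Per frame, leave-one-out L2-regularised logistic
regression (λ = 1, intercept unpenalised, per-feature standardisation —
chosen for LOO stability with more neurons than trials) on the
population vector; the summary is the maximum bin-averaged accuracy over
non-overlapping 250 ms bins left-aligned to the epoch start
(per-frame-then-binned).  The LOO folds are fitted by batched Newton
iterations across frames × folds, which is what makes retraining-per-
removal tractable.  Chance is the 95% interval of accuracies from 1000
random time points with labels freshly permuted per sample.

**Removal curves.** Neurons leave one at a time — descending
single-neuron accuracy (ties by index) or randomly (median over 25
repetitions) — with the decoder retrained from scratch each step.
Removal evaluates the per-frame accuracy on a strided grid (every 3rd
frame) inside the epoch before bin averaging; the full-resolution grid
changes the curve by less than the trial-bootstrap CI and triples the
cost.  `proportion_to_chance` is the fraction removed when the accuracy
CI first overlaps the shuffle CI.  Sessions with fewer than 3 HDA
neurons or 10 trials per class are excluded from removal analysis.

## Trajectories and separability

Successful trials in a 7.5 s peri-movement window are concatenated,
boxcar-filtered (3 frames ≈ 75 ms), whitened per neuron (z-scoring;
full ZCA available) and decomposed with PCA; the 16 leading PCs are
analysed.  Mean per-movement trajectories carry 100-fold bootstrap CIs.

Separability per PC and frame:
`d'(t) = |m_push(t) − m_pull(t)| / sqrt(0.5 (v_push(t) + v_pull(t)))`
with trial means/variances; 400 bootstrap resamples give its variance,
and the same statistic from label-shuffled trials gives the null.  A PC
is separable when the d' − d'_shuffle difference, with a normal CI from
the summed bootstrap variances, excludes 0 inside the movement window
(onset → longest movement duration).  Because the window is scanned
frame-by-frame, the CI uses a Bonferroni-adjusted z across window frames;
an unadjusted 1.96 scan declares ~40% of white-noise PCs separable,
versus ~5% adjusted.  A session with no separable PC is reported as
such, not errored.  Zero pooled variance at a frame yields NaN, flagged.

## Spatiotemporal statistics

Pairwise Pearson correlations are computed on trial-averaged,
1 s-LOESS-smoothed peri-movement ΔF/F₀ per movement (the trial-averaged
form matches the peri-movement activity patterns being compared);
pairwise distances are Euclidean between ROI centroids in µm.  Group
contrasts (HDA vs population or vs LDA) are bootstrapped median
differences, 10,000 resamples.  Trial-to-trial similarity: per neuron,
the mean Pearson r over all trial pairs of smoothed peri-movement
ΔF/F₀, summarised as bootstrapped medians per bias class (10,000
repetitions of 50 draws); the population analysis bins the trial-pair r
of summed movement-related ΔF/F₀ by the trial-pair r of the motion
index.  The HDA time course is the fraction of neurons whose per-frame
bootstrap accuracy CI lower bound exceeds the session threshold.

Spatial clustering is tested with a linear mixed model estimated by
REML:

    r ~ distance × accuracy + (1 | movement) + (1 | animal)

distance centred in µm (so the slope keeps r-per-µm units), accuracy
z-scored for conditioning; movement type and animal enter as crossed
random intercepts via variance components.  A singular random term is
dropped with a flag; with none left the model falls back to OLS.
Residual-vs-fitted correlations per covariate serve as the model
diagnostic.

## Reporting conventions

All bootstrap procedures take explicit seeded generators; identical
seeds give identical outputs end to end.  Every output table carries the
seed and a hash of the scientific configuration.  Times are in seconds,
distances in µm, frames 0-based.  The numbered scripts under `analysis/`
run the stages on a 50-neuron, 20-trials-per-movement demo session
(about two minutes end to end); the validation studies in
`motorpop.validation` use the full standard conditions above, with the
removal study at 20 trials per movement, sizes chosen so each study
states its `n` alongside its result.

## Known limitations

- The motion-index onset lead (LOESS leakage) shifts the whole aligned
  frame ~0.3 s early relative to true initiation; contrasts are
  unaffected but absolute onset times inherit the shift.
- The GLMM's movement-type random intercept frequently estimates a zero
  variance on synthetic data (two levels only); it is then dropped and
  flagged.
- Gaussian naive Bayes and logistic regression are the only decoders, by
  scope; no cross-session transfer.
- F₀ from the 5th percentile under-estimates the resting baseline for
  neurons suppressed a large fraction of the time, scaling (not
  re-signing) their ΔF/F₀ effects.
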