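# Methods

This note documents the models, numerical choices and limitations behind
`cuedecode`, in the spirit of the methods documentation of packages such
as statsmodels or mne.

## Synthetic experiment

### Design

A session comprises three cue conditions (acoustic motion, visual symbolic
precue, visual symbolic postcue) × two motion directions × 156 trials,
i.e. 936 trials.  Within each condition × direction cell,
`round(validity · trials)` trials carry a congruent cue; at the default
66% validity this is 103/156 = 66.0%, so validity is enforced exactly per
cell (the alternative — per block or per session — is not distinguishable
from published task descriptions; per-cell is the strictest reading and
makes the congruency analyses exactly balanced).  Trials are arranged in
mini-blocks of 78 trials of a single condition, with condition order
re-randomised within each of four experimental blocks.

### Stimulus

Random-dot kinematograms: 1300 dots in a 10° aperture (central 0.8°
empty), 4 °/s, 9-frame limited lifetime at 120 Hz, 96 frames (800 ms).
Motion coherence is redrawn independently for each of the eight 12-frame
epochs from a normal centred on the observer's threshold (SD 10
percentage points) and clipped to [0, 100] %.  Clipping (rather than
resampling) is the simplest reading of a bounded coherence range; at
thresholds ≳ 15% the clipping bias on the mean is negligible (verified by
Monte-Carlo in the test suite at mean 50: bias < 0.1 points).  Per frame,
`round(coherence · n_dots)` randomly chosen dots displace coherently by
`speed/frame_rate`; the remainder are reborn at random positions, as are
dots exceeding their lifetime or leaving the aperture.

### Observer

Choices follow a logistic model
`P(right) = lapse/2 + (1−lapse)·σ(β_m·(k·e) + β_c·cue + β_αm·α·(k·e) + β_αc·α·cue)`
with signed per-epoch evidence `e_j = direction · coherence_j/100`, a
temporal kernel `k` (default uniform), cue coded ±1, and `α` the trial's
z-scored log alpha power.  Defaults: β_m = 5 (≈71% correct on motion
alone at an 18% coherence threshold — the level a 2-down/1-up staircase
targets), β_c = 0.4 (a few percentage points of congruency benefit),
β_αm = +0.25, β_αc = −0.25 (alpha up-weights the stimulus and
down-weights the cue, the qualitative pattern the spectral GLMs are built
to detect), lapse 0.02.  The model is odd under joint mirroring of
direction, cue and evidence, so left/right symmetry is exact.

### EEG

Epochs span −0.5 to 1.0 s around stimulus onset at 150 Hz (the analysis
rate; recording-rate simulation exists only to exercise resampling).
Three additive parts, all in µV:

* **1/f background** (exponent 1, 10 µV RMS per channel), independent
  across channels and trials.
* **Alpha oscillation** at 8 Hz with log-normal trial-to-trial amplitude
  (`exp(N(log 8, 0.4))`), random phase, a fixed smooth posterior
  topography, full amplitude before stimulus onset and exponential
  desynchronisation (τ = 150 ms) after it.  The z-scored log power of
  this oscillation is the ground-truth `α` fed to the observer, closing
  the loop between prestimulus state and behaviour.
* **Evoked component**: a Gaussian bump (SD 50 ms) at 0.32 s whose signed
  amplitude follows the motion direction (4 µV), multiplied by the
  congruency gain (default 1.3) on congruent trials, mixed through a
  smooth occipital-like topography.  Only latency, topography and gain
  matter for the recovery tests; the waveform shape is a free choice.

Optionally, blink-like artifacts (300 µV, 80 ms Gaussian) are added to
the EOG channels (with 30% volume conduction to frontal channels) on a
random subset of trials to exercise the rejection rules.

What the generator does **not** emulate: volume-conducted correlated
noise between channels, non-stationary drifts, muscle artifacts,
cross-frequency structure, realistic evoked waveform morphology, and
saccade-related potentials.  Passing recovery tests therefore show that
the analysis chain is correct and well-calibrated, not that it is robust
to every pathology of real recordings.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.6–70 Hz, applied
forward-backward: ≈48 dB/octave effective roll-off, comfortably meeting a
20 dB-per-octave stop-band requirement), then polyphase resampling to
150 Hz.  Trial rejection uses two rules: (i) any EEG electrode exceeding
±175 µV (applied before re-referencing); (ii) the peak of the 1 Hz
high-passed EOG exceeding the across-trial mean by 3 SD.  The EOG
statistics are estimated iteratively (robust median/MAD start, then
mean + 3·SD on retained trials until the flagged set is stable): a
single pass lets the artifacts inflate their own threshold and fails to
reject even 10× artifacts once they exceed a few percent of trials.
Bad channels are replaced by the unweighted mean of their k = 4 nearest
neighbours by sensor geometry, then all EEG channels are re-referenced to
the common average.  ICA is deliberately out of scope (component
selection is judgment-based and not reproducible as code).

## Behavioural analyses

* **Accuracy/RT summary**: condition × congruency cell means, a fully
  within-subject two-way ANOVA implemented from sums of squares (each
  effect tested against its own subject-interaction error; partial
  η² = SS_effect/(SS_effect+SS_error)), cross-checked against pingouin in
  the tests, plus paired t tests with paired Cohen's d = mean(Δ)/SD(Δ).
* **Signal detection**: hits/false alarms relative to leftward motion,
  d′ = z(H) − z(FA), c = −(z(H)+z(FA))/2 per cue side; the two per-side
  criteria are combined after sign alignment, and the magnitude is
  reported (a signed version, positive when responses are drawn toward
  the cue, is retained as `cue_following_bias`).  Extreme rates use the
  log-linear correction (0.5 added to every count cell).
* **Staircase**: 2-down/1-up with step 4% until the second reversal, 2%
  afterwards, start 40%; threshold = mean of the last six reversal
  levels; three interleaved tracks averaged.  The rule's equilibrium is
  at P(correct)² = ½, i.e. 70.7% correct, which the acceptance script
  probes with a Weibull observer.
* **Motion energy**: the dot movie is projected onto the horizontal axis
  (per-frame dot histogram) and filtered with complex space-time Gabors
  tuned to ±(0.8 cyc/°, 3.2 Hz) — i.e. to the 4 °/s dot speed; signed
  evidence is rightward-minus-leftward energy per 12-frame epoch,
  normalised by total energy.  A ground-truth backend (signed per-epoch
  coherence) is the default in tests, where filter tuning is not the
  question.
* **Perceptual templates**: per-epoch difference in mean evidence between
  right- and left-choice trials, z-scored against ≥100 choice-label
  shuffles — which makes the weights invariant to affine evidence
  rescaling.  Congruency contrasts of templates use the participant-level
  percentile bootstrap.

## Decoding

Per 92 ms window (stepped at 46 ms, reported at the window's first time
point), electrode activity is time-averaged and a two-class LDA is
trained with shrinkage covariance Σ_γ = (1−γ)Σ̂ + γ(tr Σ̂/C)·I, γ = 0.1.
AUC comes from stratified sixfold cross-validation, averaged over 100
repetitions on random class-balanced 80% subsamples (equal per-class
draws; this also absorbs unequal cell sizes).  Projection vectors are
averaged over repetitions after sign-aligning each to the first (dot-product
sign) so they cannot cancel.  The forward model is the normalized
correlation between the discriminant component and the data,
`a_ch = cov(x_ch, y)/σ_y`: for single-source data it recovers the mixing
pattern exactly and it is invariant to rescaling of w.

Congruency effects use sixfold cross-validation: weights at the window
of interest are estimated on training folds, evidence is projected on
held-out trials at every window, aligned by the true direction (y·label;
the bias is omitted, as once aligned it carries label sign rather than
information), and the congruent-minus-incongruent mean course per
participant enters a one-sample sign-flip cluster-mass test.  Onset
latencies ("first time bin of the earliest significant cluster") are
compared between conditions with a participant-level percentile
bootstrap; resamples in which either condition loses its effect are
dropped and counted, and the estimate is flagged unreliable beyond 50%
drops.

## Spectral analysis

The time-frequency transform runs on the *virtual channel* y(t) = wᵀx(t)
(sample-wise projection, no window averaging).  Grid: 2–15 Hz in 1 Hz
steps, 16–50 Hz in 2 Hz steps; wavelet width rising linearly from 3
cycles at 2 Hz to 9 at 35 Hz and constant above (the linear ramp is the
simplest schedule consistent with the stated endpoints; it is
configurable).  Poststimulus samples are zeroed *before* the transform,
which makes the prestimulus estimates bit-identical no matter what the
evoked response contains (asserted as a test).  The epoch is zero-padded
so the widest wavelet fits, power is restricted to the prestimulus window
(−0.5 to 0 s; figure-style reporting can crop further) and z-scored
across trials per bin.  Frequencies whose full wavelet support exceeds
the prestimulus span (below ≈6 Hz with a 0.5 s window) are kept but
flagged with a warning, since their estimates lean on the zeroed region.

Choice GLM per participant and bin: logistic regression of choice on
{stim, cue, stim×cue, power, power×stim, power×cue} (±1 coding, power
z-scored per bin, products not re-standardised).  A power main effect is
included so the interaction model is properly nested, and reported
alongside the rest.  Non-converged or separated fits fall back to a weak
ridge (L2, C = 1).  The accuracy GLM uses {congruency, power,
power×congruency}.  Group inference is the 2-D cluster-mass sign-flip
test on the per-participant betas.  Follow-ups: median-split of trials by
cluster-averaged power within participant with per-congruency paired t
tests (BH-FDR over the two tests; cluster masks intersect bin-wise), and
the cue-direction power contrast for precue trials.

## Group statistics

One-sample sign-flip cluster-mass permutation: bin-wise t against zero,
two-sided first-level threshold at α₁ = 0.05 (t distribution, df = n−1),
clusters = connected supra-threshold sets (consecutive bins in 1-D,
4-connectivity in 2-D) of extent ≥ 3 bins ("minimal cluster size of
three neighbours" is read as minimum extent, the only meaningful reading
on a 1-D grid).  The null collects, per sign-flip permutation, the single
maximal absolute cluster mass over both signs (max-statistic correction;
the two-sided test is then controlled at 5% overall).  p-values use the
+1 correction, so p = 0 is impossible; when 2ⁿ distinct flips are fewer
than the requested permutations, all flips are enumerated exactly.  This
construction is conservative on small 1-D grids (empirical family-wise
rate ≈ 0.002–0.02 at 20 × 40 null bins, vs the nominal ≤ 0.05), which is
the accepted behaviour of cluster-extent-thresholded max-statistic tests.

The percentile bootstrap resamples participants with replacement
(default 2000), takes percentile CIs, and reports
p = 2·min(P(θ*≤0), P(θ*≥0)); like all percentile bootstraps it mildly
undercovers at n ≈ 20 (≈90% empirical for a nominal 95% on normal data),
which the tests acknowledge rather than hide.  BH-FDR is the step-up
adjustment with monotonicity enforcement.

## Problem sizes and determinism

Defaults follow the task design (20 participants × 936 trials, 128
channels, 100 LDA subsample repetitions).  The test suite and the
acceptance script run the same code on reduced cohorts (typically 6–20
simulated participants, 100–250 trials, 8–16 channels, 2–5 repetitions),
sizes at which every planted effect is still comfortably recoverable;
the cluster-calibration check uses the full 500 datasets × 500
permutations.  All randomness flows through `numpy.random.Generator`
seeds, and the pipeline's `summary.json` is byte-identical across runs
with the same configuration and seed.

## Known limitations

* The generator's EEG is additive and spatially simplistic (see above);
  the motion-energy filters are fixed-bandwidth and not fit to human
  contrast sensitivity.
* ICA denoising, source-space analysis (beamforming) and eye-tracking
  analyses are out of scope.
* RTs are placeholders (log-normal), so RT analyses beyond cell means and
  the ANOVA machinery are not meaningful on synthetic data.
* The latency bootstrap re-runs a cluster test per resample; for speed
  its inner permutation count defaults to 500 (the outer bootstrap
  dominates the p-value's resolution).
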