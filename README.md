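# cuedecode

Analysis toolkit for cued visual-motion discrimination experiments, from
behavioural psychophysics to single-trial EEG decoding — built around a
synthetic-experiment generator so that every stage of the analysis can be
validated as a recovery problem with known ground truth.

## The scientific problem

In a cued motion-discrimination task, observers judge the direction
(left/right) of an 800 ms random-dot stimulus whose motion coherence is
redrawn every 12 frames around the observer's threshold.  On each trial an
auxiliary probabilistic cue — concurrent acoustic motion, a visual symbolic
precue, or a visual symbolic postcue — points in the correct direction with
66% validity.  Three questions drive the analysis:

1. **Behaviour.** How much does each cue help?  Quantified by accuracy /
   signal-detection measures (d′ = z(H) − z(FA), criterion c combined over
   cue sides), and by reverse-correlation *perceptual templates*: the
   choice-conditioned difference in momentary motion evidence, z-scored
   against a label-shuffle null, which shows *when* stimulus information
   drives decisions.
2. **Neural encoding.** When does the brain's representation of motion
   direction improve on congruently cued trials?  A regularized linear
   discriminant (shrinkage LDA, γ = 0.1) is trained in sliding 92 ms
   windows (46 ms steps) over the epoch; its cross-validated ROC AUC traces
   the encoding of motion direction over time, the forward model
   a = cov(x, y)/σ_y gives the interpretable scalp pattern, and the
   direction-aligned single-trial evidence y(t) = wᵀx(t) is contrasted
   between congruent and incongruent trials with cluster-mass permutation
   tests.
3. **Prestimulus state.** Does prestimulus alpha power shape how cue and
   stimulus are combined?  Morlet wavelet power (2–50 Hz; poststimulus
   period zeroed, power z-scored across trials) of the LDA component enters
   single-trial logistic GLMs of choice
   (stim, cue, stim×cue, power, power×stim, power×cue) and of accuracy
   (congruency, power, power×congruency), with group-level sign-flip
   cluster-mass inference over the time–frequency plane.

Because participant recordings for such experiments are typically not
public, the package ships a fully parameterised generator
(`cuedecode.synthetic`) producing the design, dot stimuli, a logistic
observer whose choices weight motion evidence, cue, and alpha state, and
multichannel EEG with a planted direction-discriminative component
(boosted on congruent trials), 1/f noise and trial-varying alpha.

## Worked example

```python
import cuedecode as cd

# one synthetic participant: 120 trials, 16 EEG channels
table, epochs, alpha, info = cd.simulate_session(
    cd.DesignSpec(trials_per_cell=20),
    eeg=cd.EEGSimParams(n_channels=16), seed=101)

lda = cd.SlidingWindowLDA(reps=5, random_state=0)
lda.fit(epochs, table["direction"].to_numpy())
peak_time, peak_auc = lda.peak()
print(f"accuracy {table['correct'].mean():.3f}  "
      f"AUC peak {peak_auc:.3f} at {peak_time:.3f} s")
```

prints

```
accuracy 0.758  AUC peak 0.706 at 0.282 s
```

The observer performs at ~76% correct (its motion weight was chosen to sit
near a 71%-correct coherence threshold, plus the cue benefit), and the
decoder finds the planted direction-discriminative component: the AUC time
course peaks at the window starting 0.282 s — within one 46 ms window step
of the planted 0.32 s latency — at AUC ≈ 0.71.

The full pipeline (simulate → preprocess → behaviour → decode → spectral
GLMs), configured by a YAML file, runs from the shell:

```bash
cuedecode run-all --config config.yaml --seed 7 --out runs/r1
```

and writes tidy CSVs, cluster-test JSONs, an AUC figure and a
`summary.json` that is byte-identical across runs with the same seed.

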