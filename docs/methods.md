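# Methods

This note documents the models, parameters and design choices behind
`alscore`, and what the synthetic-cohort experiments do and do not
demonstrate.

## Problem setting

ALSFRS-R assigns each of 12 functions an integer 0–4 (4 = normal).  The
pipeline treats subscore prediction as weakly supervised frame
classification: every fixed-duration frame of a recording inherits the
recording's label (the nearest same-participant assessment within 60 days;
recordings without one are discarded, and equidistant ties resolve to the
earlier assessment, favoring the pre-recording state).  Dates are integer
day offsets from an arbitrary cohort epoch; calendar handling stays in the
readers.

## Featurization

**Voice** (`alscore.voice`): resample to 8 kHz mono (polyphase; stereo
averaged), cut into non-overlapping 960 ms frames (7680 samples; trailing
partial frame dropped).  Per frame: STFT with a 25 ms periodic Hann window
(200 samples) hopped every 10 ms — 96 hops at offsets 0, 80, …, 7600, with
windows overrunning the frame zero-padded — FFT length 256, magnitude
spectra integrated through a 64-filter triangular mel filterbank (HTK
formula, 125–3800 Hz, unit-area filters), then ln(mel + 0.001).  Result:
one 96×64 window per frame.  Whether magnitude or power spectra feed the
mel integration is exposed as the `power` flag (default magnitude); the
natural logarithm is used.

**Accelerometer** (`alscore.accel`): per limb (LA, LW, RA, RW; the
both-wrists exercise is excluded from the data model), the 30 Hz tri-axial
series is reduced to the vector magnitude and cut into non-overlapping 75 s
frames (2250 samples).  Per frame: rectangular 7 s windows (210 samples)
hopped every 4 s — 19 windows, the final ones zero-padded — FFT length 256,
linear magnitude, giving 19×129 patches.  The hop is fixed at 4 s because
the printed patch shape (19 time steps = 75/(7−3)) requires it; a 3 s hop
would give 23 windows.  The rectangular window keeps the pure-sinusoid
oracle exact.  Feeding per-limb VM (rather than per-axis) spectrograms to
the CNN matches the VM-based treatment of the 1 Hz variants.

The 1 Hz stream is derived by averaging consecutive 30-sample VM blocks
when no native 1 Hz export exists.  The three 1 Hz summaries:

* **TBVM**: Σ_limb coeff_limb · (mean VM_limb / 717.9) with coefficients
  LA 2.497844, RA 2.492674, LW 1.0, RW 1.01044 (left wrist defined the
  healthy-volunteer maximum, hence exactly 1).  TBVM is linear and
  homogeneous by construction.
* **FFT-1Hz**: per limb, DC magnitude / n (mean level) and the largest
  non-DC magnitude / n (dominant periodic component; a pure sinusoid of
  amplitude a over an integer number of periods yields a/2).  Only the
  total of 8 features is externally fixed; the choice of these two
  quantities is a package decision and is isolated in `fft1hz_features`
  so it can be swapped.
* **Uniform-1Hz**: VM series truncated/zero-padded to 70 samples per limb
  (280 values), z-scored per position with statistics estimated on the
  training split only (`Uniform1HzScaler`); zero-variance positions are
  centered but not scaled.

## Models and training

All classifiers emit one sigmoid activation per (function, score) label —
5 activations per function, 45 for the 9-function multi-label head — and
are trained with per-label logistic loss.  Each frame's loss is weighted by
the inverse frame-level frequency of its class label, normalized so the
weighted mean over frames is 1; with balanced classes this reduces exactly
to the unweighted loss.  Mini-batches sample frames uniformly across all
recordings (not per recording), consistent with the frame-level weighting.

The network core (`alscore._nn`) is a deliberately small numpy
implementation — dense and 3×3 same-padding conv layers, batch norm, ReLU,
2×2 max pooling, global average pooling, Adam/SGD — with hand-derived
backward passes, float64 throughout, and fully seeded initialization and
shuffling, so training is bit-reproducible for a given `random_state`.

The CNN (`SpectrogramCNNClassifier`) is a compact VGG-style stack:
[conv 3×3, batch norm, ReLU, max pool 2×2] per block with doubling filter
counts, then global average pooling and a dense head.  The default filter
stack is (8, 16, 32), sized so voice-model training completes in minutes
on one CPU at desk scale; the `filters` parameter accepts larger stacks
(e.g. (32, 64, 128)) for full-scale runs.  Estimator defaults mirror the
full-scale hyperparameters (voice: batch 64, lr 1e-5, 25 epochs; accel
CNN: batch 32; MLP/logistic/linear: batch 100, 60 epochs).  When a
validation set is supplied, the parameters with the best validation macro
multiclass AUC are restored after training (the selection metric was an
open choice; validation AUC matches the reported evaluation metric).

The linear-regression variant minimizes squared error on the integer score
and enters AUC comparisons through a distance softmax
p_k ∝ exp(−(k − ŷ)²/τ), τ = 0.5; an exact integer prediction yields an
argmax at that integer.

Per-class sigmoids do not sum to one, so each frame's activations are
normalized into a proper distribution before recording-level averaging
(normalize-then-average; average-then-normalize is available via
`aggregate_recording(..., normalize="after")`).  The continuous score is
the expectation Σ k·p_k, affine in the distribution and bounded in [0, 4].

## Evaluation

`multiclass_auc` computes, per score class with both positives and
negatives present, the one-vs-rest ROC-AUC using that class's probability
as the ranking score (midrank ties, matching a Mann–Whitney pair-counting
oracle exactly), and averages unweighted; one-sided classes are skipped
with a logged note.  Bootstrap CIs are percentile intervals over resampled
recordings (participant-level resampling is possible by passing
participant aggregates as the records, since repeated measures are
correlated); resamples on which the metric is undefined are redrawn and
counted.  R² matrices are squared Pearson correlations on
pairwise-complete rows, NaN (never fabricated) where a column is constant.
Slopes are OLS score-on-day fits requiring ≥3 points; day-zero alignment
shifts a timeline so the event is day 0 and splits it into pre (<0) and
post (≥0) segments, each sloped only when it has ≥3 points.  Confusion
matrices use argmax predictions with ties resolved to the lowest class.

## Synthetic cohort

`alscore.simulate` generates the study conditions every experiment runs
under.  Defaults: 60 participants followed 360 days; assessments every
~60 days (jitter sd 8 d); recording sessions (voice + accelerometer) every
45 days; self-reports mis-rated ±1 with probability 0.05; onset mix
78% limb / 15% bulbar / 7% respiratory.

Severity trajectories are affine in time, clipped to [0, 4]: a shared
participant baseline (mean 3.3, sd 0.4) and decline rate (mean
−0.0025 score/day ≈ −0.9/year per function, sd 0.0015, forced ≤ 0) are
modulated by group-level offsets (sd 0.2) and log-normal slope multipliers
(sd 0.3) for the bulbar trio, fine-motor items, lower-limb pair and
respiratory trio, plus small per-function noise (sd 0.1).  Onset type
deepens and accelerates its own group(s).  This variance decomposition
makes within-group score correlations exceed cross-group ones (R² ≈ 0.7 vs
≈ 0.3 at n = 120) while retaining a shared progression factor — which is
what lets limb-driven signals partially predict respiratory scores, as
observed in real cohorts.

Signals are monotone in severity by construction.  Voice: a 120 Hz
harmonic carrier gated by a raised-cosine syllable envelope; syllable rate
falls from 3.5 to 1.5 Hz, gaps widen, pitch jitter and broadband noise
grow as severity drops; peak amplitude ≤ 1.  Accelerometer: per-limb
oscillation (0.5–2.5 Hz) with amplitude 0.05–1.05 g, projected on a random
fixed orientation, gated by 60 s exercise bouts (75% duty), with additive
sensor noise (sd 0.05); ankles are driven by the lower-limb latents,
wrists by the fine-motor latents.  Series represent gravity-compensated
dynamic acceleration.

All randomness flows from one seed through `SeedSequence.spawn`: child 0
is cohort-level, child 1+i belongs to participant i, and per-recording
draws come from that participant's stream, so each sub-generator is
independently reproducible.  Treatment events (30% of participants,
uniform in the middle 30–70% of follow-up) shift nothing; they exist to
exercise day-zero alignment.

**What passing does and does not show.**  The generator produces idealized,
strongly informative, stationary signals: no phonetic content, no speaker
identity, no device calibration drift, no missing limbs, no exercise
mis-timing.  Parameter recovery on it validates the *pipeline* — that
featurization preserves the severity signal, the weighted training and
aggregation recover it, and the evaluation measures it — not the
clinical-scale accuracy achievable on real recordings.

## Desk-scale experiment settings

`alscore.experiments` runs the full method on one CPU in minutes: features
standardized by training-split statistics, MLP (64 hidden units, lr 1e-3,
60 epochs) for FFT-1Hz, and the (8, 16, 32)-filter CNN (lr 1e-3, batch 64,
8 epochs) for voice.  The raised learning rate and reduced epoch count are
sized to the small synthetic cohort (~1700 training windows) where the
full-scale schedule (lr 1e-5, 25 epochs) would be far from convergence;
both are ordinary arguments, not fixed behavior.

## Known limitations

* The exact published CNN layer stack is only partially specified
  upstream; the compact stack here is a faithful shape-compatible stand-in
  and is configurable.
* Voice-content verification (that the prescribed sentence was actually
  spoken) and exercise segmentation are out of scope; inputs are assumed
  pre-segmented.
* Distribution calibration (temperature scaling, isotonic) is not
  implemented; expected scores inherit any mis-calibration of the sigmoid
  activations.
* `pairwise_r2` requires ≥3 paired observations and reports NaN for
  degenerate columns rather than imputing.
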