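# Methods

## The problem

Feature-based attention — prioritising a stimulus *feature* (here, the
luminance polarity of a dot field) rather than a location — modulates the
amplitude of steady-state visual evoked potentials (SSVEPs): the EEG
response phase-locked to a flickering stimulus grows when that stimulus is
attended. A brain–computer interface can exploit this by frequency-tagging
two intermingled dot fields (black and white dots flickering at 6.0 and
7.5 Hz) and asking, from a short single-trial EEG epoch, *which colour is
the participant attending?* This package implements the full benchmarking
pipeline for that question: a simulator of the task and its EEG, BIDS/
BrainVision I/O, sliding-window FFT feature extraction with exclusion rules,
six classifiers under two training regimes, and a model of how accuracy
grows with the decoding window.

## The task and schedule (`task_design`)

One session is 160 trials (8 blocks × 20). Each trial is a 2 s colour cue
followed by 15 s of flickering dot motion containing five 500 ms bursts of
coherent motion in the cued colour only. The three binary factors —
distractor (both colours present vs only the cued colour), cued colour, and
colour→frequency pairing — are fully crossed: each of the 8 cells occurs
exactly 20 times. Coherent-motion directions (0/90/180/270°) are balanced
within each (distractor, pairing) stratum: 200 targets per stratum, 50 per
direction.

Motion-onset times are rejection-sampled: five uniforms on [1.0, 13.5] s,
accepted when consecutive onsets are separated by more than 2.0 s (0.5 s
burst + 1.5 s minimum gap after its offset). Rejection keeps the marginal
spacing distribution unbiased; the accept rate is ≈0.6%, so candidates are
drawn in batches. Feasibility is checked against the packing bound
`1.0 + 5·0.5 + 4·1.5 + 1.5 = 11.0 ≤ 15`.

Triggers are 8-bit codes on a dedicated channel: cue onset (1–8) and trial
onset (11–18) enumerate (frequency × colour × distractor), motion onsets
(101–132) add the direction, feedback is always 222. Encode→decode is a
bijection; real datasets carry their own code tables, injected via
`TriggerMap`.

Behavioural scoring attributes the first key press in `(onset, onset+1.5 s]`
to that target: matching direction → correct (ACC 1, RT recorded), mismatch
→ incorrect (ACC 2), none → miss (ACC 0). The paper's source does not state
the acceptance window; 1.5 s is chosen because the enforced ≥1.5 s
offset-to-onset gap then guarantees unique attribution.

## The synthetic world (`synthetic_data`)

Per participant the generator emits a continuous 5-channel (Iz, O1, O2, Oz,
POz) recording at 1200 Hz plus the trigger channel, with trials every
18.5 s. During each 15 s stimulation period:

| component | model | default |
|---|---|---|
| SSVEP | sin at f and 2f, phase-locked to stimulation onset | amplitudes below; harmonic ratio 0.4 |
| cued 6.0 Hz | | 1.47 µV (uncued 1.33) |
| cued 7.5 Hz | | 1.05 µV (uncued 0.93) |
| electrode gains | per-frequency multiplicative, mean exactly 1 | ±10% jitter |
| alpha | narrowband Gaussian process, 10 ± 1 Hz bump, coherent across electrodes | 4 µV RMS |
| background | 1/f^β Gaussian, band-limited 1–100 Hz (2nd-order edges) | β = 1, 3.75 µV SD |
| motion transient | sin² bump, 1 s, after every motion onset | 10 µV |
| artifacts | sin² excursions, 0.3 s, Poisson times, one channel | 2/min at ±200 µV |

The SSVEP amplitudes are the study's grand means; distractor-absent trials
contain only the cued frequency. Behaviour is generated as frame-wise key
presses (correct with the configured per-condition probability, 62.17%
present / 87.74% absent; errors split evenly between miss and wrong key) and
then *scored* by the same routine used for real data, so ACC/RT are
consistent with the response stream by construction. RTs are shifted
lognormal (shift 0.2 s, σ = 0.4) with the configured means (0.64 / 0.58 s),
truncated to the attribution window.

Three generator choices deserve explanation:

- **Alpha as narrowband noise, not a per-trial sinusoid.** A coherent 10 Hz
  sinusoid with a fixed per-trial phase gives every trial a stable spectral
  fingerprint (via leakage into the 6–12 Hz feature bins at short windows).
  Trial-wise cross-validated classifiers *learn* that fingerprint and
  anti-generalise: LDA measured reproducibly below chance. Real alpha drifts
  within a trial; a 10 ± 1 Hz Gaussian process (coherence ≈ 0.5 s) has
  random phase in every trial without being a trial ID.
- **Band-limited background.** The deposited recordings were filtered
  1–100 Hz online. An unfiltered 1/f process is dominated by sub-hertz
  drift, which again acts as a per-trial fingerprint in short zero-padded
  epochs. The noise generator therefore applies 2nd-order band edges at 1
  and 100 Hz.
- **Noise scale.** `noise_scale = 3.75 µV` was fixed by a one-off
  calibration so that simple-feature LDA lands near 65% at the 4 s window
  (measured ≈51/53/56/59/66% across the five windows). The aspirational
  55%-at-0.25 s / 65%-at-4 s pair is not jointly reachable with one dial:
  with temporally unstructured noise the class separation scales ≈√window,
  so anchoring 4 s pins 0.25 s near 51%. Real data do better at short
  windows, plausibly because attentional state and noise power fluctuate at
  the trial timescale — structure this generator deliberately omits. A green
  effect-recovery test therefore establishes correct *direction and
  ordering* of effects, not the study's exact short-window accuracy.

## Features (`features`)

Epochs of 0.25/0.5/1/2/4 s are cut every 0.25 s from each 15 s trial
(60/59/57/53/45 per trial). Two exclusion rules follow: any sample
exceeding 150 µV absolute in any channel (strictly greater excluded), and
strictly more than 1/3 of the epoch inside the union of 1 s post-onset
periods of the coherent-motion targets. Surviving epochs are balanced across
the two attended colours within each (distractor, pairing) stratum by
removing random epochs from the larger class (seeded).

Epochs shorter than 2 s are zero-padded to 2 s (0.5 Hz resolution); 2 s and
4 s epochs are transformed at native length, whose finer grids still contain
every 0.5 Hz bin. Single-sided amplitudes are scaled by `2/N_signal`
(the *unpadded* length), keeping a unit sinusoid at ≈1 regardless of
padding. Feature sets: `simple` (6.0, 7.5 Hz), `+harmonic` (12.0, 15.0),
`+alpha` (8.0–12.0 in 0.5 Hz steps, always 9 bins so the feature dimension
is window-independent). The full set is 13 frequencies × 5 channels = 65
features (12.0 Hz intentionally appears in both the harmonic and alpha
blocks).

## Decoders (`decoders`)

The z-score baseline averages the amplitude at each tag over channels,
z-scores it against populations built from the training epochs of the same
display configuration, and predicts the colour paired with the larger
z-score (ties: seeded fair coin). The original description is silent on
channel handling, so the channel-mean default is switchable to averaging
per-channel z-scores (`mode="mean_of_z"`). Populations are computed from training
folds only — including test epochs would leak.

The learned classifiers consume the full feature vector: LDA (pooled
covariance, uniform priors), logistic regression by SGD with L2 penalty
λ = 1/n, an RBF SVM whose kernel scale is the median pairwise distance on
≤1000 subsampled training points, a 2×10 MLP trained on squared-error loss
by SGD with momentum and an adaptive learning rate (≤500 passes or <1e-6
improvement over 20), and 1-nearest-neighbour. Features are column-
standardised by training-fold statistics for the scale-sensitive four
(LR/SVM/MLP/KNN); LDA and the z-score rule consume raw amplitudes.

Regimes: 10-fold CV with folds cut by *trial* (overlapping epochs of one
trial never span train and test), and a single iteration of training on
distractor-absent epochs tested on distractor-present epochs. Classifiers
are fitted per colour-frequency pairing and accuracies averaged across the
two pairings.

Two choices respond to artifacts of class-balanced trial-wise CV: folds are
*stratified* by the trial's class, and LDA uses uniform priors. Without
either, every fold's training set leans against its test set's majority
class, and with a weak signal the classifiers follow the training
imbalance — measured at 26% accuracy (LDA, empirical priors, unstratified)
on data carrying a genuine positive signal. Stratification preserves the
trial-wise separation guarantee.

## Evaluation (`evaluation`)

Behavioural summaries count only ACC = 1 as correct and average RT over
correct targets. SSVEP amplitudes average the trial time series within each
(distractor, pairing, cued-frequency) cell *before* the FFT — phase-locked
responses survive averaging, random-phase alpha cancels. The analysis
window is the first **14 s** of each trial: 15 s is *not* an integer number
of 7.5 Hz cycles (112.5), so no 15 s FFT bin sits at 7.5 Hz and a pure
0.93 µV tone would read ≈0.59 µV through half-cycle leakage; at 14 s both
tags (84 and 105 cycles) and their harmonics fall on exact bins.

Accuracy as a function of window size T follows
`ACC = a(1 − e^{−s(T−i)})` — asymptote a (%), rate s (1/s), x-intercept
i (s) — fitted by multistart nonlinear least squares (starts a ∈ {55, 65,
75}, s ∈ {0.1, 0.5, 2}, i ∈ {−1, 0, 0.2}; bounds a ∈ (50, 100], s > 0,
i < min T). The window reaching fraction q of the asymptote is
`T = i + ln(1/(1−q))/s`. Noiseless curves are recovered exactly; with only
the five experimental windows (≤4 s ≈ 86% of a typical asymptote) the
asymptote is weakly identified and can run to its bound on small samples —
the recovery property is validated on a 0.25–10 s design instead. Constant
accuracy curves leave s unidentified and raise an error.

Group aggregation averages pairings first, reports means per
(classifier, regime, window, variant), the per-participant maximum-accuracy
table, and Bonferroni-corrected paired t-tests of each classifier against
the z-score baseline.

## What a green test establishes

The simulator reproduces the study's *structure* — amplitudes, their
attentional modulation, counterbalancing, trigger semantics, behavioural
rates, exclusion-rule edge cases — with stationary Gaussian noise. It does
not model trial-level attentional drift, eye blinks or physiologically
shaped artifacts, electrode-specific noise spectra, or the 120 Hz display
itself (dot geometry is carried as metadata only). Tests that pass on
synthetic data therefore validate the pipeline's correctness and the
direction of its effects; absolute accuracies on the deposited recordings
will differ, and the original toolbox's classifier internals are not fully
specified, so full-grid accuracy tables are indicative only.

Null checks respect the dependence structure: overlapping epochs within a
trial are correlated, so chance-level tests are evaluated at trial
resolution rather than with an epoch-count binomial, which would spuriously
reject.
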