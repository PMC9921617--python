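# Methods

`minav` re-creates, in software only, a self-paced motor-imagery
brain–computer interface for street-view navigation: the user starts
walking by imagining a sustained two-hand flexion, selects rotation with
an eye blink, and steers left/right with single-hand clenching imagery.
This note documents the models, parameter choices and numerical
decisions behind each stage, and what the synthetic benchmark does and
does not demonstrate.

## Synthetic EEG model

Each trial is channels × samples in microvolts at 250 Hz, on an
8-channel dry-electrode montage (Fz, C3, Cz, C4, P3, P4 plus mastoid
references TP9/TP10).

* **Background**: 1/f-shaped noise (white noise re-weighted by
  `1/sqrt(f)` in the spectral domain), RMS `background_amplitude`
  (default 10 μV) on every channel. A 1/f surrogate is the standard
  broadband EEG stand-in; it reproduces the spectral tilt but none of
  the non-stationarity of real recordings.
* **Sensorimotor rhythms**: band-limited Gaussian noise in the mu
  (8–12 Hz, default 6 μV RMS) and beta (14–25 Hz, default 4 μV RMS)
  bands on the central/parietal channels. Narrow-band noise rather than
  a sinusoid so that trial-to-trial phase and envelope vary.
* **Event-related desynchronization**: imagery multiplies the
  *oscillation amplitude* of the contralateral channel(s) by
  `(1 − erd_depth)` — C4 for left-hand imagery, C3 for right-hand,
  both for two-hand flexion, none at rest. The broadband background is
  never modulated. The task/rest band-power ratio of the oscillatory
  component is therefore `(1 − erd_depth)²`, which the generator tests
  verify with Welch periodograms at vanishing background. The default
  depth of 0.5 represents a clearly present but not extreme
  desynchronization; the end-to-end benchmark uses 0.8 (a high-SNR
  subject) and 0.0 (no signal) as the two poles.
* **Blinks**: a biphasic transient (one windowed sine cycle, 200 ms,
  unit-peak-normalised) with peak `blink_amplitude` (150 μV) on Fz and
  volume-conduction-like attenuated copies on neighbouring channels.
  The biphasic shape keeps the transient's energy above the 4 Hz edge
  of the blink-detection band: the measured filtered/raw peak ratio is
  ≈ 0.89, so a 150 μV blink comfortably exceeds the 100 μV detection
  threshold after filtering. A smooth unipolar bump of the same
  duration would lose most of its peak to the high-pass edge.
* **Artifacts**: an optional injected transient with peak
  `artifact_amplitude` (250 μV), above the 200 μV rejection gate.

Trial timing follows the recording protocol the decoder is built for:
6 s flexion and rest epochs, 2 s left/right epochs, 70 trials per class,
flexion/rest in sessions 1–2 and left/right in sessions 3–4. Everything
is driven by a single seeded generator; a fixed seed reproduces every
sample bit-for-bit.

What passing tests on this generator show: the pipeline recovers
spatially and spectrally structured power differences at realistic
amplitudes and SNR. What they do not show: robustness to real-world
non-stationarity, electrode drift, EMG/movement contamination, or
subject variability — the generator has no volume-conduction forward
model and its rhythms are stationary within a trial.

## Signal path

Epochs are re-referenced to the mastoid mean (TP9/TP10, then dropped).
All filtering is **causal** (forward-only) Butterworth, including during
offline training, so offline and online decoding share one code path
and produce identical labels for identical epochs; zero-phase filtering
would be unavailable online.

Thresholds operate on the absolute signal value because EEG deflections
are bipolar, with strict inequality at the boundary: an epoch is
rejected as artifact iff max |x| > 200 μV on any channel; a blink is
detected iff the 4–40 Hz-filtered Fz trace exceeds 100 μV in magnitude.
The first 0.2 s of a filtered trace are excluded from maximum checks to
ignore causal-filter start-up ringing.

## Decoder

1. **Filter bank** — twenty 5th-order Butterworth band-passes: 4 Hz-wide
   bands stepped by 2 Hz from (4, 8) to (40, 44), plus a 4–40 Hz
   broadband, applied to all 6 decode channels → 120 channels.
2. **CSP** — per band, the standard two-class common-spatial-pattern
   solution: per-trial sample covariances are trace-normalised (making
   the fit invariant to per-trial gain), averaged per class, ridge-regularised
   (1e-6 of the mean eigenvalue), and jointly diagonalised via the
   generalized eigenproblem `C_a w = λ (C_a + C_b) w`. The two extreme
   eigenvectors compress 6 → 2 channels per band → 40 channels.
   Patterns (mixing columns, for topographic reading) are columns of
   the inverse transpose of the full filter matrix. Bands are fitted
   independently; no band selection is performed.
3. **Features** — five statistics per channel in sliding windows of 200
   samples with hop 15 (complete windows only, floor convention):
   log-power `log(mean(x²)+1)`, log-variance, zero-crossing rate with
   `sgn(0) = +1` (so an all-zero window has ZCR 0), sum of absolute
   values, and peak-to-peak. 5 × 40 = 200 features per step; a 6 s epoch
   yields 87 steps and a 2 s epoch 21. (Published step counts of
   117/67 for these window parameters would require ≈ 7.8 s / 4.8 s
   epochs; with the stated task durations the counts above follow from
   `floor((N − 200)/15) + 1` and are used throughout. Epoch lengths
   remain configurable.)
4. **Classifier** — a single bidirectional LSTM layer (64 hidden units
   per direction), dropout (0.5, training only) on the concatenated
   final hidden states of the two directions, then a dense 2-way
   softmax. Implemented directly in numpy (forward pass and full
   backpropagation through time), trained with Adam, initial learning
   rate 5e-5 decayed by 0.8 each iteration (= one pass over the
   training set), at most 50 iterations, L2 0.1 on weight matrices.
   Gradients are validated against finite differences in the test
   suite.

   *Numerical choice*: the readout weights start at zero. Under this
   learning-rate schedule total parameter displacement is tiny, so the
   recurrent layer acts mostly as a fixed nonlinear feature map; with a
   zero-initialised readout the decision boundary's orientation is set
   by the accumulated (consistent) gradient direction rather than by a
   random initialisation, which makes argmax decisions correct for
   separable classes even at small step sizes. Feature sequences are
   standardised with training-split statistics. Classification reads
   the final sequence step of both directions.

   A deterministic logistic-regression baseline on time-averaged
   features sits behind the same contract, to separate pipeline bugs
   from sequence-model behavior.

Two binary decoders are trained per dataset — flexion–rest (6 s epochs)
and left–right (2 s epochs) — on a stratified, seeded 50/20 per-class
split; CSP banks and scalers are fitted on the training split only.
Epochs failing the artifact gate are excluded from training and refused
(not classified) online. A single positive flexion classification
triggers the start command; the consecutive-positives count is
configurable. The online clock advances in 0.5 s quanta through a ring
buffer; decoding never raises on finite input (the outcomes are a
label, `artifact`, or `no_decision`).

## Navigation automaton

States: idle → (flexion) → switch (2 s) → walk, or → rotation if a
blink arrives during the switch window. Walking emits one forward move
per second. Low-level mode stops on a blink; middle-level mode stops
automatically *in front of* a junction (one-edge look-ahead), and
ignores blinks while walking. A blink in the rotation state exits to
idle.

Rotation strategies:

* **NE** — every classification executes immediately; structurally,
  classification errors and navigation errors coincide.
* **DC** — an arrow displays the first classification; a second
  identical one executes it; a mismatch resets to an empty pair (no
  partial credit — only the success path is prescribed, so the reset is
  this package's choice).
* **EC** — the arrow enters a correction state with a 2 s dwell (one
  blink-detection epoch; no duration is prescribed); a blink vetoes and
  executes the opposite direction, silence confirms.

Headings are quantized to the four compass directions; one rotation
command is one 90° increment (street-view arrow semantics). The world
is a directed graph with 2-D node positions and junction flags
(auto-flagged at degree ≥ 3 if requested), loadable from YAML/JSON;
bundled builders produce a straight street, a grid city and a museum
corridor — hand-drawn topologies, not geo-accurate maps. The automaton
is total: every (state, event) pair has a defined transition, and
malformed events are rejected with the state unchanged.

## Closed-loop simulation and oracles

The user model follows a route of walk legs and single turns. In
abstract mode each imagination decodes correctly with probability `p`
and each blink is detected with probability `q`; in full mode the same
interface generates synthetic EEG and runs it through a trained
pipeline, so strategy logic is testable both fast and end-to-end.

The rotation controller tracks the *net* heading offset and keeps
issuing intents toward the target, so the offset performs a ±1 random
walk absorbed at +1 (a wrong execution is corrected by
counter-rotating, never by rotating 270° the long way). Per intended
rotation the simulator counts misclassified imaginations
(`No_error`), executed wrong rotations (`No_navigation_error`) and
total imaginations (`No_imagination`).

Closed forms (by Wald's identity on the absorbed walk):
`E[No_imagination]` is `1/(2p−1)` under NE, `2/(2p−1)` under DC (only
agreeing pairs execute: +1 w.p. p², −1 w.p. (1−p)²), and `1/(2r−1)`
under EC with effective success `r = p + (1−p)q` — exactly 1 when
blink detection is reliable. The Monte-Carlo counterpart simulates the
walks directly from Bernoulli draws and agrees within 2% at 10⁵
rotations; they diverge (and the code signals it) at `p ≤ 0.5`.

Time accounting uses simulated seconds only: 6 s per flexion epoch,
2 s per left/right epoch, 2 s switch, 0.5 s per blink-detection
attempt, 2 s EC correction window, 1 s per forward move. With a
perfect decoder the walk command therefore issues after exactly 6 s
and an NE rotation after exactly 2 s; with `p < 1` all times are
strictly larger. Blink unreliability (`q < 1`) costs one detection
quantum per failed attempt wherever a blink is required.

Metrics are invariant to world geometry for a fixed turn sequence;
only route topology matters (verified by rescaling maps in the tests).

## Problem sizes and reproducibility

The test suite trains reduced decoders (10 trials/class, 7/3 split) for
pipeline tests and one full-scale decoder (70 trials/class, 50/20
split) for the end-to-end benchmark; Monte-Carlo checks use 10⁵
rotations. `scripts/acceptance.py` recomputes the architecture counts,
the feature-formula oracle, CSP pattern recovery, the perfect-decoder
loop, the strategy Monte-Carlo and the full-scale benchmark from a
single `--seed`. All randomness flows through seeded
`numpy.random.Generator` instances; training is single-threaded
deterministic.

## Known limitations

* The synthetic generator omits volume conduction, non-stationarity and
  real artifact morphology; benchmark accuracies (≈ 0.95–1.0 at ERD
  depth 0.8) are an upper bound, not a prediction for human subjects,
  whose reported accuracies for this kind of dry-electrode setup are
  far lower (≈ 0.6–0.8).
* The printed learning-rate schedule barely moves the recurrent
  weights; the classifier behaves close to a trained readout over a
  random bidirectional recurrent feature map. This is faithful to the
  configured schedule, and adequate on separable data, but it is not a
  fully converged BiLSTM.
* EDF export requires an external EDF writer; the package provides
  reading via MNE and an `mne.io.RawArray` bridge instead.
* False-positive blinks (spontaneous blinks misread as commands) are
  not modeled; `q` covers missed detections only.
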