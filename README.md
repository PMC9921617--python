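# minav

Motor-imagery EEG decoding and shared-control street navigation,
hardware-free.

`minav` is a complete, simulation-backed implementation of a self-paced
motor-imagery brain–computer interface (BCI) for navigating a virtual
street network. A user starts walking by imagining a sustained two-hand
flexion, switches to rotation with an eye blink, and steers with left-
or right-hand clenching imagery. Because a low-channel dry-electrode
motor-imagery decoder is inevitably noisy, the control layer adds
error-control strategies that trade time for safety. The package is
aimed at BCI researchers and students who want to study the *system*
— decoder plus control logic — without hardware: every stage runs on
synthetic EEG with the statistical structure the decoder assumes.

## What is inside

* **Synthetic EEG** (`minav.synthetic`) — labeled trials with 1/f
  background, mu (8–12 Hz) and beta (14–25 Hz) sensorimotor rhythms,
  event-related desynchronization (ERD) contralateral to the imagined
  hand, plus blink and artifact injection. Bit-reproducible under a
  fixed seed.
* **Signal core** (`minav.signals`) — mastoid re-referencing, causal
  Butterworth filtering, a 200 μV artifact gate and a 100 μV frontal
  blink detector (4–40 Hz filtered Fz).
* **FBCSP** (`minav.fbcsp`) — a 20-band filter bank (4 Hz-wide bands
  stepped by 2 Hz from 4–8 to 40–44 Hz plus a 4–40 Hz broadband) and
  per-band common spatial patterns: 6 channels → 120 band channels →
  40 CSP channels. CSP filters `w` solve `C_a w = λ (C_a + C_b) w` on
  trace-normalised average trial covariances.
* **Features** (`minav.features`) — five statistics (log-power,
  log-variance, zero-crossing rate, sum of absolute values,
  peak-to-peak) in sliding windows of 200 samples, hop 15 → a
  200-dimensional feature sequence.
* **Classifier** (`minav.classifier`) — a bidirectional LSTM sequence
  classifier written in numpy (Adam, learning rate 5e-5 decaying ×0.8
  per iteration, ≤ 50 iterations, L2 0.1, dropout 0.5), plus a logistic
  baseline behind the same contract.
* **Decoder** (`minav.decoder`) — end-to-end offline training of the
  flexion–rest (6 s epochs) and left–right (2 s epochs) decoders with a
  stratified 50/20 split, and online decoding from a 0.5 s-quantum ring
  buffer.
* **Navigation** (`minav.navigation`) — the switch/walk/rotation state
  machine over a street graph, low-level (blink-stop) and middle-level
  (stop in front of junctions) control, and three rotation strategies:
  NE (none), DC (double confirmation), EC (blink-veto error
  correction).
* **Closed-loop simulation** (`minav.simulate`) — an abstract or
  full-pipeline user following a route; per-rotation metrics
  `No_error`, `No_navigation_error`, `No_imagination`; analytic
  expectations `1/(2p−1)` (NE), `2/(2p−1)` (DC), `1` (EC with reliable
  blinks) with Monte-Carlo counterparts.

## Worked example

```python
from minav import (SyntheticConfig, generate_dataset, fit_offline,
                   DecoderConfig, TrainingConfig, UserModel, run_closed_loop)

# 1. a high-SNR synthetic subject: 70 trials/class, strong ERD
trials = generate_dataset(SyntheticConfig(trial_counts=70, erd_depth=0.8,
                                          rng_seed=7))

# 2. train both decoders on the 50/20 split
pipeline = fit_offline(trials, DecoderConfig(training=TrainingConfig(rng_seed=1)))
print("flexion-rest:", pipeline.flexion_rest.holdout["accuracy"])
print("left-right:  ", pipeline.left_right.holdout["accuracy"])

# 3. close the loop with an abstract user of 75% rotation accuracy
route = [("walk", 3), ("turn", "left"), ("walk", 2)]
result = run_closed_loop(UserModel(route=route, p=0.75), strategy="ec",
                         mode="middle", seed=0)
print("imaginations/rotation:", result.metrics.no_imagination)
print("wrong rotations:      ", result.metrics.no_navigation_error)
```

Output:

```
flexion-rest: 1.0
left-right:   1.0
imaginations/rotation: 1.0
wrong rotations:       0.0
```

The decoders separate strong synthetic ERD perfectly (real subjects are
far noisier — see `docs/methods.md`), and the error-correction strategy
turns a 75%-accurate rotation decoder into mistake-free navigation at
one imagination per turn, because every misread arrow is vetoed by a
blink and flipped.

The same workflow is available from the shell:

```bash
minav simulate-data --out data.h5 --erd-depth 0.8 --seed 7
minav train --data data.h5 --out model.h5 --seed 1
minav evaluate --model model.h5 --data data.h5
minav run-sim --strategy dc --level middle --route "walk:3,turn:left" --accuracy 0.8
minav compare-strategies --accuracies 0.6,0.7,0.8,0.9
```

## Scope

No hardware streaming, no external map services, no GUI: streams are
replayed from files or the generator, and the street network is a
simulated graph. The human-subject results of dry-electrode BCI studies
are not reproducible from synthetic data; this package reproduces the
*system* and its structural/qualitative behavior. See
`docs/methods.md` for the model details and limitations.
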