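# Methods

`nestscale` re-creates, in library form, the signal chain of an automated
nest-box scale that weighs small unrestrained birds (100–190 g falcons in
the motivating deployment) as they cross a corridor pan: raw 16 Hz
readings in, one tagged body-weight estimate per visit out. This note
records the models, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Acquisition model

The scale emits `sps = 16` readings per second, each carrying a device
stability flag. Readings are mapped to calibrated grams as

    w = gain · raw + offset − tare

where `(gain, offset)` come from an annual ordinary-least-squares fit
against certified reference masses (`fit_gain`), and the tare is tracked
continuously while the pan is empty.

**Tare tracking.** The tare is the robust location of a sliding window of
the last 64 gain-corrected empty-pan readings (≈ 4 s), computed by
iteratively reweighted least squares with Huber weights. The scale
estimate is frozen at 1.4826 × MAD of the window (tuning constant 1.345,
~95% Gaussian efficiency); iteration is warm-started from the previous
tare, capped at 10 iterations with a 10⁻⁶ g convergence tolerance. A
near-constant window (MAD ≈ 0) degenerates to the median. This follows
slow dirt-driven drift (~1 g/day) while one-sample wind spikes, even two
orders of magnitude above the tare, move the estimate by < 0.2 g.

**Segmentation.** A pattern opens at the first calibrated reading
strictly above `start_threshold` (50 g) and closes on the
`end_consecutive_below`-th (5th) consecutive reading at or below it,
after which every trailing below-threshold reading is stripped — so a
pattern never ends on an empty-pan sample. Sub-critical dips (runs of
below-threshold readings shorter than 5, e.g. the bird briefly lifting
off) are retained; readings above the valid range (50–300 g) are dropped
as wind artefacts, though they still break a below-threshold run — the
pan is plainly not empty. Tare
updating is suspended from open to close; a stream ending mid-pattern
yields a pattern flagged `truncated`, excluded from estimation by
default. Patterns must outlast one second (strictly more than 16
samples) to be valid.

Boundary conventions (the verbal rules leave them open): the valid range
is inclusive at both ends, opening requires strictly `> threshold`, and
`≤ threshold` counts toward closing. All are configurable.

## Features

Repetition counts are undefined for continuous values, so weights are
first quantized to a step (default 1 g, the scale's practical display
resolution; ties round away from zero). Nine variables summarize a
pattern: the two most frequent values and their counts
(`max_1/n_1`, `max_2/n_2`), the two longest runs of identical consecutive
values (`max_c1/nc_1`, `max_c2/nc_2`), and the sample count `n_el`.
Every tie resolves to the larger weight; with fewer than two distinct
values (or runs) the second-place slots are zero, keeping the vector
total. Because a resting bird's weight is the density mode of the
oscillating signal, these order statistics carry most of the usable
information at a cost low enough for a microcontroller.

## Estimation

Patterns with any stable readings are estimated by the arithmetic mean of
those readings (`stable_mean`); the device flags stability only when
consecutive readings agree to within its accuracy, so these estimates are
treated as unbiased and good to < 1 g. All-unstable patterns — the large
majority, ~85% — go through a 9-H-1 multilayer perceptron with logistic
activations; the output activation times a resample factor `R` gives
grams. Every estimate carries a stable/unstable tag.

The package ships the published 9-3-1 connection-weight set as a
round-trippable parameter file. Two of its conventions were never
published and are declared here explicitly:

* **Input scaling** — weight-valued features are divided by `R`,
  count-valued features by `n_max = 2048` samples (128 s). Consequently
  the shipped weights serve as a forward-pass verification fixture;
  gram-accurate estimation on new data requires retraining under this
  declared scaling, which the training module does.
* **`R` (resample factor)** — default 300 g, the top of the valid range,
  so the network output spans exactly the plausible weights.
* The published pseudocode's `1/(1+e^sum)` is a reversed sigmoid and its
  loop omits the per-neuron bias; the default forward pass uses the
  standard `σ(x) = 1/(1+e^(−x))` with biases (the weight table lists a
  bias row per neuron), and a `sigmoid_orientation="as_printed"` switch
  preserves the reversed form for fidelity experiments.

Accuracy against a manual capture is `100·(1 − |manual − est|/manual)`
percent, reported to two decimals.

## Training protocol

Mixed patterns (≥ 1 stable and ≥ 1 unstable reading) are the only
supervised source: target = mean of the stable readings, features = the
nine variables of the stable-removed remainder. Examples are split 50/50
at random; networks with 1–9 hidden neurons are fitted and the smallest
hidden layer within 0.1 percentage points of the best held-out accuracy
is selected.

Optimization is full-batch back-propagation on the MSE of the scaled
output (targets divided by `R`), with classic momentum: learning rate
0.2, momentum 0.9, up to 40,000 epochs, weights initialized U(−0.5, 0.5)
from the run seed, early stop when the training MSE has not improved for
500 epochs. Plain gradient descent at textbook rates was evaluated first
and under-converges badly here — the scaled targets live in a ~0.3-wide
sub-interval of the sigmoid range, so gradients are small — while
momentum reaches the linear-regression noise floor of the features in a
few seconds of CPU; the early-stop monitor is the training loss itself
(the protocol defines no separate validation split). All knobs live in
`TrainConfig`. Training is deterministic for a fixed seed.

## Synthetic visit simulator

The simulator is the package's ground-truth instrument; its defaults are
the study conditions everything else is tested under.

* **Visits**: true weight uniform in 100–190 g; duration lognormal with
  mean 23.18 s (log-sd 0.5); raw reading = tare + true weight + movement
  oscillation + N(0, 0.2²) read noise.
* **Movement**: AR(1) with coefficient 0.9 at 16 Hz (≈ 0.7 s correlation
  time) and stationary sd = amplitude/2 with amplitude 12 g — i.e. the
  configured amplitude is read as the ~2σ envelope of the excursions.
* **Stable plateaus**: with probability 0.15 a visit contains one quiet
  interval (uniform 2–6 s) where the oscillation is suppressed; only
  there can the stability tagger fire, reproducing the observed ~15%
  yield of stable patterns.
* **Stability tagger** (the real device rule is proprietary; this is an
  explicit stand-in): a sample is stable iff max−min of the trailing 8
  raw readings ≤ 1 g — "variation between consecutive measurements below
  the accuracy of the device".
* **Empty pan**: tare level 10 g, linear drift 1 g/day plus read noise;
  wind spikes as a Poisson process (2/h) with magnitudes 320–500 g,
  deliberately above the valid range.
* **Gaps**: exponential with 10 s mean (1 s minimum so every pattern can
  close). Idle time carries no information, so inter-visit gaps are kept
  short rather than colony-realistic.
* **Seasons**: per-bird linear(-plus-breakpoint) weight trends, females
  offset +15 g; the season log is *event-windowed* — only ~3 s of
  empty-pan context is stored around each visit and ticks jump between
  events, the way a field logger stores activity windows. Ticks remain
  absolute time, so day-resolved trend recovery is a pure pipeline
  exercise.

What the simulator does **not** emulate: prey-delivery steps inside a
visit, two birds on the pan, non-stationary movement spectra, RFID read
failures, temperature-dependent gain. Passing the synthetic end-to-end
checks therefore demonstrates that the pipeline recovers weights whose
distributional shape matches the generative model above — it is a
desk-scale counterpart of the field result, not a re-measurement of it.

## Problem sizes used in checks

The end-to-end synthetic study uses 7,856 visits (the size of the
historical stable-pattern corpus), of which ~15% yield mixed patterns
(~1,200 supervised examples, split 50/50). Under the default conditions
the trained H=3 network reaches ≈ 98.9% held-out mean accuracy and the
whole pipeline's MAE against ground truth is ≈ 1.8 g — within the 98.5%
/ 4 g operating figures of the original deployment. Seasonal trend
recovery is checked with 8 birds × 45 days × 2 visits/day. Oracle
equivalence checks use 10,000 random sequences (features) and 1,000
random toy streams (segmentation).

## Telemetry accounting

The raw-forwarding payload formula is implemented verbatim as published,
`16 · SPS · P_T · N_Bytes · N_msg`, although its leading 16 together with
`N_Bytes = 16` double-counts relative to the also-published figure of 371
bytes saved per average pattern. The reconciliation —
`round(SPS · P_T)` raw samples eliminated per pattern, one byte each,
giving 371 at 16 sps × 23.18 s — is provided side by side
(`bytes_saved_per_pattern`); neither reading silently corrects the other.
The packed uplink record (tick, centigram weight, flag byte, 8-byte nest
id) is 15 bytes, within the 16-byte message budget; weights are held at
0.01 g so packing round-trips losslessly. Radio energy is exposed only as
`bytes × time-per-byte × power` with user-supplied constants.

## Known limitations

* The shipped reference network cannot produce gram-accurate estimates
  because its original input scaling is unrecoverable; it is a fixture,
  not a field model.
* The IRLS tare assumes outlier contamination well under half the
  window; a sustained artefact (> ~30 s of continuous wind load below
  the start threshold) would drag the tare.
* Segmentation merges two visits separated by fewer than 5 below-
  threshold samples (~0.3 s) into one pattern.
* The stability tagger is a surrogate; real devices may flag differently,
  which would shift the stable/unstable mix but not the pipeline
  structure.
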