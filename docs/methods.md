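# Methods

## Problem setting

A worker wears five inertial measurement units (head, chest centre, upper
arm, thigh, calf). Each unit logs a triaxial accelerometer in g and a
triaxial gyroscope in deg/s; the fixed channel order is placement (HEAD,
CHEST, UPPER_ARM, THIGH, CALF) × modality (accel before gyro) × axis
(X, Y, Z), 30 columns. Decisions are made once per second: recognition maps
each one-second window to one of seven working postures (BT bending, KN
kneeling, MO climbing, SQ squatting, ST standing, WK walking, WO overhead
work), and all risk analysis consumes the resulting label-per-second stream.
UNKNOWN is an internal eighth code for unassessable seconds (sensor gaps);
it never enters risk statistics.

## Ingestion and alignment

Sensor CSVs are one file per placement with header
`epoch_ms,ax,ay,az,gx,gy,gz`. The nominal rate is inferred as the reciprocal
of the median inter-sample interval, rounded to integer Hz. Sessions are
built by placing all placements on a common grid — latest start to earliest
end, default 25 Hz — with per-channel linear interpolation. The logging rate
is an implementation default (25 Hz gives 25-sample windows at the 1-s
cadence), configurable; clock alignment assumes loosely synchronized sensor
clocks and does no cross-correlation sync. Grid points farther than two grid
steps from a source sample, and sessions missing placements (which are
zero-filled), are flagged in a per-sample gap mask; windows touching the
mask are dropped from recognition and the corresponding seconds are UNKNOWN
in predicted timelines.

## Synthetic worker simulator

Real recordings of this kind are rarely shareable, so the package generates
labeled sessions with the statistical structure the pipeline assumes. It is
a stand-in, not a biomechanical model.

**Schedule.** A semi-Markov chain over the seven postures. Run labels are
drawn so that realized *time* share tracks a target class mix (default the
imbalanced jobsite mix BT 14.1, KN 7.3, MO 0.8, SQ 0.3, ST 39.7, WK 18.0,
WO 19.7 percent; the printed table sums to 99.9% and is renormalized). Run
lengths are shifted-geometric with per-posture means (defaults 10–40 s,
static postures longer) truncated below at `dwell_min` (default 2 s);
geometric is the minimal-assumption dwell law and its memorylessness keeps
the holding-time detector exercised at all run lengths. Adjacent runs never
repeat a label; since forbidding immediate repeats skews the naive draw
probabilities, the draw weights are calibrated by fixed-point iteration so
the chain's stationary run frequencies match the target mix exactly (the
spread of realized shares at 36,000 s is a few percentage points).

**Emission.** Per second, each accelerometer channel reads the gravity
component of a hand-specified unit vector per (posture, placement) — chosen
so every class pair differs by ≥ 0.3 g on some channel, making the task
learnable by construction with the noise level (default sd 0.05 g)
controlling difficulty — plus Gaussian noise. Walking adds a gait sinusoid
(default 0.3 g at 2 Hz) to the thigh and calf vertical axes. Gyroscope
channels are Gaussian noise (default sd 5 deg/s) plus transients
proportional to the gravity reorientation rate across posture boundaries,
which are cross-faded over `transition_blend` (default 0.5 s). Climbing (MO)
is emitted as a per-second cycle of bend/stand/step micro-poses, reflecting
that ladder climbing is a composite motion — this deliberately makes MO
hard to separate from BT/ST/WK at a one-second horizon, reproducing the
qualitative confusability of composite classes. Everything is seeded and
bit-reproducible; worker *k* of a cohort uses `base_seed + k`.

**What passing tests on this generator do not show:** robustness to soft
tissue artifact, sensor drift, placement variation between workers, or
per-posture channel distributions of real work — none of which the emission
model contains. Results on synthetic cohorts demonstrate the pipeline's
correctness and its behaviour under the assumed structure, not field
accuracy.

## Recognition

Windows are non-overlapping 1-s slices (stride configurable); the split is
a seeded uniform shuffle partitioned 72/18/10 (largest-remainder rounding)
at the window level — matching a protocol in which all workers' data are
pooled before splitting; a worker-level split can be had by windowing
sessions separately and splitting the session list. Channels are
standardized with mean/sd fitted on the training subset only (sd floored at
1e-6); the stats object is fingerprinted in tests to assert no leakage.

Two models:

* **Baseline** — multinomial logistic regression (scikit-learn, L2, C=10)
  on 60 summary features (per-channel mean and sd per window). Serves as the
  conventional-model reference.
* **Convolutional-recurrent network** — one 1-D convolution along the time
  axis over all 30 channels (64 filters, kernel 5, stride 1, ReLU), two
  stacked LSTM layers (width 64), softmax over the classes from the final
  timestep. Trained with Adam (lr 3e-3, batch 64) on cross-entropy with
  early stopping on validation macro F1 (patience 5 by default). One
  architectural source describes a single recurrent layer and another two;
  the default is two with depth exposed in config. The network and its
  reverse-mode autodiff are implemented in numpy inside the package
  (float64, fully seeded → bit-identical runs) and gradient-checked against
  central finite differences in the test suite.

Argmax ties break toward the lowest index in the fixed label order
(BT < KN < MO < SQ < ST < WK < WO). Metrics: one-vs-rest precision, recall
and F1 with the 0-convention for empty denominators (this affects rare
classes like SQ), overall accuracy, macro F1 as the unweighted mean over
the seven classes, and a confusion matrix with row-normalized counterpart
(rows = true labels). The evaluation protocol repeats
split→normalize→train→test over five seeds and reports mean and sd.

**Permutation importance.** For each of the 30 channels: permute that
channel's values across all windows and time steps of the test subset
(seeded), re-evaluate, record baseline minus permuted accuracy; repeat five
rounds and rank by mean drop. The drop in overall accuracy is the importance
metric; the helper that permutes all channels at once checks that accuracy
then collapses to the majority-class share. All 30 channels are always
evaluated.

## Ergonomic assessment

**Streaming MHT detection.** The detector keeps the current run label and a
counter, resetting on any label change or UNKNOWN. A posture with threshold
*T* alarms at the first second the counter reaches *T*+1. Under
`ONCE_PER_RUN` (default — frequent repeated alarms annoy wearers) that is
the only alarm per run; under `REPEAT_EVERY_THRESHOLD` it fires again at
counts 2*T*+1, 3*T*+1, …. Streaming output is property-tested identical to
offline recomputation from the run decomposition. Threshold values for
specific postures are workplace parameters; the shipped defaults (BT 60 s,
WO 60 s, SQ 60 s, KN 120 s; ST, WK, MO exempt) are an illustrative table,
fully overridable. MO is exempt and excluded from the awkward set by
default because climbing is composite motion rather than a static hold.

**Periodic individual assessment.** The timeline is partitioned into
windows (default 1800 s; the final partial window is assessed over its
actual length; windows < 60 s are rejected as meaningless). Runs are clipped
at window boundaries — a 70-s hold split 40/30 contributes max-holds of 40
and 30 to adjacent windows — keeping windows independent. Per posture and
window: seconds held, breach count (runs longer than the threshold), breach
total duration (full duration of breaching runs), max hold, occurrences per
minute (run *starts* per minute — "occurrence" is read as the start of a
new bout), and proportion. The proportion denominator is the assessed
(non-UNKNOWN) seconds, with UNKNOWN seconds reported separately; posture
seconds plus UNKNOWN seconds always sum to the window length. OWAS-style
action categories come from proportion cut-points per awkward posture
(defaults p1=0.10, p2=0.30, p3=0.50; bands are parameters, not normative
claims): AC1 below p1, then AC2, AC3, AC4 with left-closed upper bands
(a share exactly at a cut-point takes the higher category). Non-awkward
postures are always AC1. Correction suggestions rank postures by category,
then proportion, then name. Full OWAS scoring from joint angles is out of
scope — the mapping consumes recognized posture classes, not measured
angles.

**Jobsite aggregation.** "Average number of detected awkward postures" is
interpreted as mean awkward posture-seconds per worker — with one
recognition per second the two readings coincide. Interval index is
`window_start_epoch // interval_length`; workers contribute only to
intervals they cover, so per-interval worker counts are interval-specific,
and daily per-trade proportions weight every assessed second equally.
Urgency ranks trades by worst per-posture category, then daily awkward
proportion, then name; the peak interval is the argmax of summed awkward
seconds (earliest on ties). Outputs contain trades and counts only, never
worker identifiers — asserted by a schema scan in tests.

## Numerical and testing choices

Randomized suites use fixed seeds (hypothesis runs derandomized); every
stochastic claim is tested across seeds where cheap. Independent brute-force
oracles — literal run scans, naive metric recounts, raw-timeline
aggregation — live in the test tree and share no code with the
implementation. The classifier-recovery checks run on a 4-worker,
400-s-per-worker cohort (1,600 windows) at the default noise level with the
network capped at 10 epochs; these sizes keep the full suite fast while
leaving the accuracy criteria comfortably met, and scale up linearly if
larger cohorts are wanted.

## Known limitations

- The emission model is synthetic; no claim transfers to field data
  without retraining and re-evaluation on real recordings.
- MHT thresholds and OWAS bands ship as illustrative defaults, not as the
  published ergonomic tables, and must be configured for real use.
- The window-level split lets windows from one worker appear in both train
  and test; for deployment-style evaluation use a worker-level split.
- The one-second, non-overlapping windowing discards sub-second dynamics;
  stride is configurable but untested below 1 s.
- Mobile/cloud delivery (apps, dashboards, sync) is out of scope; reports
  are JSON and plain text.
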