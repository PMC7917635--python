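# posturekit

Wearable-IMU posture recognition and musculoskeletal-disorder (MSD) risk
assessment for physically demanding work, with construction trades as the
motivating setting.

Workers who spend long stretches bending, kneeling, squatting or working
overhead accumulate injury risk that neither they nor their supervisors can
see. `posturekit` turns recordings from five body-worn inertial measurement
units — head, chest centre, upper arm, thigh and calf, each streaming a
triaxial accelerometer (g) and gyroscope (deg/s), 30 channels in all — into
per-second posture labels and then into actionable ergonomic feedback:

- **Posture recognition.** Each one-second window of the 30-channel matrix is
  classified into one of seven working postures: BT bending, KN kneeling,
  MO climbing, SQ squatting, ST standing, WK walking, WO overhead work.
  Two classifiers are provided: a logistic-regression baseline on per-window
  channel summaries, and a convolutional-recurrent network — one 1-D
  convolution over the window, two stacked LSTM layers, softmax readout —
  implemented in numpy with the package's own reverse-mode autodiff.
- **Real-time Maximum Holding Time (MHT) alarms.** A streaming detector
  counts consecutive identical postures and alarms the second the count
  exceeds the posture's holding-time limit, while the posture is still held.
- **Periodic individual assessment.** Per 30-minute window and posture:
  breach counts and durations, maximum hold, run frequency per minute, time
  proportion, and an OWAS-style action category AC1 (no action) … AC4
  (correct immediately) from the proportion.
- **Jobsite aggregation.** Individual assessments pooled per trade and
  interval into an anonymous daily manager view: mean awkward seconds per
  worker, per-trade proportions, correction-urgency ranking, peak interval.
- **Channel importance.** Feature permutation: shuffle one channel across
  the test subset and measure the accuracy drop.
- **Synthetic worker simulator.** Field IMU data of this kind is rarely
  shareable, so the package ships a generator producing labeled sessions
  with the structure the pipeline assumes: a semi-Markov posture schedule
  with a strongly imbalanced class mix (ST 39.7%, WO 19.7%, WK 18.0%,
  BT 14.1%, KN 7.3%, MO 0.8%, SQ 0.3%) and geometric dwell times, emitted
  into channels via posture-specific gravity orientations plus noise.

## Worked example

```python
from posturekit import (
    PostureScheduleSpec, simulate_cohort, make_windows, concat_datasets,
    split_dataset, fit_normalization, apply_normalization,
    train_cln, evaluate,
)

cohort = simulate_cohort(4, spec=PostureScheduleSpec(duration=400), base_seed=0)
ds = concat_datasets([make_windows(s, t) for s, t in cohort])
train, val, test = split_dataset(ds, seed=0)          # 72% / 18% / 10%
stats = fit_normalization(train)
model = train_cln(apply_normalization(train, stats),
                  apply_normalization(val, stats),
                  config={"max_epochs": 10, "patience": 3}, seed=0)
res = evaluate(model, apply_normalization(test, stats))
print(f"accuracy {res.overall_accuracy:.3f}, macro F1 {res.macro_f1:.3f}")
```

prints

```
accuracy 1.000, macro F1 0.857
```

Accuracy is the fraction of correctly recognized seconds; macro F1 averages
per-class F1 without support weighting, so it drops when a rare class (here
SQ, 0.3% of time) has too few test windows to be scored — the class-imbalance
effect the metric is there to expose. The `examples/` directory has one
short script per capability: simulation, training, streaming alarms,
individual assessment, jobsite reports, channel importance. A thin CLI
(`posturekit simulate|train|evaluate|predict|assess|site|importance|config`)
wraps the same functions for shell use.

## Layout

- `src/posturekit/` — library: `io_motion` (CSV I/O, alignment),
  `synthetic` (simulator), `recognition` (windowing, models, metrics,
  importance), `nn` (autodiff core), `assessment` (MHT + periodic),
  `jobsite` (aggregation), `reports`, `config`, `cli`.
- `tests/` — unit, property and end-to-end suites with independent
  brute-force oracles.
- `docs/methods.md` — models, parameters, design choices and limitations.
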