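"""Train both posture classifiers and compare them on held-out windows.

Windows are one second of the 30-channel matrix; the pooled cohort is split
72/18/10 into train/validation/test, channels standardized with train-fitted
statistics, and two models trained: a logistic-regression baseline on
per-window mean/sd summaries, and the convolutional-recurrent network (1-D
convolution + two LSTM layers + softmax) that reads the raw window.
"""

from posturekit import (
    EmissionSpec,
    PostureScheduleSpec,
    apply_normalization,
    concat_datasets,
    evaluate,
    fit_normalization,
    make_windows,
    simulate_cohort,
    split_dataset,
    train_baseline,
    train_cln,
)

cohort = simulate_cohort(
    4, spec=PostureScheduleSpec(duration=400), espec=EmissionSpec(), base_seed=0
)
ds = concat_datasets([make_windows(s, t) for s, t in cohort])
print(f"{len(ds)} one-second windows from {len(cohort)} workers")

train, val, test = split_dataset(ds, seed=0)
stats = fit_normalization(train)
train_n, val_n, test_n = (apply_normalization(d, stats) for d in (train, val, test))

baseline = train_baseline(train_n, val_n, seed=0)
rb = evaluate(baseline, test_n)
print(f"baseline:  accuracy {rb.overall_accuracy:.3f}, macro F1 {rb.macro_f1:.3f}")

cln = train_cln(train_n, val_n, config={"max_epochs": 10, "patience": 3}, seed=0)
rc = evaluate(cln, test_n)
print(f"conv-LSTM: accuracy {rc.overall_accuracy:.3f}, macro F1 {rc.macro_f1:.3f}")

# Accuracy counts correctly recognized seconds; macro F1 averages per-class
# F1 without weighting, so it drops when rare classes (SQ, MO) are missed
# even if overall accuracy stays high.
for lab, (p, r, f1) in rc.per_class.items():
    print(f"  {lab.value}: precision {p:.2f}, recall {r:.2f}, F1 {f1:.2f}")
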