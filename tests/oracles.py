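"""Brute-force reference implementations used only by tests.

These recompute alarm streams, per-window statistics, jobsite aggregates and
classification metrics with the most literal possible loops, independent of
the package's code paths, so agreement is a meaningful check.
"""

from __future__ import annotations

import numpy as np

from posturekit.assessment import ActionCategory, AlarmPolicy, MhtRuleSet, OwasRuleSet
from posturekit.types import LABEL_ORDER, PostureLabel, PostureTimeline


def brute_runs(labels):
    """(label, offset, length) runs by literal scanning."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] is labels[i]:
            j += 1
        out.append((labels[i], i, j - i))
        i = j
    return out


def brute_alarms(timeline: PostureTimeline, rules: MhtRuleSet):
    """Alarm (posture, trigger_epoch, held, threshold) tuples from runs."""
    start = timeline.start_epoch_s
    out = []
    for lab, off, length in brute_runs(timeline.labels):
        if lab is PostureLabel.UNKNOWN:
            continue
        thr = rules.thresholds.get(lab)
        if thr is None:
            continue
        if rules.alarm_policy is AlarmPolicy.ONCE_PER_RUN:
            if length > thr:
                out.append((lab, start + off + thr, thr + 1, thr))
        else:
            k = 1
            while k * thr + 1 <= length:
                out.append((lab, start + off + k * thr, k * thr + 1, thr))
                k += 1
    return out


def brute_window_stats(labels, mht: MhtRuleSet, owas: OwasRuleSet):
    """Per-posture Table-of-statistics for one window's label list."""
    runs = brute_runs(labels)
    stats = {}
    unknown = sum(1 for l in labels if l is PostureLabel.UNKNOWN)
    assessed = len(labels) - unknown
    minutes = len(labels) / 60.0
    for lab in LABEL_ORDER:
        mine = [r for r in runs if r[0] is lab]
        seconds = sum(r[2] for r in mine)
        thr = mht.thresholds.get(lab)
        breaches = [r for r in mine if thr is not None and r[2] > thr]
        prop = seconds / assessed if assessed else 0.0
        if lab in owas.awkward_set and lab in owas.bands:
            p1, p2, p3 = owas.bands[lab]
            cat = (ActionCategory.AC1 if prop < p1 else
                   ActionCategory.AC2 if prop < p2 else
                   ActionCategory.AC3 if prop < p3 else ActionCategory.AC4)
        else:
            cat = ActionCategory.AC1
        stats[lab] = {
            "seconds": seconds,
            "breach_count": len(breaches),
            "breach_total_duration": sum(r[2] for r in breaches),
            "max_hold": max((r[2] for r in mine), default=0),
            "run_count": len(mine),
            "occurrences_per_minute": len(mine) / minutes,
            "proportion": prop,
            "owas_category": cat,
        }
    return stats, unknown


def brute_metrics(true: np.ndarray, pred: np.ndarray, n_classes: int):
    """Naive recount of precision/recall/F1/accuracy/confusion."""
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(true, pred):
        conf[t, p] += 1
    per = {}
    f1s = []
    for c in range(n_classes):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per[c] = (prec, rec, f1)
        f1s.append(f1)
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    return per, acc, float(np.mean(f1s)), conf
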