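"""Individual ergonomic risk assessment from posture timelines.

Two assessments operate on the per-second label stream:

* **Maximum Holding Time (MHT)** — a streaming detector counts consecutive
  identical postures and raises an alarm the moment the count exceeds the
  posture's holding-time limit, so a worker can correct a prolonged static
  posture in real time.
* **Periodic profile** — every assessment window (default 30 min), per-posture
  exposure statistics are computed (breach counts and durations, maximum hold,
  run frequency, time proportion) and each posture's time share is mapped to
  an OWAS-style action category AC1 (no action needed) … AC4 (corrective
  action needed immediately).

Holding-time limits for specific postures are workplace parameters; the
defaults shipped here are an illustrative table, not a normative claim, and
every threshold and band is overridable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .types import DEFAULT_AWKWARD_SET, LABEL_ORDER, PostureLabel, PostureTimeline

#: Sentinel for postures never subject to holding-time alarms.
EXEMPT = None


class AlarmPolicy(enum.Enum):
    ONCE_PER_RUN = "ONCE_PER_RUN"
    REPEAT_EVERY_THRESHOLD = "REPEAT_EVERY_THRESHOLD"


@dataclass
class MhtRuleSet:
    """Holding-time limits (seconds) per posture; ``None`` means exempt.

    Dynamic or neutral postures (standing, walking) and composite motion
    (climbing) default to exempt. The default numbers are illustrative.
    """

    thresholds: dict[PostureLabel, int | None] = field(
        default_factory=lambda: {
            PostureLabel.BT: 60,
            PostureLabel.KN: 120,
            PostureLabel.SQ: 60,
            PostureLabel.WO: 60,
            PostureLabel.ST: EXEMPT,
            PostureLabel.WK: EXEMPT,
            PostureLabel.MO: EXEMPT,
        }
    )
    alarm_policy: AlarmPolicy = AlarmPolicy.ONCE_PER_RUN

    def __post_init__(self) -> None:
        for lab, thr in self.thresholds.items():
            if thr is not None and thr < 1:
                raise ValueError(f"threshold for {lab.value} must be >= 1 s")

    def threshold(self, label: PostureLabel) -> int | None:
        return self.thresholds.get(label, EXEMPT)


class ActionCategory(enum.IntEnum):
    """OWAS-style action categories, ordered by urgency."""

    AC1 = 1  # no corrective action needed
    AC2 = 2  # corrective action in the near future
    AC3 = 3  # corrective action as soon as possible
    AC4 = 4  # corrective action immediately


@dataclass
class OwasRuleSet:
    """Proportion cut-points mapping a posture's time share to a category.

    ``bands[posture] = (p1, p2, p3)``: share < p1 is AC1, [p1, p2) AC2,
    [p2, p3) AC3, >= p3 AC4. Postures outside ``awkward_set`` are always AC1.
    """

    bands: dict[PostureLabel, tuple[float, float, float]] = field(
        default_factory=lambda: {
            lab: (0.10, 0.30, 0.50) for lab in DEFAULT_AWKWARD_SET
        }
    )
    awkward_set: frozenset[PostureLabel] = DEFAULT_AWKWARD_SET

    def __post_init__(self) -> None:
        for lab, (p1, p2, p3) in self.bands.items():
            if not (0 < p1 < p2 < p3 < 1):
                raise ValueError(f"bands for {lab.value} must satisfy 0<p1<p2<p3<1")


@dataclass(frozen=True)
class Alarm:
    """One holding-time breach event."""

    worker_id: str
    posture: PostureLabel
    run_start_epoch: int  # s
    trigger_epoch: int  # s
    held_seconds_at_trigger: int
    threshold: int

    def to_record(self) -> dict:
        return {
            "worker_id": self.worker_id,
            "posture": self.posture.value,
            "run_start_epoch": self.run_start_epoch,
            "trigger_epoch": self.trigger_epoch,
            "held_seconds_at_trigger": self.held_seconds_at_trigger,
            "threshold": self.threshold,
        }


def runs_of(timeline: PostureTimeline) -> list[tuple[PostureLabel, int, int]]:
    """Maximal runs of identical labels as ``(label, start_epoch_s, length_s)``.

    Concatenating the runs reconstructs the timeline; UNKNOWN seconds break
    surrounding runs and are emitted as their own runs.
    """
    out: list[tuple[PostureLabel, int, int]] = []
    start_s = timeline.start_epoch_s
    cur = timeline.labels[0]
    run_start = 0
    for i, lab in enumerate(timeline.labels[1:], start=1):
        if lab is not cur:
            out.append((cur, start_s + run_start, i - run_start))
            cur = lab
            run_start = i
    out.append((cur, start_s + run_start, len(timeline.labels) - run_start))
    return out


class MhtStreamDetector:
    """Incremental holding-time detector.

    Feed labels one per second via :meth:`push`; alarms are returned as they
    trigger. The online output is identical to recomputing offline from the
    full timeline (see :func:`detect_mht_offline`).
    """

    def __init__(self, rules: MhtRuleSet, worker_id: str = "", start_epoch_s: int = 0):
        self.rules = rules
        self.worker_id = worker_id
        self._epoch = start_epoch_s
        self._cur: PostureLabel | None = None
        self._count = 0
        self._run_start = start_epoch_s

    def push(self, label: PostureLabel) -> list[Alarm]:
        if not isinstance(label, PostureLabel):
            raise ValueError(f"not a posture label: {label!r}")
        if label is not self._cur or label is PostureLabel.UNKNOWN:
            self._cur = label
            self._count = 0
            self._run_start = self._epoch
        self._count += 1
        alarms: list[Alarm] = []
        thr = self.rules.threshold(label)
        if label is not PostureLabel.UNKNOWN and thr is not None and self._count > thr:
            over = self._count - thr - 1
            fire = (
                self._count == thr + 1
                if self.rules.alarm_policy is AlarmPolicy.ONCE_PER_RUN
                else over % thr == 0
            )
            if fire:
                alarms.append(
                    Alarm(
                        worker_id=self.worker_id,
                        posture=label,
                        run_start_epoch=self._run_start,
                        trigger_epoch=self._epoch,
                        held_seconds_at_trigger=self._count,
                        threshold=thr,
                    )
                )
        self._epoch += 1
        return alarms


def detect_mht_stream(
    labels: Iterable[PostureLabel],
    rules: MhtRuleSet,
    worker_id: str = "",
    start_epoch_s: int = 0,
) -> Iterator[Alarm]:
    """Run the streaming detector over a label iterable, yielding alarms."""
    det = MhtStreamDetector(rules, worker_id=worker_id, start_epoch_s=start_epoch_s)
    for lab in labels:
        yield from det.push(lab)


def detect_mht_offline(timeline: PostureTimeline, rules: MhtRuleSet) -> list[Alarm]:
    """Convenience wrapper: stream the whole timeline and collect alarms."""
    return list(
        detect_mht_stream(
            timeline.labels, rules,
            worker_id=timeline.worker_id,
            start_epoch_s=timeline.start_epoch_s,
        )
    )


@dataclass
class PostureStats:
    """Per-posture exposure statistics within one assessment window."""

    seconds: int = 0
    breach_count: int = 0
    breach_total_duration: int = 0
    max_hold: int = 0
    run_count: int = 0
    occurrences_per_minute: float = 0.0
    proportion: float = 0.0
    owas_category: ActionCategory = ActionCategory.AC1


@dataclass
class IndividualAssessment:
    """One worker's posture profile over one assessment window."""

    worker_id: str
    trade: str
    window_start_epoch: int  # s
    window_length: int  # s actually assessed (final window may be shorter)
    per_posture: dict[PostureLabel, PostureStats]
    unknown_seconds: int
    correction_suggestions: list[PostureLabel]

    @property
    def assessed_seconds(self) -> int:
        return self.window_length - self.unknown_seconds

    def awkward_seconds(self, awkward_set: frozenset[PostureLabel] = DEFAULT_AWKWARD_SET) -> int:
        return sum(st.seconds for lab, st in self.per_posture.items() if lab in awkward_set)

    def to_dict(self) -> dict:
        return {
            "worker_id": self.worker_id,
            "trade": self.trade,
            "window_start_epoch": self.window_start_epoch,
            "window_length": self.window_length,
            "unknown_seconds": self.unknown_seconds,
            "per_posture": {
                lab.value: {
                    "seconds": st.seconds,
                    "breach_count": st.breach_count,
                    "breach_total_duration": st.breach_total_duration,
                    "max_hold": st.max_hold,
                    "run_count": st.run_count,
                    "occurrences_per_minute": st.occurrences_per_minute,
                    "proportion": st.proportion,
                    "owas_category": f"AC{int(st.owas_category)}",
                }
                for lab, st in self.per_posture.items()
            },
            "correction_suggestions": [lab.value for lab in self.correction_suggestions],
        }

    @staticmethod
    def from_dict(d: dict) -> "IndividualAssessment":
        per = {}
        for code, st in d["per_posture"].items():
            per[PostureLabel(code)] = PostureStats(
                seconds=st["seconds"],
                breach_count=st["breach_count"],
                breach_total_duration=st["breach_total_duration"],
                max_hold=st["max_hold"],
                run_count=st["run_count"],
                occurrences_per_minute=st["occurrences_per_minute"],
                proportion=st["proportion"],
                owas_category=ActionCategory(int(st["owas_category"][2])),
            )
        return IndividualAssessment(
            worker_id=d["worker_id"],
            trade=d["trade"],
            window_start_epoch=d["window_start_epoch"],
            window_length=d["window_length"],
            per_posture=per,
            unknown_seconds=d["unknown_seconds"],
            correction_suggestions=[PostureLabel(c) for c in d["correction_suggestions"]],
        )


def owas_action_category(
    proportion: float, posture: PostureLabel, owas: OwasRuleSet
) -> ActionCategory:
    """Map a posture's time share to an action category.

    Bands are left-closed at the top: a share exactly at a cut-point falls in
    the higher category. Non-awkward postures are always AC1.
    """
    if not (0.0 <= proportion <= 1.0):
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    if posture not in owas.awkward_set or posture not in owas.bands:
        return ActionCategory.AC1
    p1, p2, p3 = owas.bands[posture]
    if proportion < p1:
        return ActionCategory.AC1
    if proportion < p2:
        return ActionCategory.AC2
    if proportion < p3:
        return ActionCategory.AC3
    return ActionCategory.AC4


def assess_individual(
    timeline: PostureTimeline,
    mht: MhtRuleSet | None = None,
    owas: OwasRuleSet | None = None,
    window_length: int = 1800,
) -> list[IndividualAssessment]:
    """Partition a timeline into assessment windows and profile each.

    Runs are clipped at window boundaries (a hold spanning two windows counts
    separately in each), keeping windows independent. The final partial
    window is assessed over its actual length. UNKNOWN seconds are excluded
    from the proportion denominator and reported separately.
    """
    mht = mht if mht is not None else MhtRuleSet()
    owas = owas if owas is not None else OwasRuleSet()
    if window_length < 60:
        raise ValueError("window_length must be >= 60 s")

    out: list[IndividualAssessment] = []
    n = len(timeline.labels)
    start_s = timeline.start_epoch_s
    for w0 in range(0, n, window_length):
        w1 = min(w0 + window_length, n)
        seg = PostureTimeline(
            worker_id=timeline.worker_id,
            trade=timeline.trade,
            start_epoch=(start_s + w0) * 1000,
            labels=timeline.labels[w0:w1],
            source=timeline.source,
        )
        seg_len = w1 - w0
        runs = runs_of(seg)
        stats = {lab: PostureStats() for lab in LABEL_ORDER}
        unknown = 0
        for lab, rstart, rlen in runs:
            if lab is PostureLabel.UNKNOWN:
                unknown += rlen
                continue
            st = stats[lab]
            st.seconds += rlen
            st.run_count += 1
            st.max_hold = max(st.max_hold, rlen)
            thr = mht.threshold(lab)
            if thr is not None and rlen > thr:
                st.breach_count += 1
                st.breach_total_duration += rlen
        assessed = seg_len - unknown
        minutes = seg_len / 60.0
        for lab, st in stats.items():
            st.occurrences_per_minute = st.run_count / minutes
            st.proportion = st.seconds / assessed if assessed > 0 else 0.0
            st.owas_category = owas_action_category(st.proportion, lab, owas)
        suggestions = sorted(
            (lab for lab in LABEL_ORDER if stats[lab].seconds > 0),
            key=lambda lab: (-int(stats[lab].owas_category), -stats[lab].proportion, lab.value),
        )
        out.append(
            IndividualAssessment(
                worker_id=timeline.worker_id,
                trade=timeline.trade,
                window_start_epoch=start_s + w0,
                window_length=seg_len,
                per_posture=stats,
                unknown_seconds=unknown,
                correction_suggestions=suggestions,
            )
        )
    return out


def write_alarm_log(alarms: Sequence[Alarm], path) -> None:
    """Append alarms to a line-delimited JSON event log."""
    with open(path, "a") as fh:
        for a in alarms:
            fh.write(json.dumps(a.to_record()) + "\n")
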