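"""Jobsite-level synthesis of individual assessments.

Managers care about trades and times of day, not individuals: the aggregator
pools each trade's workers within every assessment interval (default 30 min),
reports the mean awkward-posture seconds per worker, builds the daily
per-trade exposure profile, assigns OWAS-style action categories from daily
proportions, and ranks trades by correction urgency. Outputs carry trade
labels and counts only — never worker identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assessment import ActionCategory, IndividualAssessment, OwasRuleSet, owas_action_category
from .types import LABEL_ORDER, PostureLabel


@dataclass
class TradeDaily:
    """One trade's pooled daily exposure."""

    n_workers: int
    assessed_seconds: int
    awkward_seconds: int
    awkward_proportion: float
    per_posture_proportion: dict[PostureLabel, float]
    owas_category: dict[PostureLabel, ActionCategory]
    worst_category: ActionCategory


@dataclass
class JobsiteAssessment:
    """Daily jobsite view: per-trade per-interval means and daily summaries."""

    interval_length: int
    intervals: list[int]  # sorted interval indices present
    # (trade, interval index) -> mean awkward seconds per worker in that interval
    mean_awkward_by_trade_interval: dict[tuple[str, int], float]
    n_workers_by_trade_interval: dict[tuple[str, int], int]
    trades: dict[str, TradeDaily]
    urgency_rank: list[str]  # trades, most urgent first
    peak_interval: int
    peak_trade: str

    def to_dict(self) -> dict:
        return {
            "interval_length": self.interval_length,
            "intervals": self.intervals,
            "mean_awkward_by_trade_interval": {
                f"{t}:{i}": v for (t, i), v in self.mean_awkward_by_trade_interval.items()
            },
            "n_workers_by_trade_interval": {
                f"{t}:{i}": v for (t, i), v in self.n_workers_by_trade_interval.items()
            },
            "trades": {
                t: {
                    "n_workers": d.n_workers,
                    "assessed_seconds": d.assessed_seconds,
                    "awkward_seconds": d.awkward_seconds,
                    "awkward_proportion": d.awkward_proportion,
                    "per_posture_proportion": {
                        lab.value: p for lab, p in d.per_posture_proportion.items()
                    },
                    "owas_category": {
                        lab.value: f"AC{int(c)}" for lab, c in d.owas_category.items()
                    },
                    "worst_category": f"AC{int(d.worst_category)}",
                }
                for t, d in self.trades.items()
            },
            "urgency_rank": self.urgency_rank,
            "peak_interval": self.peak_interval,
            "peak_trade": self.peak_trade,
        }


def aggregate_jobsite(
    assessments: Iterable[IndividualAssessment],
    interval_length: int = 1800,
    owas: OwasRuleSet | None = None,
) -> JobsiteAssessment:
    """Pool individual assessments into the daily jobsite view.

    Interval index is ``window_start_epoch // interval_length``. Workers
    present for only part of the day contribute only to intervals they cover,
    so per-interval worker counts are interval-specific.
    """
    owas = owas if owas is not None else OwasRuleSet()
    assessments = list(assessments)
    if not assessments:
        raise ValueError("no assessments to aggregate")

    trade_of: dict[str, str] = {}
    seen: set[tuple[str, int]] = set()
    awkward = owas.awkward_set

    # (trade, interval) accumulators
    awk_sum: dict[tuple[str, int], int] = {}
    n_workers: dict[tuple[str, int], int] = {}
    # per-trade daily accumulators
    trade_sec: dict[str, dict[PostureLabel, int]] = {}
    trade_assessed: dict[str, int] = {}
    trade_worker_ids: dict[str, set[str]] = {}

    for a in assessments:
        if a.worker_id in trade_of and trade_of[a.worker_id] != a.trade:
            raise ValueError(f"conflicting trade for worker {a.worker_id}")
        trade_of[a.worker_id] = a.trade
        interval = a.window_start_epoch // interval_length
        key = (a.worker_id, interval)
        if key in seen:
            raise ValueError(f"worker {a.worker_id} has multiple assessments in interval {interval}")
        seen.add(key)

        tkey = (a.trade, interval)
        awk_sum[tkey] = awk_sum.get(tkey, 0) + a.awkward_seconds(awkward)
        n_workers[tkey] = n_workers.get(tkey, 0) + 1

        sec = trade_sec.setdefault(a.trade, {lab: 0 for lab in LABEL_ORDER})
        for lab, st in a.per_posture.items():
            sec[lab] += st.seconds
        trade_assessed[a.trade] = trade_assessed.get(a.trade, 0) + a.assessed_seconds
        trade_worker_ids.setdefault(a.trade, set()).add(a.worker_id)

    mean_awk = {k: awk_sum[k] / n_workers[k] for k in awk_sum}
    intervals = sorted({i for (_, i) in awk_sum})

    trades: dict[str, TradeDaily] = {}
    for trade in sorted(trade_sec):
        sec = trade_sec[trade]
        assessed = trade_assessed[trade]
        props = {
            lab: (sec[lab] / assessed if assessed > 0 else 0.0) for lab in LABEL_ORDER
        }
        cats = {lab: owas_action_category(props[lab], lab, owas) for lab in LABEL_ORDER}
        awk_sec = sum(sec[lab] for lab in awkward)
        trades[trade] = TradeDaily(
            n_workers=len(trade_worker_ids[trade]),
            assessed_seconds=assessed,
            awkward_seconds=awk_sec,
            awkward_proportion=awk_sec / assessed if assessed > 0 else 0.0,
            per_posture_proportion=props,
            owas_category=cats,
            worst_category=max(cats.values()),
        )

    urgency = rank_trade_names(trades)
    peak_interval, _ = peak_exposure_from_table(awk_sum, intervals)
    # peak trade = highest daily awkward proportion, ties broken by name
    peak_trade = min(
        sorted(trades), key=lambda t: (-trades[t].awkward_proportion, t)
    )

    return JobsiteAssessment(
        interval_length=interval_length,
        intervals=intervals,
        mean_awkward_by_trade_interval=mean_awk,
        n_workers_by_trade_interval=n_workers,
        trades=trades,
        urgency_rank=urgency,
        peak_interval=peak_interval,
        peak_trade=peak_trade,
    )


def rank_trade_names(trades: Mapping[str, TradeDaily]) -> list[str]:
    """Trades ordered by (worst category desc, awkward proportion desc, name)."""
    return sorted(
        trades,
        key=lambda t: (-int(trades[t].worst_category), -trades[t].awkward_proportion, t),
    )


def rank_trades(jobsite: JobsiteAssessment) -> list[tuple[str, ActionCategory, float]]:
    """Urgency ranking as ``(trade, worst category, daily awkward proportion)``."""
    return [
        (t, jobsite.trades[t].worst_category, jobsite.trades[t].awkward_proportion)
        for t in rank_trade_names(jobsite.trades)
    ]


def peak_exposure_from_table(
    awk_sum: Mapping[tuple[str, int], float], intervals: Sequence[int]
) -> tuple[int, float]:
    totals = {i: 0.0 for i in intervals}
    for (_, i), v in awk_sum.items():
        totals[i] += v
    if not totals:
        raise ValueError("no intervals")
    best = min(intervals, key=lambda i: (-totals[i], i))
    return best, totals[best]


def peak_exposure(jobsite: JobsiteAssessment) -> tuple[int, float]:
    """Interval with the highest total awkward seconds across trades
    (earliest interval on ties)."""
    totals = {i: 0.0 for i in jobsite.intervals}
    for (t, i), mean in jobsite.mean_awkward_by_trade_interval.items():
        totals[i] += mean * jobsite.n_workers_by_trade_interval[(t, i)]
    best = min(jobsite.intervals, key=lambda i: (-totals[i], i))
    return best, totals[best]


def write_jobsite_report(jobsite: JobsiteAssessment, path) -> None:
    with open(path, "w") as fh:
        json.dump(jobsite.to_dict(), fh, indent=2)
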