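"""Human-readable and JSON report rendering.

Individual reports carry three sections — the posture profile for the
assessment window, postures held past their holding-time limits, and overused
postures with correction suggestions. Jobsite reports carry four — awkward
posture distribution over time and trades, the proportion of awkward postures
by trade, correction urgency among trades, and a daily summary with
recommendations. Jobsite output is anonymous: trades and counts only.
"""

from __future__ import annotations

import json
from typing import Union

from .assessment import ActionCategory, IndividualAssessment
from .jobsite import JobsiteAssessment
from .types import PostureLabel

_URGENCY_TEXT = {
    ActionCategory.AC1: "no corrective action needed",
    ActionCategory.AC2: "corrective action in the near future",
    ActionCategory.AC3: "corrective action as soon as possible",
    ActionCategory.AC4: "corrective action immediately",
}


def render_individual(a: IndividualAssessment) -> str:
    lines = [
        f"Posture profile — worker {a.worker_id} ({a.trade}), "
        f"window start {a.window_start_epoch} s, length {a.window_length} s",
        "",
        "1. Posture profile",
    ]
    for lab, st in a.per_posture.items():
        if st.seconds == 0:
            continue
        lines.append(
            f"   {lab.value}: {st.seconds} s ({st.proportion:.1%}), "
            f"{st.run_count} run(s), max hold {st.max_hold} s, "
            f"{st.occurrences_per_minute:.2f}/min, {st.owas_category.name}"
        )
    if a.unknown_seconds:
        lines.append(f"   (unassessed: {a.unknown_seconds} s)")
    lines.append("")
    lines.append("2. Postures held for too long")
    breaches = [
        (lab, st) for lab, st in a.per_posture.items() if st.breach_count > 0
    ]
    if breaches:
        for lab, st in breaches:
            lines.append(
                f"   {lab.value}: {st.breach_count} breach(es), "
                f"total {st.breach_total_duration} s, longest {st.max_hold} s"
            )
    else:
        lines.append("   none")
    lines.append("")
    lines.append("3. Overused postures and correction suggestions")
    flagged = [
        lab for lab in a.correction_suggestions
        if a.per_posture[lab].owas_category > ActionCategory.AC1
    ]
    if flagged:
        for lab in flagged:
            st = a.per_posture[lab]
            lines.append(
                f"   {lab.value} ({st.proportion:.1%}): {_URGENCY_TEXT[st.owas_category]}"
            )
    else:
        lines.append("   no corrections recommended")
    return "\n".join(lines)


def render_jobsite(j: JobsiteAssessment) -> str:
    lines = [
        f"Jobsite daily summary — {len(j.trades)} trade(s), "
        f"{len(j.intervals)} interval(s) of {j.interval_length} s",
        "",
        "1. Awkward posture distribution over time and trades "
        "(mean awkward seconds per worker)",
    ]
    for trade in sorted(j.trades):
        cells = [
            f"{j.mean_awkward_by_trade_interval.get((trade, i), 0.0):.0f}"
            for i in j.intervals
        ]
        lines.append(f"   {trade}: {' '.join(cells)}")
    lines.append("")
    lines.append("2. Proportion of awkward postures by trade")
    for trade in sorted(j.trades):
        d = j.trades[trade]
        lines.append(
            f"   {trade}: {d.awkward_proportion:.1%} "
            f"({d.n_workers} worker(s), worst {d.worst_category.name})"
        )
    lines.append("")
    lines.append("3. Urgency for posture correction among trades")
    for rank, trade in enumerate(j.urgency_rank, start=1):
        d = j.trades[trade]
        lines.append(
            f"   {rank}. {trade} — {d.worst_category.name}: "
            f"{_URGENCY_TEXT[d.worst_category]}"
        )
    lines.append("")
    lines.append("4. Daily summary and safety recommendations")
    lines.append(
        f"   Peak exposure in interval {j.peak_interval}; "
        f"highest awkward share in trade '{j.peak_trade}'."
    )
    worst = j.trades[j.urgency_rank[0]].worst_category if j.urgency_rank else ActionCategory.AC1
    if worst > ActionCategory.AC1:
        lines.append(
            f"   Recommend prioritizing posture correction for '{j.urgency_rank[0]}' "
            f"({_URGENCY_TEXT[worst]})."
        )
    else:
        lines.append("   No corrections recommended today.")
    return "\n".join(lines)


def render_report(assessment: Union[IndividualAssessment, JobsiteAssessment]) -> str:
    if isinstance(assessment, IndividualAssessment):
        return render_individual(assessment)
    return render_jobsite(assessment)


def report_json(assessment: Union[IndividualAssessment, JobsiteAssessment]) -> str:
    return json.dumps(assessment.to_dict(), indent=2, sort_keys=True)
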