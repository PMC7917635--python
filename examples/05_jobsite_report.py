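"""Aggregate a simulated workday into the jobsite-level manager view.

Individual 30-minute assessments are pooled per trade and interval: the
report shows mean awkward-posture seconds per worker over the day, daily
awkward-time proportions by trade, correction urgency ranking, and the peak
exposure interval — anonymously, trades and counts only.
"""

from posturekit import (
    PostureScheduleSpec,
    aggregate_jobsite,
    assess_individual,
    simulate_cohort,
)
from posturekit.reports import render_jobsite

trades = {f"w{k}": ("mason" if k < 4 else "electrician") for k in range(8)}
cohort = simulate_cohort(
    8, trades=trades, spec=PostureScheduleSpec(duration=7200), base_seed=5
)

assessments = []
for _, timeline in cohort:
    assessments.extend(assess_individual(timeline, window_length=1800))

jobsite = aggregate_jobsite(assessments, interval_length=1800)
print(render_jobsite(jobsite))

# The per-trade rows give mean awkward seconds per worker in each 30-min
# interval; the urgency ranking orders trades by worst OWAS category, then
# awkward-time share, so the first-listed trade needs attention soonest.
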