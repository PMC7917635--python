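"""Periodic individual risk assessment with OWAS-style action categories.

Every 30-minute window of a posture timeline is profiled per posture: how
many holds breached the MHT limit and for how long, the longest hold, how
often the posture recurred per minute, and its share of the assessed time.
The time share maps to an action category — AC1 (no action) through AC4
(correct immediately) — for awkward postures.
"""

from posturekit import PostureScheduleSpec, assess_individual, sample_schedule
from posturekit.reports import render_individual

timeline = sample_schedule(PostureScheduleSpec(duration=3600), seed=3)
timeline.worker_id, timeline.trade = "w1", "mason"

for assessment in assess_individual(timeline, window_length=1800):
    print(render_individual(assessment))
    print()

# Each window lists per-posture seconds, run counts, max holds and action
# categories; section 2 lists holds that exceeded their limits, and section 3
# ranks overused postures, worst action category first.
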