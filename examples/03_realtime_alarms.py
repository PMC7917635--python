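"""Stream a posture label sequence through the holding-time detector.

The detector counts consecutive identical per-second postures and fires the
moment the count exceeds that posture's Maximum Holding Time (MHT) limit —
here the illustrative defaults (e.g. bending 60 s, kneeling 120 s; standing
and walking exempt). Alarms arrive while the posture is still held, so the
worker can correct it.
"""

from posturekit import MhtRuleSet, MhtStreamDetector, PostureLabel

# a worker bends for 90 s, stands up briefly, then kneels for 150 s
stream = (
    [PostureLabel.BT] * 90 + [PostureLabel.ST] * 10 + [PostureLabel.KN] * 150
)

detector = MhtStreamDetector(MhtRuleSet(), worker_id="w1")
for second, label in enumerate(stream):
    for alarm in detector.push(label):
        print(
            f"t={second:3d}s  ALARM: {alarm.posture.value} held "
            f"{alarm.held_seconds_at_trigger} s (limit {alarm.threshold} s)"
        )

# Expected: one bending alarm at t=60 (held 61 s > 60 s limit) and one
# kneeling alarm at t=220 (held 121 s > 120 s limit). The brief standing
# break resets the counter, which is why bending never alarms twice.
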