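import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_timeline
from oracles import brute_alarms, brute_runs, brute_window_stats
from posturekit.assessment import (
    ActionCategory,
    AlarmPolicy,
    MhtRuleSet,
    MhtStreamDetector,
    OwasRuleSet,
    assess_individual,
    detect_mht_offline,
    owas_action_category,
    runs_of,
)
from posturekit.types import LABEL_ORDER, PostureLabel, PostureTimeline


def tl_of(labels, start_epoch_s=0):
    return PostureTimeline(
        worker_id="w", trade="t", start_epoch=start_epoch_s * 1000, labels=labels
    )


def random_rules(rng) -> MhtRuleSet:
    thresholds = {}
    for lab in LABEL_ORDER:
        thresholds[lab] = None if rng.random() < 0.3 else int(rng.integers(1, 40))
    policy = AlarmPolicy.ONCE_PER_RUN if rng.random() < 0.5 else AlarmPolicy.REPEAT_EVERY_THRESHOLD
    return MhtRuleSet(thresholds=thresholds, alarm_policy=policy)


class TestRunsOf:
    def test_simple_runs(self):
        tl = tl_of([PostureLabel.ST, PostureLabel.ST, PostureLabel.BT])
        assert runs_of(tl) == [
            (PostureLabel.ST, 0, 2),
            (PostureLabel.BT, 2, 1),
        ]

    def test_single_run(self):
        tl = tl_of([PostureLabel.KN] * 100, start_epoch_s=50)
        assert runs_of(tl) == [(PostureLabel.KN, 50, 100)]

    def test_reconstruction_on_random_timelines(self, rng):
        for _ in range(500):
            tl = random_timeline(rng, with_unknown=True)
            runs = runs_of(tl)
            assert sum(r[2] for r in runs) == len(tl)
            assert all(a[0] is not b[0] for a, b in zip(runs, runs[1:]))
            rebuilt = [lab for lab, _, n in runs for _ in range(n)]
            assert rebuilt == tl.labels
            # epochs are contiguous
            assert runs[0][1] == tl.start_epoch_s
            for (_, s1, n1), (_, s2, _) in zip(runs, runs[1:]):
                assert s2 == s1 + n1


class TestMhtStream:
    def test_long_kneel_once_per_run(self):
        rules = MhtRuleSet(thresholds={PostureLabel.KN: 60},
                           alarm_policy=AlarmPolicy.ONCE_PER_RUN)
        alarms = detect_mht_offline(tl_of([PostureLabel.KN] * 100), rules)
        assert len(alarms) == 1
        a = alarms[0]
        assert a.trigger_epoch == 60  # second 61 of the run, 0-based epoch 60
        assert a.held_seconds_at_trigger == 61
        assert a.threshold == 60

    def test_alternation_never_alarms(self):
        rules = MhtRuleSet(thresholds={PostureLabel.BT: 60})
        labels = [PostureLabel.BT, PostureLabel.ST] * 200
        assert detect_mht_offline(tl_of(labels), rules) == []

    def test_repeat_policy_fires_every_threshold(self):
        rules = MhtRuleSet(thresholds={PostureLabel.BT: 10},
                           alarm_policy=AlarmPolicy.REPEAT_EVERY_THRESHOLD)
        alarms = detect_mht_offline(tl_of([PostureLabel.BT] * 35), rules)
        assert [a.held_seconds_at_trigger for a in alarms] == [11, 21, 31]

    def test_unknown_resets_counter(self):
        rules = MhtRuleSet(thresholds={PostureLabel.BT: 5})
        labels = [PostureLabel.BT] * 5 + [PostureLabel.UNKNOWN] + [PostureLabel.BT] * 5
        assert detect_mht_offline(tl_of(labels), rules) == []

    def test_exempt_never_alarms(self):
        rules = MhtRuleSet()  # ST exempt by default
        assert detect_mht_offline(tl_of([PostureLabel.ST] * 5000), rules) == []

    def test_non_label_token_rejected(self):
        det = MhtStreamDetector(MhtRuleSet())
        with pytest.raises(ValueError):
            det.push("ST")

    def test_streaming_equals_offline_oracle(self, rng):
        """Randomized equivalence of the incremental detector and the
        brute-force run-scan, under both alarm policies."""
        for _ in range(2000):
            tl = random_timeline(rng, with_unknown=True)
            rules = random_rules(rng)
            got = [
                (a.posture, a.trigger_epoch, a.held_seconds_at_trigger, a.threshold)
                for a in detect_mht_offline(tl, rules)
            ]
            assert got == brute_alarms(tl, rules)

    def test_run_start_epoch_consistent(self, rng):
        for _ in range(100):
            tl = random_timeline(rng)
            rules = random_rules(rng)
            for a in detect_mht_offline(tl, rules):
                assert a.trigger_epoch >= a.run_start_epoch + a.threshold


class TestOwasCategory:
    RULES = OwasRuleSet()

    def test_zero_proportion_is_ac1(self):
        assert owas_action_category(0.0, PostureLabel.BT, self.RULES) is ActionCategory.AC1

    def test_boundary_is_left_closed_upper(self):
        p1, p2, p3 = self.RULES.bands[PostureLabel.BT]
        assert owas_action_category(p2, PostureLabel.BT, self.RULES) is ActionCategory.AC3
        assert owas_action_category(p1, PostureLabel.BT, self.RULES) is ActionCategory.AC2
        assert owas_action_category(p3, PostureLabel.BT, self.RULES) is ActionCategory.AC4

    def test_non_awkward_always_ac1(self):
        assert owas_action_category(0.9, PostureLabel.ST, self.RULES) is ActionCategory.AC1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            owas_action_category(1.5, PostureLabel.BT, self.RULES)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_proportion(self, p, q):
        lo, hi = min(p, q), max(p, q)
        assert owas_action_category(lo, PostureLabel.KN, self.RULES) <= owas_action_category(
            hi, PostureLabel.KN, self.RULES
        )


class TestAssessIndividual:
    def test_all_standing_window(self):
        out = assess_individual(tl_of([PostureLabel.ST] * 1800))
        assert len(out) == 1
        a = out[0]
        st_stats = a.per_posture[PostureLabel.ST]
        assert st_stats.proportion == 1.0
        assert st_stats.run_count == 1
        assert st_stats.occurrences_per_minute == pytest.approx(1 / 30)
        assert all(s.breach_count == 0 for s in a.per_posture.values())

    def test_crafted_bending_breaches(self):
        labels = []
        for _ in range(3):
            labels += [PostureLabel.BT] * 70 + [PostureLabel.ST] * 70
        labels += [PostureLabel.ST] * (1800 - len(labels))
        a = assess_individual(tl_of(labels))[0]
        bt = a.per_posture[PostureLabel.BT]
        assert bt.breach_count == 3
        assert bt.breach_total_duration == 210
        assert bt.max_hold == 70
        assert bt.proportion == pytest.approx(210 / 1800)

    def test_window_partition_and_final_partial(self):
        out = assess_individual(tl_of([PostureLabel.ST] * 4000), window_length=1800)
        assert [a.window_length for a in out] == [1800, 1800, 400]
        assert [a.window_start_epoch for a in out] == [0, 1800, 3600]

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            assess_individual(tl_of([PostureLabel.ST] * 100), window_length=30)

    def test_runs_clipped_at_window_boundary(self):
        # a 70-s hold split 40/30 across the boundary
        labels = [PostureLabel.ST] * 20 + [PostureLabel.BT] * 70 + [PostureLabel.ST] * 30
        out = assess_individual(tl_of(labels), window_length=60)
        assert out[0].per_posture[PostureLabel.BT].max_hold == 40
        assert out[1].per_posture[PostureLabel.BT].max_hold == 30

    def test_brute_force_agreement_on_random_timelines(self, rng):
        """Every reported statistic equals a literal recount from runs."""
        mht = MhtRuleSet()
        owas = OwasRuleSet()
        for _ in range(300):
            tl = random_timeline(rng, length=int(rng.integers(60, 500)), with_unknown=True)
            wlen = int(rng.integers(60, 200))
            for a in assess_individual(tl, mht, owas, window_length=wlen):
                off = a.window_start_epoch - tl.start_epoch_s
                seg = tl.labels[off : off + a.window_length]
                exp, unknown = brute_window_stats(seg, mht, owas)
                assert a.unknown_seconds == unknown
                for lab in LABEL_ORDER:
                    got, want = a.per_posture[lab], exp[lab]
                    assert got.seconds == want["seconds"]
                    assert got.breach_count == want["breach_count"]
                    assert got.breach_total_duration == want["breach_total_duration"]
                    assert got.max_hold == want["max_hold"]
                    assert got.run_count == want["run_count"]
                    assert got.occurrences_per_minute == pytest.approx(
                        want["occurrences_per_minute"]
                    )
                    assert got.proportion == pytest.approx(want["proportion"])
                    assert got.owas_category is want["owas_category"]

    def test_seconds_conservation(self, rng):
        for _ in range(100):
            tl = random_timeline(rng, with_unknown=True)
            for a in assess_individual(tl, window_length=60):
                total = sum(s.seconds for s in a.per_posture.values())
                assert total + a.unknown_seconds == a.window_length
                if a.unknown_seconds == 0:
                    assert sum(s.proportion for s in a.per_posture.values()) == pytest.approx(1.0)

    def test_concatenation_additivity(self, rng):
        """Assessing two halves separately equals assessing the
        concatenation with window_length = half length."""
        half = 300
        a_labels = random_timeline(rng, length=half).labels
        b_labels = random_timeline(rng, length=half).labels
        whole = assess_individual(tl_of(a_labels + b_labels), window_length=half)
        part_a = assess_individual(tl_of(a_labels), window_length=half)[0]
        part_b = assess_individual(tl_of(b_labels, start_epoch_s=half), window_length=half)[0]
        for got, want in zip(whole, [part_a, part_b]):
            for lab in LABEL_ORDER:
                assert got.per_posture[lab] == want.per_posture[lab]

    def test_suggestions_rank_worst_category_first(self):
        # 60% bending (AC4), 20% kneeling (AC2), rest standing
        labels = ([PostureLabel.BT] * 1080 + [PostureLabel.KN] * 360
                  + [PostureLabel.ST] * 360)
        a = assess_individual(tl_of(labels))[0]
        assert a.correction_suggestions[0] is PostureLabel.BT

    def test_assessment_json_round_trip(self, rng):
        from posturekit.assessment import IndividualAssessment

        tl = random_timeline(rng, length=400, with_unknown=True)
        for a in assess_individual(tl, window_length=120):
            back = IndividualAssessment.from_dict(a.to_dict())
            assert back == a
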