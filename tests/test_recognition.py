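import numpy as np
import pytest

from oracles import brute_metrics
from posturekit import recognition as rec
from posturekit.synthetic import EmissionSpec, PostureScheduleSpec, emit_session, sample_schedule, simulate_cohort
from posturekit.types import LABEL_ORDER, PostureLabel, PostureTimeline, TimelineSource


def small_cohort_dataset(n_workers=3, duration=300, noise=0.05, base_seed=0):
    cohort = simulate_cohort(
        n_workers,
        spec=PostureScheduleSpec(duration=duration),
        espec=EmissionSpec(accel_noise_sd=noise),
        base_seed=base_seed,
    )
    return rec.concat_datasets([rec.make_windows(s, t) for s, t in cohort])


@pytest.fixture(scope="module")
def cohort_ds():
    return small_cohort_dataset()


class TestMakeWindows:
    def test_clean_session_counts(self):
        tl = sample_schedule(PostureScheduleSpec(duration=60), seed=0)
        ses = emit_session(tl, EmissionSpec(), rate=25)
        ds = rec.make_windows(ses, tl)
        assert ds.windows.shape == (60, 25, 30)
        assert ds.n_dropped == 0

    def test_masked_seconds_dropped(self):
        labels = [PostureLabel.ST] * 60
        labels[10:20] = [PostureLabel.UNKNOWN] * 10
        tl = PostureTimeline(worker_id="w", trade="t", start_epoch=0, labels=labels)
        ses = emit_session(tl, EmissionSpec(), rate=25)
        ds = rec.make_windows(ses, tl)
        assert len(ds) == 50
        assert ds.n_dropped == 10

    def test_labels_align_with_epochs(self, rng):
        for _ in range(30):
            tl = sample_schedule(
                PostureScheduleSpec(duration=int(rng.integers(30, 120))),
                seed=int(rng.integers(1000)),
            )
            ses = emit_session(tl, EmissionSpec(seed=int(rng.integers(1000))), rate=25)
            ds = rec.make_windows(ses, tl)
            for w, lab_idx, epoch in zip(ds.windows, ds.labels, ds.window_epochs):
                assert tl.labels[epoch - tl.start_epoch_s] is LABEL_ORDER[lab_idx]


class TestSplit:
    def test_canonical_sizes(self, cohort_ds):
        ds100 = cohort_ds.subset(np.arange(100))
        tr, va, te = rec.split_dataset(ds100, seed=0)
        assert (len(tr), len(va), len(te)) == (72, 18, 10)

    def test_largest_remainder_at_w10(self, cohort_ds):
        ds10 = cohort_ds.subset(np.arange(10))
        tr, va, te = rec.split_dataset(ds10, seed=0)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_deterministic_and_seed_sensitive(self, cohort_ds):
        a = rec.split_dataset(cohort_ds, seed=3)
        b = rec.split_dataset(cohort_ds, seed=3)
        c = rec.split_dataset(cohort_ds, seed=4)
        assert np.array_equal(a[0].window_epochs, b[0].window_epochs)
        assert not np.array_equal(a[0].window_epochs, c[0].window_epochs)

    def test_partition_disjoint_exhaustive(self, cohort_ds):
        tr, va, te = rec.split_dataset(cohort_ds, seed=1)
        all_epochs = np.concatenate([d.window_epochs for d in (tr, va, te)])
        assert len(all_epochs) == len(cohort_ds)
        # window_epochs identify windows uniquely within one session cohort?
        # workers share epoch ranges, so compare label+epoch multisets
        got = sorted(zip(all_epochs.tolist(), np.concatenate([d.labels for d in (tr, va, te)]).tolist()))
        want = sorted(zip(cohort_ds.window_epochs.tolist(), cohort_ds.labels.tolist()))
        assert got == want

    def test_bad_fractions_rejected(self, cohort_ds):
        with pytest.raises(ValueError):
            rec.split_dataset(cohort_ds, fractions=(0.7, 0.2, 0.2))


class TestNormalization:
    def test_constant_channel_zeroed(self, cohort_ds):
        ds = cohort_ds.subset(np.arange(50))
        ds.windows[:, :, 7] = 3.14
        stats = rec.fit_normalization(ds)
        out = rec.apply_normalization(ds, stats)
        np.testing.assert_allclose(out.windows[:, :, 7], 0.0, atol=1e-6)

    def test_train_mean_zero(self, cohort_ds):
        stats = rec.fit_normalization(cohort_ds)
        out = rec.apply_normalization(cohort_ds, stats)
        flat = out.windows.reshape(-1, 30)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-9)

    def test_no_leakage_into_test_stats(self, cohort_ds):
        """Applying train-fitted stats elsewhere never mutates them."""
        tr, va, te = rec.split_dataset(cohort_ds, seed=0)
        stats = rec.fit_normalization(tr)
        fp = stats.fingerprint()
        rec.apply_normalization(te, stats)
        rec.apply_normalization(va, stats)
        assert stats.fingerprint() == fp
        assert rec.apply_normalization(te, stats).normalization is stats


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4, 5, 6] * 3)
        res = rec.evaluate_predictions(y, y)
        assert res.overall_accuracy == 1.0
        assert res.macro_f1 == 1.0
        np.testing.assert_array_equal(res.confusion_rownorm, np.eye(7))

    def test_all_one_class_on_balanced_two_class(self):
        true = np.array([0] * 50 + [1] * 50)
        pred = np.zeros(100, dtype=int)
        res = rec.evaluate_predictions(true, pred)
        assert res.overall_accuracy == 0.5
        # per-class F1: class0 = 2/3, class1 = 0, macro over the 2 present
        p0, r0, f0 = res.per_class[LABEL_ORDER[0]]
        assert f0 == pytest.approx(2 / 3)
        assert res.per_class[LABEL_ORDER[1]][2] == 0.0

    def test_matches_brute_force_recount(self, rng):
        for _ in range(300):
            n = int(rng.integers(5, 100))
            true = rng.integers(0, 7, size=n)
            pred = rng.integers(0, 7, size=n)
            res = rec.evaluate_predictions(true, pred)
            per, acc, mf1, conf = brute_metrics(true, pred, 7)
            assert res.overall_accuracy == pytest.approx(acc)
            assert res.macro_f1 == pytest.approx(mf1)
            np.testing.assert_array_equal(res.confusion, conf)
            for i, lab in enumerate(LABEL_ORDER):
                assert res.per_class[lab] == pytest.approx(per[i])

    def test_rownorm_rows_sum_to_one(self, rng):
        true = rng.integers(0, 7, size=200)
        pred = rng.integers(0, 7, size=200)
        res = rec.evaluate_predictions(true, pred)
        sums = res.confusion_rownorm.sum(axis=1)
        support = res.confusion.sum(axis=1)
        for s, sup in zip(sums, support):
            assert s == pytest.approx(1.0 if sup > 0 else 0.0, abs=1e-9)


class TestClassifiers:
    def test_baseline_separable_two_class(self, rng):
        X = rng.normal(scale=0.1, size=(200, 25, 30))
        y = rng.integers(0, 2, size=200) * 4  # ST (4) vs BT (0)
        X[:, :, 6] += np.where(y == 4, 1.0, -1.0)[:, None]
        ds = rec.WindowedDataset(windows=X, labels=y, window_epochs=np.arange(200))
        model = rec.train_baseline(ds, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_baseline_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 25, 30))
        ds = rec.WindowedDataset(
            windows=X, labels=np.zeros(20, dtype=int), window_epochs=np.arange(20)
        )
        with pytest.raises(ValueError):
            rec.train_baseline(ds, seed=0)

    def test_baseline_high_accuracy_on_cohort(self, cohort_ds):
        tr, va, te = rec.split_dataset(cohort_ds, seed=0)
        stats = rec.fit_normalization(tr)
        model = rec.train_baseline(rec.apply_normalization(tr, stats), seed=0)
        res = rec.evaluate(model, rec.apply_normalization(te, stats))
        assert res.overall_accuracy >= 0.95

    def test_label_permutation_collapses_to_chance(self, cohort_ds):
        tr, va, te = rec.split_dataset(cohort_ds, seed=0)
        stats = rec.fit_normalization(tr)
        tr_n = rec.apply_normalization(tr, stats)
        rng = np.random.default_rng(0)
        shuffled = rec.WindowedDataset(
            windows=tr_n.windows,
            labels=rng.permutation(tr_n.labels),
            window_epochs=tr_n.window_epochs,
            normalization=tr_n.normalization,
        )
        model = rec.train_baseline(shuffled, seed=0)
        res = rec.evaluate(model, rec.apply_normalization(va, stats))
        majority = np.bincount(va.labels, minlength=7).max() / len(va)
        assert res.overall_accuracy <= majority + 0.1

    def test_cln_deterministic_predictions(self, cohort_ds):
        sub = cohort_ds.subset(np.arange(200))
        stats = rec.fit_normalization(sub)
        sub_n = rec.apply_normalization(sub, stats)
        cfg = {"max_epochs": 2, "filters": 8, "hidden": 8}
        m1 = rec.train_cln(sub_n, None, config=cfg, seed=7)
        m2 = rec.train_cln(sub_n, None, config=cfg, seed=7)
        np.testing.assert_array_equal(
            m1.predict(sub_n.windows), m2.predict(sub_n.windows)
        )

    def test_cln_loss_decreases_on_tiny_set(self, rng):
        X = rng.normal(scale=0.1, size=(10, 25, 30))
        y = np.array([0, 4] * 5)
        X[:, :, 6] += np.where(y == 4, 1.0, -1.0)[:, None]
        ds = rec.WindowedDataset(windows=X, labels=y, window_epochs=np.arange(10))
        model = rec.train_cln(ds, None, config={"max_epochs": 5, "filters": 4, "hidden": 4}, seed=0)
        hist = model.config["loss_history"]
        assert hist[-1] < hist[0]

    def test_model_save_load_round_trip(self, cohort_ds, tmp_path):
        sub = cohort_ds.subset(np.arange(300))
        stats = rec.fit_normalization(sub)
        sub_n = rec.apply_normalization(sub, stats)
        for kind, trainer, cfg in [
            ("BASELINE", rec.train_baseline, None),
            ("CLN", rec.train_cln, {"max_epochs": 1, "filters": 4, "hidden": 4}),
        ]:
            model = trainer(sub_n, None, config=cfg, seed=0)
            d = tmp_path / kind
            model.save(d)
            back = rec.ClassifierModel.load(d)
            np.testing.assert_array_equal(
                back.predict(sub_n.windows), model.predict(sub_n.windows)
            )


class TestPredictTimeline:
    def test_constant_session_predicts_constant(self):
        # train on the generator's output, then predict a pure-ST session
        ds = small_cohort_dataset(n_workers=2, duration=200)
        stats = rec.fit_normalization(ds)
        model = rec.train_baseline(rec.apply_normalization(ds, stats), seed=0)
        labels = [PostureLabel.ST] * 30
        tl = PostureTimeline(worker_id="w", trade="t", start_epoch=0, labels=labels)
        ses = emit_session(tl, EmissionSpec(accel_noise_sd=0.0, gyro_noise_sd=0.0), rate=25)
        pred = rec.predict_timeline(model, ses)
        assert pred.source is TimelineSource.PREDICTED
        assert len(pred) == 30
        assert all(lab is PostureLabel.ST for lab in pred.labels)

    def test_masked_seconds_unknown(self):
        ds = small_cohort_dataset(n_workers=2, duration=100)
        stats = rec.fit_normalization(ds)
        model = rec.train_baseline(rec.apply_normalization(ds, stats), seed=0)
        labels = [PostureLabel.ST] * 5 + [PostureLabel.UNKNOWN] * 2 + [PostureLabel.ST] * 5
        tl = PostureTimeline(worker_id="w", trade="t", start_epoch=0, labels=labels)
        ses = emit_session(tl, EmissionSpec(), rate=25)
        pred = rec.predict_timeline(model, ses)
        assert pred.labels[5] is PostureLabel.UNKNOWN
        assert pred.labels[6] is PostureLabel.UNKNOWN
        assert pred.labels[0] is not PostureLabel.UNKNOWN


class TestProtocolAndImportance:
    def test_single_round_equals_direct(self, cohort_ds):
        summary = rec.run_protocol(cohort_ds, model_kind="BASELINE", rounds=1, seeds=[0])
        assert summary.mean_accuracy == summary.rounds[0].overall_accuracy
        assert summary.sd_accuracy == 0.0

    def test_mean_is_arithmetic_mean(self, cohort_ds):
        summary = rec.run_protocol(cohort_ds, model_kind="BASELINE", rounds=3, seeds=[0, 1, 2])
        accs = [r.overall_accuracy for r in summary.rounds]
        assert summary.mean_accuracy == pytest.approx(np.mean(accs))
        assert np.isfinite(summary.sd_accuracy)

    def test_zero_rounds_rejected(self, cohort_ds):
        with pytest.raises(ValueError):
            rec.run_protocol(cohort_ds, rounds=0, seeds=[])

    def test_signal_channel_ranks_first(self, rng):
        """A channel carrying the only class signal dominates the ranking;
        pure-noise channels show negligible drops."""
        X = rng.normal(scale=0.3, size=(400, 25, 30))
        y = rng.integers(0, 2, size=400) * 4
        X[:, :, 12] += np.where(y == 4, 1.0, -1.0)[:, None]
        ds = rec.WindowedDataset(windows=X, labels=y, window_epochs=np.arange(400))
        tr = ds.subset(np.arange(300))
        te = ds.subset(np.arange(300, 400))
        model = rec.train_baseline(tr, seed=0)
        fi = rec.permutation_importance(model, te, rounds=5, seed=0)
        names = [str(c) for c in rec.all_channels()]
        assert fi.ranking[0] == names[12]
        assert fi.per_channel[names[12]][0] >= 0.3
        for i, name in enumerate(names):
            if i != 12:
                assert abs(fi.per_channel[name][0]) <= 0.05

    def test_identity_permutation_zero_drop(self, rng):
        """Degenerate check: 'permuting' a constant channel changes nothing."""
        X = rng.normal(scale=0.3, size=(60, 25, 30))
        X[:, :, 3] = 1.0  # constant channel: any permutation is the identity
        y = rng.integers(0, 2, size=60) * 4
        X[:, :, 12] += np.where(y == 4, 1.0, -1.0)[:, None]
        ds = rec.WindowedDataset(windows=X, labels=y, window_epochs=np.arange(60))
        model = rec.train_baseline(ds, seed=0)
        fi = rec.permutation_importance(model, ds, rounds=2, seed=0)
        names = [str(c) for c in rec.all_channels()]
        assert fi.per_channel[names[3]][0] == 0.0

    def test_permute_all_collapses_to_majority(self, rng):
        X = rng.normal(scale=0.3, size=(300, 25, 30))
        y = rng.integers(0, 2, size=300) * 4
        X[:, :, 12] += np.where(y == 4, 1.0, -1.0)[:, None]
        ds = rec.WindowedDataset(windows=X, labels=y, window_epochs=np.arange(300))
        model = rec.train_baseline(ds, seed=0)
        acc = rec.permute_all_channels_accuracy(model, ds, seed=0)
        majority = np.bincount(y, minlength=7).max() / len(y)
        assert abs(acc - majority) <= 0.1
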