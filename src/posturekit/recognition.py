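"""Posture recognition: windowing, classifiers, evaluation, importance.

Recognition operates at a one-second cadence: a session's 30-channel matrix
is cut into non-overlapping one-second windows (rate samples long), each
labeled from the reference timeline. Windows touching sensor gaps or
UNKNOWN seconds are dropped. The dataset is shuffled and split 72/18/10 into
train/validation/test at the window level, channels are standardized with
statistics fitted on the training portion only, and one of two classifiers
is trained:

* ``BASELINE`` — a regularized multinomial logistic regression on per-window
  per-channel mean and standard deviation summaries (60 features), the kind
  of conventional model this problem was historically approached with;
* ``CLN`` — the convolutional-recurrent network (one 1-D convolution over
  the raw window, stacked LSTM layers, softmax readout), trained with Adam
  and early stopping on validation macro F1.

Evaluation reports per-class precision/recall/F1, overall accuracy, macro F1
and a row-normalized confusion matrix; the protocol repeats train/test over
several seeds. Channel importance is measured by feature permutation:
shuffle one channel across the test subset and record the accuracy drop.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from . import nn
from .types import (
    LABEL_ORDER,
    N_CHANNELS,
    PostureLabel,
    PostureTimeline,
    SessionData,
    TimelineSource,
    all_channels,
)

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(LABEL_ORDER)}


@dataclass
class NormalizationStats:
    """Per-channel standardization statistics, fitted on training data only."""

    mean: np.ndarray  # (30,)
    sd: np.ndarray  # (30,), floored at 1e-6

    def fingerprint(self) -> str:
        return f"{self.mean.tobytes().hex()[:32]}:{self.sd.tobytes().hex()[:32]}"


@dataclass
class WindowedDataset:
    """Per-second windows: (W, L, 30) values with one label per window."""

    windows: np.ndarray
    labels: np.ndarray  # (W,) integer indices into LABEL_ORDER
    window_epochs: np.ndarray  # (W,) start second of each window
    normalization: NormalizationStats | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.windows.ndim != 3 or self.windows.shape[2] != N_CHANNELS:
            raise ValueError("windows must be (W, L, 30)")
        if len(self.labels) != len(self.windows):
            raise ValueError("one label per window required")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            window_epochs=self.window_epochs[idx],
            normalization=self.normalization,
        )


def make_windows(session: SessionData, timeline: PostureTimeline) -> WindowedDataset:
    """Cut a session into labeled non-overlapping one-second windows.

    Windows overlapping the gap mask or labeled UNKNOWN are excluded;
    ``n_dropped`` counts them.
    """
    rate = session.rate
    if rate < 1:
        raise ValueError("session rate must be a positive integer per second")
    n_sec = min(session.n_samples // rate, len(timeline.labels))
    wins, labs, epochs = [], [], []
    dropped = 0
    start_s = timeline.start_epoch_s
    for s in range(n_sec):
        sl = slice(s * rate, (s + 1) * rate)
        lab = timeline.labels[s]
        if lab is PostureLabel.UNKNOWN or session.gap_mask[sl].any():
            dropped += 1
            continue
        wins.append(session.matrix[sl])
        labs.append(LABEL_TO_INDEX[lab])
        epochs.append(start_s + s)
    if not wins:
        return WindowedDataset(
            windows=np.zeros((0, rate, N_CHANNELS)),
            labels=np.zeros(0, dtype=int),
            window_epochs=np.zeros(0, dtype=int),
            n_dropped=dropped,
        )
    return WindowedDataset(
        windows=np.stack(wins),
        labels=np.array(labs, dtype=int),
        window_epochs=np.array(epochs, dtype=int),
        n_dropped=dropped,
    )


def concat_datasets(datasets: Sequence[WindowedDataset]) -> WindowedDataset:
    """Pool windows from several sessions into one dataset."""
    datasets = [d for d in datasets if len(d) > 0]
    if not datasets:
        raise ValueError("no windows to concatenate")
    return WindowedDataset(
        windows=np.concatenate([d.windows for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        window_epochs=np.concatenate([d.window_epochs for d in datasets]),
        n_dropped=sum(d.n_dropped for d in datasets),
    )


def split_dataset(
    ds: WindowedDataset,
    fractions: tuple[float, float, float] = (0.72, 0.18, 0.10),
    seed: int = 0,
) -> tuple[WindowedDataset, WindowedDataset, WindowedDataset]:
    """Seeded uniform shuffle, then partition by fractions.

    Subset sizes use largest-remainder rounding so they always sum to W.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    W = len(ds)
    if W < 10:
        raise ValueError("need at least 10 windows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(W)
    exact = np.array(fractions) * W
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for _ in range(W - sizes.sum()):
        k = int(np.argmax(remainder))
        sizes[k] += 1
        remainder[k] = -1
    i1, i2 = sizes[0], sizes[0] + sizes[1]
    return ds.subset(perm[:i1]), ds.subset(perm[i1:i2]), ds.subset(perm[i2:])


def fit_normalization(train: WindowedDataset) -> NormalizationStats:
    """Per-channel mean/sd over all training windows and time steps."""
    flat = train.windows.reshape(-1, N_CHANNELS)
    return NormalizationStats(
        mean=flat.mean(axis=0), sd=np.maximum(flat.std(axis=0), 1e-6)
    )


def apply_normalization(ds: WindowedDataset, stats: NormalizationStats) -> WindowedDataset:
    """Standardize every channel with the given (train-fitted) statistics."""
    return WindowedDataset(
        windows=(ds.windows - stats.mean) / stats.sd,
        labels=ds.labels,
        window_epochs=ds.window_epochs,
        normalization=stats,
        n_dropped=ds.n_dropped,
    )


def summary_features(windows: np.ndarray) -> np.ndarray:
    """Per-channel mean and standard deviation per window: (W, 60)."""
    return np.concatenate([windows.mean(axis=1), windows.std(axis=1)], axis=1)


@dataclass
class ClassifierModel:
    """A trained posture classifier.

    ``predict`` is a pure function of the stored parameters and the input
    window; ``label_order`` is fixed at training time and argmax ties break
    toward the lowest index in it.
    """

    kind: str  # "BASELINE" | "CLN"
    label_order: tuple[PostureLabel, ...]
    normalization: NormalizationStats
    config: dict
    _sk_model: LogisticRegression | None = None
    _net: nn.ConvRecurrentNet | None = None

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """Class probabilities (W, 7) for normalized windows."""
        if self.kind == "BASELINE":
            feats = summary_features(windows)
            proba = np.zeros((len(windows), len(self.label_order)))
            cls = self._sk_model.classes_
            proba[:, cls] = self._sk_model.predict_proba(feats)
            return proba
        return self._net.predict_proba(windows)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Predicted label indices; ties break to the lowest label index."""
        return np.argmax(self.predict_proba(windows), axis=1)

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "kind": self.kind,
            "label_order": [lab.value for lab in self.label_order],
            "config": self.config,
            "norm_mean": self.normalization.mean.tolist(),
            "norm_sd": self.normalization.sd.tolist(),
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        if self.kind == "CLN":
            np.savez(os.path.join(directory, "weights.npz"), **self._net.get_weights())
        else:
            np.savez(
                os.path.join(directory, "weights.npz"),
                coef=self._sk_model.coef_,
                intercept=self._sk_model.intercept_,
                classes=self._sk_model.classes_,
            )

    @staticmethod
    def load(directory: str | os.PathLike) -> "ClassifierModel":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        stats = NormalizationStats(
            mean=np.array(meta["norm_mean"]), sd=np.array(meta["norm_sd"])
        )
        order = tuple(PostureLabel(v) for v in meta["label_order"])
        weights = np.load(os.path.join(directory, "weights.npz"))
        model = ClassifierModel(
            kind=meta["kind"], label_order=order, normalization=stats,
            config=meta["config"],
        )
        if meta["kind"] == "CLN":
            cfg = meta["config"]
            net = nn.ConvRecurrentNet(
                n_classes=len(order),
                filters=cfg.get("filters", 64),
                kernel=cfg.get("kernel", 5),
                hidden=cfg.get("hidden", 64),
                depth=cfg.get("depth", 2),
            )
            net.set_weights({k: weights[k] for k in weights.files})
            model._net = net
        else:
            lr = LogisticRegression()
            lr.coef_ = weights["coef"]
            lr.intercept_ = weights["intercept"]
            lr.classes_ = weights["classes"]
            model._sk_model = lr
        return model


DEFAULT_CLN_CONFIG: dict = {
    "filters": 64,
    "kernel": 5,
    "hidden": 64,
    "depth": 2,
    "lr": 3e-3,
    "batch_size": 64,
    "max_epochs": 30,
    "patience": 5,
}

DEFAULT_BASELINE_CONFIG: dict = {"C": 10.0, "max_iter": 2000}


def _check_trainable(train: WindowedDataset) -> None:
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")


def train_baseline(
    train: WindowedDataset,
    val: WindowedDataset | None = None,
    config: Mapping | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the summary-feature logistic-regression baseline.

    Windows are expected pre-normalized with train-fitted statistics; the
    stats object is carried on the dataset and stored in the model.
    """
    _check_trainable(train)
    cfg = dict(DEFAULT_BASELINE_CONFIG)
    if config:
        cfg.update(config)
    feats = summary_features(train.windows)
    clf = LogisticRegression(
        C=cfg["C"], max_iter=cfg["max_iter"], random_state=seed,
    )
    clf.fit(feats, train.labels)
    return ClassifierModel(
        kind="BASELINE",
        label_order=LABEL_ORDER,
        normalization=train.normalization
        or NormalizationStats(np.zeros(N_CHANNELS), np.ones(N_CHANNELS)),
        config=cfg,
        _sk_model=clf,
    )


def train_cln(
    train: WindowedDataset,
    val: WindowedDataset | None = None,
    config: Mapping | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Train the convolutional-recurrent network with early stopping.

    Minimizes softmax cross-entropy with Adam; after each epoch the
    validation macro F1 is measured and the best weights are kept; training
    stops once it fails to improve for ``patience`` epochs. Deterministic
    under a fixed seed.
    """
    _check_trainable(train)
    cfg = dict(DEFAULT_CLN_CONFIG)
    if config:
        cfg.update(config)
    rng = np.random.default_rng(seed)
    net = nn.ConvRecurrentNet(
        n_classes=len(LABEL_ORDER),
        filters=cfg["filters"],
        kernel=cfg["kernel"],
        hidden=cfg["hidden"],
        depth=cfg["depth"],
        seed=seed,
    )
    opt = nn.Adam(net.params(), lr=cfg["lr"])
    X, y = train.windows, train.labels
    best_score, best_weights, since_best = -np.inf, None, 0
    history: list[float] = []
    for epoch in range(cfg["max_epochs"]):
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), cfg["batch_size"]):
            idx = order[lo : lo + cfg["batch_size"]]
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(net.forward(X[idx]), y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if val is not None and len(val) > 0:
            pred = np.argmax(net.predict_proba(val.windows), axis=1)
            score = macro_f1_from_counts(val.labels, pred, len(LABEL_ORDER))
        else:
            score = -history[-1]
        if score > best_score + 1e-12:
            best_score, best_weights, since_best = score, net.get_weights(), 0
            best_weights = {k: v.copy() for k, v in best_weights.items()}
        else:
            since_best += 1
            if since_best >= cfg["patience"]:
                break
    if best_weights is not None:
        net.set_weights(best_weights)
    model = ClassifierModel(
        kind="CLN",
        label_order=LABEL_ORDER,
        normalization=train.normalization
        or NormalizationStats(np.zeros(N_CHANNELS), np.ones(N_CHANNELS)),
        config=cfg,
        _net=net,
    )
    model.config = dict(cfg, loss_history=history)
    return model


def predict_timeline(model: ClassifierModel, session: SessionData) -> PostureTimeline:
    """Classify every usable second of a session.

    Seconds touching the gap mask come out as UNKNOWN; the timeline length is
    the whole number of seconds in the session.
    """
    rate = session.rate
    n_sec = session.n_samples // rate
    if n_sec < 1:
        raise ValueError("session shorter than 1 s")
    labels: list[PostureLabel] = [PostureLabel.UNKNOWN] * n_sec
    usable, wins = [], []
    for s in range(n_sec):
        sl = slice(s * rate, (s + 1) * rate)
        if session.gap_mask[sl].any():
            continue
        usable.append(s)
        wins.append(session.matrix[sl])
    if usable:
        W = np.stack(wins)
        W = (W - model.normalization.mean) / model.normalization.sd
        pred = model.predict(W)
        for s, p in zip(usable, pred):
            labels[s] = model.label_order[int(p)]
    return PostureTimeline(
        worker_id=session.worker_id,
        trade=session.trade,
        start_epoch=session.start_epoch,
        labels=labels,
        source=TimelineSource.PREDICTED,
    )


def macro_f1_from_counts(true: np.ndarray, pred: np.ndarray, n_classes: int) -> float:
    _, _, f1, _ = _sk_prfs(
        true, pred, labels=np.arange(n_classes), average=None, zero_division=0
    )
    return float(f1.mean())


@dataclass
class EvalResult:
    """Per-class and overall classification metrics plus confusion matrices."""

    per_class: dict[PostureLabel, tuple[float, float, float]]  # P, R, F1
    overall_accuracy: float
    macro_f1: float
    confusion: np.ndarray  # (7, 7) counts, rows = true labels
    confusion_rownorm: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_class": {
                lab.value: {"precision": p, "recall": r, "f1": f}
                for lab, (p, r, f) in self.per_class.items()
            },
            "overall_accuracy": self.overall_accuracy,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
            "confusion_rownorm": self.confusion_rownorm.tolist(),
        }


def evaluate_predictions(true: np.ndarray, pred: np.ndarray) -> EvalResult:
    """Metrics from integer label vectors (indices into LABEL_ORDER)."""
    n = len(LABEL_ORDER)
    labels = np.arange(n)
    prec, rec, f1, _ = _sk_prfs(
        true, pred, labels=labels, average=None, zero_division=0
    )
    conf = _sk_confusion(true, pred, labels=labels).astype(float)
    support = conf.sum(axis=1, keepdims=True)
    rownorm = np.divide(conf, support, out=np.zeros_like(conf), where=support > 0)
    return EvalResult(
        per_class={
            lab: (float(prec[i]), float(rec[i]), float(f1[i]))
            for i, lab in enumerate(LABEL_ORDER)
        },
        overall_accuracy=float(np.mean(true == pred)) if len(true) else 0.0,
        macro_f1=float(f1.mean()),
        confusion=conf,
        confusion_rownorm=rownorm,
    )


def evaluate(model: ClassifierModel, test: WindowedDataset) -> EvalResult:
    """Evaluate a trained model on a (normalized) test subset."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = model.predict(test.windows)
    return evaluate_predictions(test.labels, pred)


@dataclass
class ProtocolSummary:
    """Repeated train/test rounds with different seeds."""

    rounds: list[EvalResult]
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float


def run_protocol(
    ds: WindowedDataset,
    model_kind: str = "CLN",
    rounds: int = 5,
    seeds: Sequence[int] | None = None,
    config: Mapping | None = None,
    fractions: tuple[float, float, float] = (0.72, 0.18, 0.10),
) -> ProtocolSummary:
    """Repeat split→normalize→train→test ``rounds`` times and average."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    seeds = list(seeds) if seeds is not None else list(range(rounds))
    if len(seeds) != rounds:
        raise ValueError("one seed per round required")
    results = []
    for seed in seeds:
        train, val, test = split_dataset(ds, fractions=fractions, seed=seed)
        stats = fit_normalization(train)
        train_n = apply_normalization(train, stats)
        val_n = apply_normalization(val, stats)
        test_n = apply_normalization(test, stats)
        trainer = train_cln if model_kind == "CLN" else train_baseline
        model = trainer(train_n, val_n, config=config, seed=seed)
        results.append(evaluate(model, test_n))
    acc = np.array([r.overall_accuracy for r in results])
    mf1 = np.array([r.macro_f1 for r in results])
    return ProtocolSummary(
        rounds=results,
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std()),
        mean_macro_f1=float(mf1.mean()),
        sd_macro_f1=float(mf1.std()),
    )


@dataclass
class FeatureImportance:
    """Permutation importance per channel: mean and sd of the accuracy drop."""

    per_channel: dict[str, tuple[float, float]]
    ranking: list[str]  # channel names, largest mean drop first
    baseline_accuracy: float


def permutation_importance(
    model: ClassifierModel,
    test: WindowedDataset,
    rounds: int = 5,
    seed: int = 0,
) -> FeatureImportance:
    """Shuffle each channel of the test subset and record the accuracy drop.

    Each round permutes every channel independently (values shuffled across
    all windows and time steps) with a fresh seeded permutation; the drop is
    baseline accuracy minus permuted accuracy, averaged over rounds.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    rng = np.random.default_rng(seed)
    base = evaluate(model, test).overall_accuracy
    channels = all_channels()
    drops = np.zeros((rounds, len(channels)))
    W, L, C = test.windows.shape
    for r in range(rounds):
        for ci in range(C):
            perm = rng.permutation(W * L)
            shuffled = test.windows.copy()
            flat = shuffled[:, :, ci].reshape(-1)
            shuffled[:, :, ci] = flat[perm].reshape(W, L)
            pred = model.predict(shuffled)
            drops[r, ci] = base - float(np.mean(pred == test.labels))
    mean_drop = drops.mean(axis=0)
    sd_drop = drops.std(axis=0)
    names = [str(c) for c in channels]
    order = sorted(range(C), key=lambda i: (-mean_drop[i], names[i]))
    return FeatureImportance(
        per_channel={names[i]: (float(mean_drop[i]), float(sd_drop[i])) for i in range(C)},
        ranking=[names[i] for i in order],
        baseline_accuracy=base,
    )


def permute_all_channels_accuracy(
    model: ClassifierModel, test: WindowedDataset, seed: int = 0
) -> float:
    """Accuracy after permuting every channel simultaneously — should fall to
    roughly the majority-class share if the model truly reads the channels."""
    rng = np.random.default_rng(seed)
    W, L, C = test.windows.shape
    shuffled = test.windows.copy()
    for ci in range(C):
        perm = rng.permutation(W * L)
        flat = shuffled[:, :, ci].reshape(-1)
        shuffled[:, :, ci] = flat[perm].reshape(W, L)
    pred = model.predict(shuffled)
    return float(np.mean(pred == test.labels))
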