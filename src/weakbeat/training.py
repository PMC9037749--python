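"""Weak (record-label) training, supervised pre-training, and the
two-stage strategy.

The weak objective is a per-class binary cross-entropy between the
aggregated record scores and the record's label set, weighted per record
to counter class imbalance (records with one ectopic class weigh 2, with
both 4, with neither 0.1).  Supervised pre-training applies categorical
cross-entropy directly to the local predictions at annotated R peaks and
is used to initialize the weak stage away from degenerate solutions of
the ill-posed weak problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation
from .autodiff import Adam, Tensor
from .context_features import FeatureConfig, RPeakSet, knowledge_features
from .io_formats import AAMI_CLASSES, ECGRecord
from .model_core import (AggregationConfig, BeatDetector, GlobalPrediction,
                         LocalPrediction, aggregate_graph)
from .preprocess import pad_or_truncate

EPS = 1e-7  # clamp on aggregated scores before logs


@dataclass
class TrainConfig:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    patience: int = 10
    max_epochs: int = 100
    pretrain_epochs: int = 10
    weights: dict = field(default_factory=lambda: {
        "ectopic_single": 2.0, "ectopic_both": 4.0, "none": 0.1})
    seed: int = 0
    val_metric: str = "beat_f1"  # or "record_f1"


# ---------------------------------------------------------------------------
# losses (plain-numpy API)
# ---------------------------------------------------------------------------


def weak_loss(global_pred: GlobalPrediction, labels: set) -> float:
    """Mean per-class binary cross-entropy against the record label set."""
    total = 0.0
    for c in AAMI_CLASSES:
        s = float(np.clip(global_pred.scores[c], EPS, 1 - EPS))
        t = 1.0 if c in labels else 0.0
        total += t * np.log(s) + (1 - t) * np.log(1 - s)
    return -total / len(AAMI_CLASSES)


def sample_weight(labels: set, cfg: TrainConfig | None = None) -> float:
    """Per-record loss weight from the ectopic content of the label set."""
    cfg = cfg or TrainConfig()
    n_ectopic = len({"S", "V"} & set(labels))
    if n_ectopic == 2:
        return cfg.weights["ectopic_both"]
    if n_ectopic == 1:
        return cfg.weights["ectopic_single"]
    return cfg.weights["none"]


def supervised_loss(local: LocalPrediction, beats) -> float:
    """Categorical cross-entropy at annotated R peaks (excluded beats skipped)."""
    import warnings

    usable = [(p, c) for p, c in zip(beats.positions, beats.classes)
              if c in AAMI_CLASSES and p < local.n]
    if not usable:
        warnings.warn("no usable beats for supervised loss")
        return 0.0
    total = 0.0
    for pos, c in usable:
        p = float(np.clip(local.probs[pos, AAMI_CLASSES.index(c)], EPS, 1.0))
        total += np.log(p)
    return -total / len(usable)


# ---------------------------------------------------------------------------
# record preparation and batching
# ---------------------------------------------------------------------------


@dataclass
class PreparedRecord:
    """Fixed-length training view of one preprocessed record."""

    record_id: str
    signal: np.ndarray       # (L,)
    knowledge: np.ndarray    # (L, 2)
    peak_indices: np.ndarray
    beat_classes: list
    valid_n: int             # samples before zero padding
    label_set: set
    rate: float


def prepare_record(record: ECGRecord, feat_cfg: FeatureConfig | None = None,
                   pad_length: float = 20.0,
                   channels: tuple = ("relative_rr", "rr_entropy")) -> PreparedRecord:
    """Compute knowledge maps, then pad/truncate signal and maps together.

    Padding zeros carry no beats, so the feature maps are computed on the
    un-padded record and extended with zeros.
    """
    if record.beats is None:
        raise ValueError("record needs beat positions (annotations or detector)")
    feat_cfg = feat_cfg or FeatureConfig()
    rpeaks = RPeakSet(record.beats.positions, record.sampling_rate)
    kno = knowledge_features(rpeaks, len(record.samples), feat_cfg, channels)
    n_target = int(round(pad_length * record.sampling_rate))
    padded = pad_or_truncate(record, pad_length)
    if len(kno) >= n_target:
        kno = kno[:n_target]
    else:
        kno = np.concatenate([kno, np.zeros((n_target - len(kno), kno.shape[1]))])
    return PreparedRecord(
        record_id=record.record_id,
        signal=padded.samples,
        knowledge=kno,
        peak_indices=padded.beats.positions,
        beat_classes=list(padded.beats.classes),
        valid_n=min(len(record.samples), n_target),
        label_set=set(record.label_set),
        rate=record.sampling_rate,
    )


def _batch_arrays(records: list[PreparedRecord]):
    L = len(records[0].signal)
    B = len(records)
    sig = np.zeros((B, L, 1))
    kno = np.zeros((B, L, 2))
    peak_mask = np.zeros((B, L), dtype=bool)
    valid_mask = np.zeros((B, L), dtype=bool)
    targets = np.zeros((B, len(AAMI_CLASSES)))
    weights = np.zeros(B)
    for i, rec in enumerate(records):
        sig[i, :, 0] = rec.signal
        kno[i] = rec.knowledge
        peak_mask[i, rec.peak_indices] = True
        valid_mask[i, : rec.valid_n] = True
        for j, c in enumerate(AAMI_CLASSES):
            targets[i, j] = 1.0 if c in rec.label_set else 0.0
        weights[i] = 1.0
    return sig, kno, peak_mask, valid_mask, targets, weights


def weak_loss_graph(scores: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted batch mean of the per-record weak loss, on the tape."""
    s = scores.clip(EPS, 1 - EPS)
    t = Tensor(targets)
    bce = -(t * s.log() + (1.0 - t) * (1.0 - s).log()).mean(axis=1)
    return (bce * Tensor(weights)).mean()


# ---------------------------------------------------------------------------
# evaluation-mode helpers
# ---------------------------------------------------------------------------


def predict_local(model: BeatDetector, records: list[PreparedRecord],
                  batch_size: int = 32) -> np.ndarray:
    """Local probabilities for a list of same-length records, (R, L, 3)."""
    outs = []
    for i in range(0, len(records), batch_size):
        chunk = records[i : i + batch_size]
        sig, kno, *_ = _batch_arrays(chunk)
        probs = model.forward(Tensor(sig), Tensor(kno), train=False)
        outs.append(probs.data)
    return np.concatenate(outs, axis=0)


def beat_predictions(model: BeatDetector, records: list[PreparedRecord],
                     batch_size: int = 32):
    """Per-beat truth, argmax decisions, and class scores on evaluable beats.

    Returns (truth, pred, scores) where scores is (n_beats, 3) softmax
    probabilities at the R peaks.
    """
    probs = predict_local(model, records, batch_size)
    truth, pred, scores = [], [], []
    for rec, p in zip(records, probs):
        for pos, c in zip(rec.peak_indices, rec.beat_classes):
            if c not in AAMI_CLASSES:
                continue  # F/Q beats neither penalized nor rewarded
            row = p[pos]
            truth.append(c)
            pred.append(evaluation.decide(row))
            scores.append(row)
    return truth, pred, np.asarray(scores)


def _mean_f1(model: BeatDetector, records: list[PreparedRecord],
             batch_size: int) -> tuple[float, dict]:
    truth, pred, _ = beat_predictions(model, records, batch_size)
    per_class = {}
    for c in AAMI_CLASSES:
        counts = evaluation.confusion(pred, truth, c)
        per_class[c] = evaluation.rates(counts)[4]
    return float(np.mean(list(per_class.values()))), per_class


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def train_weak(model: BeatDetector, train_records: list[PreparedRecord],
               val_records: list[PreparedRecord], cfg: TrainConfig | None = None,
               agg: AggregationConfig | None = None):
    """Weakly supervised training from record-level labels.

    Minimizes the weighted weak loss with Adam, monitors the mean beat-level
    F1 over {N, S, V} on the validation records each epoch, stops when it
    has not increased for `patience` epochs, and restores the best epoch's
    parameters.  Fully seeded and deterministic.
    """
    cfg = cfg or TrainConfig()
    agg = agg or AggregationConfig()
    if not train_records or not val_records:
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    weights = np.array([sample_weight(r.label_set, cfg) for r in train_records])
    history = []
    best_f1, best_state, bad_epochs = -np.inf, model.state(), 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_records))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [train_records[i] for i in idx]
            sig, kno, peak_mask, valid_mask, targets, _ = _batch_arrays(batch)
            probs = model.forward(Tensor(sig), Tensor(kno), train=True, rng=rng)
            scores = aggregate_graph(probs, agg.method, peak_mask, valid_mask, agg.lse_b)
            loss = weak_loss_graph(scores, targets, weights[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= len(train_records)
        val_f1, per_class = _mean_f1(model, val_records, cfg.batch_size)
        history.append({"epoch": epoch, "loss": epoch_loss, "val_mean_f1": val_f1,
                        **{f"val_f1_{c}": per_class[c] for c in AAMI_CLASSES}})
        if val_f1 > best_f1:
            best_f1, best_state, bad_epochs = val_f1, model.state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.load_state(best_state)
    return model, pd.DataFrame(history)


def pretrain_supervised(model: BeatDetector, records: list[PreparedRecord],
                        epochs: int | None = None, cfg: TrainConfig | None = None):
    """Supervised pre-training on finely annotated records for a fixed budget.

    Categorical cross-entropy is applied to the local predictions at the
    R peaks of evaluable beats; no early stopping.
    """
    cfg = cfg or TrainConfig()
    epochs = cfg.pretrain_epochs if epochs is None else epochs
    if epochs == 0:
        return model
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    for _ in range(epochs):
        order = rng.permutation(len(records))
        for start in range(0, len(order), cfg.batch_size):
            batch = [records[i] for i in order[start : start + cfg.batch_size]]
            sig, kno, *_ = _batch_arrays(batch)
            onehot = np.zeros((len(batch), sig.shape[1], len(AAMI_CLASSES)))
            n_beats = 0
            for i, rec in enumerate(batch):
                for pos, c in zip(rec.peak_indices, rec.beat_classes):
                    if c in AAMI_CLASSES:
                        onehot[i, pos, AAMI_CLASSES.index(c)] = 1.0
                        n_beats += 1
            if n_beats == 0:
                continue
            probs = model.forward(Tensor(sig), Tensor(kno), train=True, rng=rng)
            loss = -(Tensor(onehot) * probs.clip(EPS, 1.0).log()).sum() * (1.0 / n_beats)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def two_stage_train(model: BeatDetector, fine_records: list[PreparedRecord],
                    coarse_records: list[PreparedRecord],
                    val_records: list[PreparedRecord],
                    cfg: TrainConfig | None = None,
                    agg: AggregationConfig | None = None):
    """Supervised pre-training followed by weak training (best weak model wins).

    With no fine records this reduces to pure weakly supervised training.
    """
    cfg = cfg or TrainConfig()
    if fine_records:
        pretrain_supervised(model, fine_records, cfg.pretrain_epochs, cfg)
    return train_weak(model, coarse_records, val_records, cfg, agg)
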