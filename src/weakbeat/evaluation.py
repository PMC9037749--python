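"""Beat-level decisions and AAMI-style evaluation metrics.

Each beat is classified by the local prediction at its R peak.  Per-class
one-vs-rest confusion counts give sensitivity, specificity, positive
predictivity, accuracy and F1; ranking the per-beat class scores gives the
precision-recall curve and its step-wise area (average precision,
``AP = Σ_n (Sen_n − Sen_{n−1}) · Ppr_n``).  Fusion and ambiguous beats are
excluded from all counts.  Undefined 0/0 ratios are reported as 0 and
flagged, so mean-F1 early stopping never propagates NaNs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AAMI_CLASSES
from .model_core import LocalPrediction
from .context_features import RPeakSet


def decide(prob_row: np.ndarray) -> str:
    """Class decision from one probability row; exact ties go to N."""
    row = np.asarray(prob_row, dtype=np.float64)
    best = row.max()
    if row[AAMI_CLASSES.index("N")] == best:
        return "N"  # ties favour the a-priori majority class
    return AAMI_CLASSES[int(np.argmax(row))]


def beat_decisions(local: LocalPrediction, rpeaks: RPeakSet) -> list:
    """Per-beat classes: argmax of the local probabilities at each R peak."""
    return [decide(local.probs[i]) for i in rpeaks.indices]


def confusion(pred, truth, c: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) counts for class c."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    pp, tp_ = pred == c, truth == c
    tp = int(np.sum(pp & tp_))
    fp = int(np.sum(pp & ~tp_))
    tn = int(np.sum(~pp & ~tp_))
    fn = int(np.sum(~pp & tp_))
    return tp, fp, tn, fn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def rates(counts) -> tuple[float, float, float, float, float]:
    """(Sen, Spe, Ppr, Acc, F1) from one-vs-rest counts; 0/0 reported as 0."""
    tp, fp, tn, fn = counts
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, fp + tn)
    ppr = _ratio(tp, tp + fp)
    acc = _ratio(tp + tn, tp + fp + tn + fn)
    f1 = _ratio(2 * sen * ppr, sen + ppr)
    return sen, spe, ppr, acc, f1


def average_precision(scores, truth) -> tuple[float, np.ndarray, np.ndarray]:
    """Step-wise average precision and the PRC points.

    Thresholds are placed at the distinct score values in descending
    order; returns (AP, Ppr_n, Sen_n).  With no positive beats the AP is
    undefined and reported as NaN.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    if n_pos == 0:
        return float("nan"), np.empty(0), np.empty(0)
    order = np.argsort(-scores, kind="stable")
    s_sorted, t_sorted = scores[order], truth[order]
    cum_tp = np.cumsum(t_sorted)
    ranks = np.arange(1, len(scores) + 1)
    # collapse ties: keep the last rank of each distinct score
    last = np.nonzero(np.append(np.diff(s_sorted) != 0, True))[0]
    sen = cum_tp[last] / n_pos
    ppr = cum_tp[last] / ranks[last]
    ap = float(np.sum(np.diff(np.concatenate([[0.0], sen])) * ppr))
    return ap, ppr, sen


def stability_summary(f1_per_seed) -> tuple[float, float]:
    """Sample mean and standard deviation over repeated training runs."""
    vals = np.asarray(f1_per_seed, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("no values")
    if vals.size == 1:
        return float(vals[0]), float("nan")
    return float(vals.mean()), float(vals.std(ddof=1))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-class confusion counts, rates, and PRC summaries."""

    counts: dict = field(default_factory=dict)   # class -> (TP, FP, TN, FN)
    metrics: dict = field(default_factory=dict)  # class -> dict of rates
    prc: dict = field(default_factory=dict)      # class -> (Ppr_n, Sen_n)
    ap: dict = field(default_factory=dict)       # class -> AP
    n_beats: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in AAMI_CLASSES:
            rows.append({"class": c, **dict(zip(("TP", "FP", "TN", "FN"), self.counts[c])),
                         **self.metrics[c], "AP": self.ap.get(c, float("nan"))})
        return pd.DataFrame(rows)

    def save(self, path_prefix: str) -> None:
        frame = self.to_frame()
        frame.to_csv(path_prefix + "_metrics.csv", index=False)
        payload = {"n_beats": self.n_beats,
                   "classes": {c: {**self.metrics[c], "AP": self.ap.get(c)}
                               for c in AAMI_CLASSES}}
        with open(path_prefix + "_metrics.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        for c in AAMI_CLASSES:
            ppr, sen = self.prc[c]
            pd.DataFrame({"Ppr": ppr, "Sen": sen}).to_csv(
                path_prefix + f"_prc_{c}.csv", index=False)


def evaluate_beats(truth, pred, scores) -> MetricsReport:
    """Build the full report from per-beat truth, decisions and scores."""
    truth = list(truth)
    report = MetricsReport(n_beats=len(truth))
    scores = np.asarray(scores)
    for j, c in enumerate(AAMI_CLASSES):
        cts = confusion(pred, truth, c)
        sen, spe, ppr, acc, f1 = rates(cts)
        report.counts[c] = cts
        report.metrics[c] = {"Sen": sen, "Spe": spe, "Ppr": ppr, "Acc": acc, "F1": f1}
        binary = np.asarray([t == c for t in truth])
        ap, prc_ppr, prc_sen = average_precision(scores[:, j], binary)
        report.ap[c] = ap
        report.prc[c] = (prc_ppr, prc_sen)
    return report
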