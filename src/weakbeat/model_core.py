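"""Network architecture, local (per-sample) prediction, and aggregation.

The detector follows a multiple-instance design: a 1-D residual
convolutional backbone extracts morphology features from the raw signal,
the feature maps are upsampled back to signal length and concatenated with
the two knowledge channels, and a time-distributed dense layer with
softmax yields a per-sample probability over {N, S, V}.  A record-level
score per class is then produced by an aggregation mechanism:

* GAP  — mean of local predictions,
* GMP  — max of local predictions,
* LSE  — log-sum-exp softened max, ``(1/b) log((1/n) Σ exp(b ŷ))``,
* MGMP — max restricted to R-peak indices (masked aggregation), which
  confines the training signal to one representative sample per beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .context_features import RPeakSet

CLASSES = ("N", "S", "V")
AGGREGATIONS = ("GAP", "GMP", "LSE", "MGMP")


@dataclass
class BackboneConfig:
    n_blocks: int = 4
    kernels: int = 32
    kernel_len: int = 8
    dropout: float = 0.25
    pool: int = 2

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def downsample(self) -> int:
        return self.pool**self.n_blocks


@dataclass
class AggregationConfig:
    method: str = "MGMP"
    lse_b: float = 5.0

    def __post_init__(self):
        if self.method not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.method!r}")
        if self.lse_b <= 0:
            raise ValueError("lse_b must be positive")


@dataclass
class LocalPrediction:
    """Per-sample class probabilities, rows summing to one."""

    probs: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(CLASSES):
            raise ValueError("probs must be (n, 3)")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class GlobalPrediction:
    scores: dict = field(default_factory=dict)  # class -> score in [0, 1]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.weight = ad.Parameter(_he_init(rng, c_in * k, (k, c_in, c_out)))
        self.bias = ad.Parameter(np.zeros(c_out))

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias)


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = ad.Parameter(_he_init(rng, c_in, (c_in, c_out)))
        self.bias = ad.Parameter(np.zeros(c_out))

    def params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ResBlock:
    """Conv-BN-ReLU-Dropout-Conv-BN, identity shortcut, ReLU, max-pool."""

    def __init__(self, channels: int, k: int, dropout: float, pool: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(channels, channels, k, rng)
        self.bn1 = ad.BatchNorm(channels)
        self.conv2 = Conv1d(channels, channels, k, rng)
        self.bn2 = ad.BatchNorm(channels)
        self.dropout = dropout
        self.pool = pool

    def params(self):
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        h = self.bn1(self.conv1(x), train).relu()
        if train:
            h = ad.dropout(h, self.dropout, rng)
        h = self.bn2(self.conv2(h), train)
        h = (h + x).relu()
        return ad.maxpool1d(h, self.pool)


class ResNetBackbone:
    """Initial channel-lifting convolution followed by residual blocks.

    Output length is ``floor(L / pool^n_blocks)`` with `kernels` channels.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator, c_in: int = 1):
        self.cfg = cfg
        self.stem = Conv1d(c_in, cfg.kernels, cfg.kernel_len, rng)
        self.blocks = [ResBlock(cfg.kernels, cfg.kernel_len, cfg.dropout, cfg.pool, rng)
                       for _ in range(cfg.n_blocks)]

    def params(self):
        out = self.stem.params()
        for b in self.blocks:
            out += b.params()
        return out

    def output_length(self, n: int) -> int:
        for _ in range(self.cfg.n_blocks):
            n //= self.cfg.pool
        return n

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if x.shape[1] < self.cfg.downsample:
            raise ValueError("input shorter than the backbone downsample factor")
        h = self.stem(x)
        for block in self.blocks:
            h = block(h, train, rng)
        return h


def build_backbone(cfg: BackboneConfig | None = None, seed: int = 0,
                   c_in: int = 1) -> ResNetBackbone:
    """Construct a ReLU-aware (He) initialized residual backbone."""
    return ResNetBackbone(cfg or BackboneConfig(), np.random.default_rng(seed), c_in)


class BeatDetector:
    """Backbone + knowledge-feature fusion + time-distributed softmax head."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None, seed: int = 0,
                 n_knowledge: int = 2):
        self.cfg = backbone_cfg or BackboneConfig()
        rng = np.random.default_rng(seed)
        self.backbone = ResNetBackbone(self.cfg, rng)
        self.head = Dense(self.cfg.kernels + n_knowledge, len(CLASSES), rng)

    def params(self):
        return self.backbone.params() + self.head.params()

    def forward(self, signal: Tensor, knowledge: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Per-sample class probabilities, shape (B, L, 3)."""
        if signal.shape[1] != knowledge.shape[1]:
            raise ValueError("signal and knowledge maps must have equal length")
        rng = rng or np.random.default_rng(0)
        feats = self.backbone(signal, train, rng)
        feats = ad.upsample_repeat(feats, self.cfg.downsample, signal.shape[1])
        merged = ad.concat([feats, knowledge], axis=-1)
        return self.head(merged).softmax(axis=-1)

    # -- parameter snapshots -------------------------------------------
    def state(self) -> list:
        arrays = [p.data.copy() for p in self.params()]
        for b in self.backbone.blocks:
            for bn in (b.bn1, b.bn2):
                arrays.append(bn.running_mean.copy())
                arrays.append(bn.running_var.copy())
        return arrays

    def load_state(self, arrays: list) -> None:
        params = self.params()
        for p, a in zip(params, arrays[: len(params)]):
            p.data = a.copy()
        rest = iter(arrays[len(params) :])
        for b in self.backbone.blocks:
            for bn in (b.bn1, b.bn2):
                bn.running_mean = next(rest).copy()
                bn.running_var = next(rest).copy()

    def save(self, path: str) -> None:
        np.savez(path, *self.state())

    def load(self, path: str) -> None:
        with np.load(path) as data:
            self.load_state([data[k] for k in data.files])


def local_predict(signal: np.ndarray, knowledge: np.ndarray,
                  model: BeatDetector) -> LocalPrediction:
    """Run the detector in evaluation mode on one record."""
    sig = Tensor(np.asarray(signal, dtype=np.float64).reshape(1, -1, 1))
    kno = Tensor(np.asarray(knowledge, dtype=np.float64).reshape(1, sig.shape[1], -1))
    probs = model.forward(sig, kno, train=False)
    return LocalPrediction(probs.data[0])


# ---------------------------------------------------------------------------
# aggregation mechanisms (evaluation-mode, plain numpy)
# ---------------------------------------------------------------------------


def _class_index(c) -> int:
    return CLASSES.index(c) if isinstance(c, str) else int(c)


def gap(local: LocalPrediction, c) -> float:
    """Global average pooling: mean local prediction for class c."""
    if local.n == 0:
        raise ValueError("no local predictions")
    return float(local.probs[:, _class_index(c)].mean())


def gmp(local: LocalPrediction, c) -> float:
    """Global max pooling: maximum local prediction for class c."""
    if local.n == 0:
        raise ValueError("no local predictions")
    return float(local.probs[:, _class_index(c)].max())


def lse(local: LocalPrediction, c, b: float = 5.0) -> float:
    """Log-sum-exp pooling, a convex approximation of the max (max-shifted)."""
    if b <= 0:
        raise ValueError("b must be positive")
    y = local.probs[:, _class_index(c)]
    m = y.max()
    return float(m + np.log(np.exp(b * (y - m)).mean()) / b)


def mgmp(local: LocalPrediction, rpeaks: RPeakSet, c) -> float:
    """Masked global max pooling: max over R-peak indices only."""
    if len(rpeaks) == 0:
        raise ValueError("masked aggregation requires at least one R peak")
    idx = rpeaks.indices
    if idx.max() >= local.n:
        raise ValueError("R-peak index beyond prediction length")
    return float(local.probs[idx, _class_index(c)].max())


def aggregate(local: LocalPrediction, cfg: AggregationConfig,
              rpeaks: RPeakSet | None = None) -> GlobalPrediction:
    """Apply the configured mechanism independently per class."""
    scores = {}
    for c in CLASSES:
        if cfg.method == "GAP":
            scores[c] = gap(local, c)
        elif cfg.method == "GMP":
            scores[c] = gmp(local, c)
        elif cfg.method == "LSE":
            scores[c] = lse(local, c, cfg.lse_b)
        else:
            if rpeaks is None:
                raise ValueError("MGMP requires R-peak positions")
            scores[c] = mgmp(local, rpeaks, c)
    return GlobalPrediction(scores)


# ---------------------------------------------------------------------------
# in-graph aggregation (training path)
# ---------------------------------------------------------------------------

_NEG = -1e9


def aggregate_graph(probs: Tensor, method: str, peak_mask: np.ndarray,
                    valid_mask: np.ndarray, lse_b: float = 5.0) -> Tensor:
    """Aggregate (B, L, 3) local probabilities to (B, 3) record scores.

    `peak_mask` selects R-peak samples (MGMP); `valid_mask` excludes padded
    samples from all mechanisms.
    """
    valid = valid_mask[:, :, None].astype(float)
    if method == "GAP":
        return (probs * Tensor(valid)).sum(axis=1) / Tensor(valid.sum(axis=1))
    if method == "GMP":
        gate = np.where(valid_mask[:, :, None], 0.0, _NEG)
        return (probs + Tensor(gate)).amax(axis=1)
    if method == "LSE":
        # max-shift per record/class for stability; the shift is a constant
        gate = np.where(valid_mask[:, :, None], 0.0, _NEG)
        shift = (probs.data + gate).max(axis=1, keepdims=True)
        e = ((probs - Tensor(shift)) * lse_b).exp() * Tensor(valid)
        mean_e = e.sum(axis=1) / Tensor(valid.sum(axis=1))
        return Tensor(shift[:, 0, :]) + mean_e.log() * (1.0 / lse_b)
    if method == "MGMP":
        gate = np.where(peak_mask[:, :, None], 0.0, _NEG)
        return (probs + Tensor(gate)).amax(axis=1)
    raise ValueError(f"unknown aggregation {method!r}")
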