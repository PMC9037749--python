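"""Knowledge-based per-sample feature maps built from R-peak positions.

Two contextual features are painted over the signal, one value per beat
region (the stretch between the midpoints of the neighbouring RR
intervals):

* **relative RR interval** — scaled fractional shortening of a beat's
  preceding RR interval against the mean RR of a 60-interval context
  window centered on it, ``s * (I_N - I_A) / I_N``.  Positive when the
  beat is premature, which suits ReLU-based networks that respond more
  readily to positive activations.
* **RR entropy** — sample entropy (m=1, r=0.05) of the median-normalized
  RR series in a sliding 60-interval window, mapped to the window's
  central heartbeat.  High values flag irregular rhythms (AF, bigeminy)
  in which a short RR does not imply ectopy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import bandpass


@dataclass
class RPeakSet:
    """Strictly increasing R-peak sample indices at a given sampling rate."""

    indices: np.ndarray
    rate: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self):
        return len(self.indices)

    @property
    def rr_seconds(self) -> np.ndarray:
        return np.diff(self.indices) / self.rate


@dataclass
class FeatureConfig:
    context_len: int = 60      # RR intervals in the relative-RR context
    scale_s: float = 10.0      # relative-RR scaling factor
    sampen_m: int = 1          # SampEn template length
    sampen_r: float = 0.05     # SampEn match threshold (on normalized RRs)
    entropy_window: int = 60   # RR intervals per entropy window
    sampen_cap: float | None = None  # None -> ln(n_pairs + 1)

    def __post_init__(self):
        if self.context_len < 2:
            raise ValueError("context_len must be >= 2")
        if self.sampen_r <= 0:
            raise ValueError("sampen_r must be positive")
        if self.entropy_window <= self.sampen_m + 1:
            raise ValueError("entropy_window must exceed sampen_m + 1")


@dataclass
class FeatureMap:
    """Per-sample feature channel aligned with the signal."""

    values: np.ndarray
    channel: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


# ---------------------------------------------------------------------------
# R-peak detection (classical energy detector; used when no annotations exist)
# ---------------------------------------------------------------------------


def detect_rpeaks(samples: np.ndarray, rate: float) -> RPeakSet:
    """Detect R peaks with band-limited energy + adaptive threshold.

    5-18 Hz band-pass concentrates QRS energy; the squared signal is
    integrated over 120 ms, peaks above an adaptive threshold are kept and
    a 200 ms refractory period suppresses T-wave double counts.  Callers
    with reference annotations should bypass this op.
    """
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < 2 * rate:
        warnings.warn("signal shorter than 2 s; no R peaks detected")
        return RPeakSet(np.empty(0, dtype=np.int64), rate)
    y = bandpass(x, rate, 5.0, min(18.0, rate / 2 - 1))
    energy = y**2
    win = max(1, int(round(0.12 * rate)))
    kernel = np.ones(win) / win
    env = np.convolve(energy, kernel, mode="same")
    thresh = 0.3 * np.quantile(env, 0.99)
    if thresh <= 0:
        return RPeakSet(np.empty(0, dtype=np.int64), rate)
    refractory = int(round(0.2 * rate))
    cand, _ = sps.find_peaks(env, height=thresh, distance=refractory)
    # refine each candidate to the local |y| maximum (true R position)
    half = int(round(0.06 * rate))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(y[lo:hi]))))
    peaks = np.unique(np.asarray(peaks, dtype=np.int64))
    return RPeakSet(peaks, rate)


# ---------------------------------------------------------------------------
# beat regions and feature painting
# ---------------------------------------------------------------------------


def beat_regions(rpeaks: RPeakSet, n_samples: int) -> list[tuple[int, int]]:
    """Partition [0, n_samples) into per-beat half-open intervals.

    Interior boundaries sit at the midpoint (floor) between adjacent
    peaks; the first region is extended to the record start and the last
    to its end.
    """
    p = rpeaks.indices
    if len(p) == 0:
        return [(0, n_samples)]
    bounds = [0]
    for a, b in zip(p[:-1], p[1:]):
        bounds.append(int((a + b) // 2))
    bounds.append(n_samples)
    return [(bounds[i], bounds[i + 1]) for i in range(len(p))]


def _context_window(center: int, n: int, width: int) -> tuple[int, int]:
    """Clamp a `width`-wide window centered at `center` into [0, n)."""
    if n <= width:
        return 0, n
    start = min(max(center - width // 2, 0), n - width)
    return start, start + width


def relative_rr_map(rpeaks: RPeakSet, n_samples: int,
                    cfg: FeatureConfig | None = None) -> FeatureMap:
    """Relative-RR feature map, one value per beat region."""
    cfg = cfg or FeatureConfig()
    regions = beat_regions(rpeaks, n_samples)
    values = np.zeros(n_samples)
    rr = np.diff(rpeaks.indices).astype(np.float64)
    if len(rr) == 0:
        warnings.warn("fewer than two R peaks; relative-RR map is all zero")
        return FeatureMap(values, "relative_rr")
    per_beat = np.zeros(len(rpeaks))
    for beat in range(1, len(rpeaks)):
        j = beat - 1  # index of the RR interval ending at this beat's peak
        lo, hi = _context_window(j, len(rr), cfg.context_len)
        i_n = rr[lo:hi].mean()
        i_a = rr[j]
        per_beat[beat] = cfg.scale_s * (i_n - i_a) / i_n
    per_beat[0] = per_beat[1] if len(rpeaks) > 1 else 0.0  # no preceding RR
    for beat, (lo, hi) in enumerate(regions):
        values[lo:hi] = per_beat[beat]
    return FeatureMap(values, "relative_rr")


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------


def sampen(sequence: np.ndarray, m: int = 1, r: float = 0.05,
           cap: float | None = None) -> float:
    """Sample entropy −ln(A/B) with Chebyshev template matching.

    B counts pairs of distinct length-m templates within distance r, A the
    same for length m+1; both counts use the first n−m template start
    positions (the standard convention, so a constant sequence scores
    exactly 0).  With no matches at either length the value is capped
    (default cap: ln(number of template pairs + 1)) to keep the feature
    finite.  Returns NaN for sequences shorter than m + 2.
    """
    x = np.asarray(sequence, dtype=np.float64)
    n = len(x)
    if n < m + 2:
        return float("nan")

    def count_pairs(length: int) -> int:
        nt = n - m  # same template count at both lengths
        templ = np.lib.stride_tricks.sliding_window_view(x, length)[:nt]
        # Chebyshev distance matrix over all template pairs
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=-1)
        within = d <= r
        return int((np.count_nonzero(within) - nt) // 2)  # i < j pairs

    b = count_pairs(m)
    a = count_pairs(m + 1)
    n_pairs = (n - m) * (n - m - 1) // 2
    cap_val = cap if cap is not None else float(np.log(n_pairs + 1))
    if b == 0:
        return cap_val
    if a == 0:
        return min(cap_val, float(np.log(b + 1)))
    return float(-np.log(a / b))


def rr_entropy_map(rpeaks: RPeakSet, n_samples: int,
                   cfg: FeatureConfig | None = None) -> FeatureMap:
    """RR-entropy feature map from sliding-window SampEn of normalized RRs."""
    cfg = cfg or FeatureConfig()
    regions = beat_regions(rpeaks, n_samples)
    values = np.zeros(n_samples)
    rr = np.diff(rpeaks.indices).astype(np.float64)
    if len(rr) == 0:
        warnings.warn("fewer than two R peaks; RR-entropy map is all zero")
        return FeatureMap(values, "rr_entropy")
    rr_norm = rr / np.median(rr)
    w = cfg.entropy_window
    per_beat = np.full(len(rpeaks), np.nan)
    if len(rr) <= w:
        val = sampen(rr_norm, cfg.sampen_m, cfg.sampen_r, cfg.sampen_cap)
        per_beat[:] = 0.0 if np.isnan(val) else val
    else:
        for start in range(len(rr) - w + 1):
            val = sampen(rr_norm[start : start + w], cfg.sampen_m, cfg.sampen_r, cfg.sampen_cap)
            central_beat = start + w // 2  # central heartbeat of the window
            per_beat[central_beat] = val
        # fill unpainted beats from the nearest painted neighbour
        painted = np.where(~np.isnan(per_beat))[0]
        for beat in np.where(np.isnan(per_beat))[0]:
            nearest = painted[np.argmin(np.abs(painted - beat))]
            per_beat[beat] = per_beat[nearest]
    for beat, (lo, hi) in enumerate(regions):
        values[lo:hi] = per_beat[beat]
    return FeatureMap(values, "rr_entropy")


def knowledge_features(rpeaks: RPeakSet, n_samples: int,
                       cfg: FeatureConfig | None = None,
                       channels: tuple = ("relative_rr", "rr_entropy")) -> np.ndarray:
    """Stack the requested knowledge channels into an (n_samples, k) array.

    Disabled channels (ablations) are replaced by zeros so the model input
    width stays fixed.
    """
    cfg = cfg or FeatureConfig()
    cols = []
    for name in ("relative_rr", "rr_entropy"):
        if name in channels:
            fmap = (relative_rr_map if name == "relative_rr" else rr_entropy_map)(
                rpeaks, n_samples, cfg)
            cols.append(fmap.values)
        else:
            cols.append(np.zeros(n_samples))
    return np.stack(cols, axis=-1)
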