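"""Signal conditioning and record-label complementation.

The pipeline unifies noise level, sampling rate and amplitude before
feature extraction: (1) subtract a one-second centered moving average to
remove baseline wander, (2) zero-phase band-pass 0.1-30 Hz, (3) resample to
125 Hz (skipped when the native rate is already within a small tolerance),
(4) standardize to zero mean / unit variance.  Records are then padded or
truncated to a fixed 20 s window for batch training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io_formats import AAMI_CLASSES, BeatAnnotation, ECGRecord


@dataclass
class PreprocessConfig:
    baseline_window: float = 1.0   # s
    band_low: float = 0.1          # Hz
    band_high: float = 30.0        # Hz
    target_rate: float = 125.0     # Hz
    resample_tolerance: float = 3.0  # Hz
    pad_length: float = 20.0       # s

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high < self.target_rate / 2:
            raise ValueError("require 0 < band_low < band_high < target_rate/2")


def remove_baseline(samples: np.ndarray, rate: float, window: float = 1.0) -> np.ndarray:
    """Subtract a centered moving average (shrinking windows at the edges)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    width = int(round(window * rate))
    if width < 1:
        raise ValueError("window shorter than one sample")
    half_l = (width - 1) // 2
    half_r = width // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, x.size)
    baseline = (csum[hi] - csum[lo]) / (hi - lo)
    return x - baseline


def bandpass(samples: np.ndarray, rate: float, low: float = 0.1, high: float = 30.0) -> np.ndarray:
    """Zero-phase (forward-backward) 2nd-order Butterworth band-pass."""
    if rate <= 2 * high:
        raise ValueError(f"sampling rate {rate} Hz cannot represent {high} Hz band edge")
    x = np.asarray(samples, dtype=np.float64)
    sos = sps.butter(2, [low, high], btype="bandpass", fs=rate, output="sos")
    padlen = min(x.size - 1, 3 * 30)
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def resample_to(samples: np.ndarray, rate: float, target: float = 125.0,
                tolerance: float = 3.0) -> tuple[np.ndarray, float]:
    """Polyphase resampling to `target` Hz; rates within `tolerance` pass through."""
    x = np.asarray(samples, dtype=np.float64)
    if abs(rate - target) <= tolerance:
        return x, rate
    frac = Fraction(target / rate).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(len(x) * target / rate))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.concatenate([y, np.full(n_out - len(y), y[-1])])
    return y, target


def normalize(samples: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit variance; constant input becomes zeros."""
    x = np.asarray(samples, dtype=np.float64)
    sd = x.std()
    if sd == 0:
        warnings.warn("constant signal; normalization returns zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def complement_labels(label_set: set) -> set:
    """Add N to an ectopic-only label set.

    A record labelled with SVEB or VEB almost always also contains sinus
    beats — unless the ectopy is part of a sustained rhythm, which the
    auxiliary tags (supraventricular tachyarrhythmia, idioventricular
    rhythm) flag.  Idempotent.
    """
    out = set(label_set)
    if ({"S", "V"} & out) and not ({"SVTA", "IVR"} & out):
        out.add("N")
    return out


def pad_or_truncate(record: ECGRecord, pad_length: float = 20.0) -> ECGRecord:
    """Fix the sample count to round(pad_length * rate); zero-pad at the end.

    Beats beyond the cut are dropped.
    """
    n_target = int(round(pad_length * record.sampling_rate))
    x = record.samples
    if len(x) >= n_target:
        y = x[:n_target].copy()
    else:
        y = np.concatenate([x, np.zeros(n_target - len(x))])
    beats = record.beats
    if beats is not None:
        keep = beats.positions < n_target
        beats = BeatAnnotation(beats.positions[keep], [c for c, k in zip(beats.classes, keep) if k])
    return replace(record, samples=y, beats=beats)


def preprocess_record(record: ECGRecord, cfg: PreprocessConfig | None = None,
                      pad: bool = False) -> ECGRecord:
    """Full conditioning pipeline: baseline -> band-pass -> resample -> normalize.

    Beat positions are rescaled along with the sampling rate and the
    record-level label set is complemented.  Padding to the fixed training
    length is optional so that feature extraction can run on full records.
    """
    cfg = cfg or PreprocessConfig()
    x = remove_baseline(record.samples, record.sampling_rate, cfg.baseline_window)
    x = bandpass(x, record.sampling_rate, cfg.band_low, cfg.band_high)
    x, new_rate = resample_to(x, record.sampling_rate, cfg.target_rate, cfg.resample_tolerance)
    x = normalize(x)
    beats = record.beats
    if beats is not None and new_rate != record.sampling_rate:
        scaled = np.round(beats.positions * new_rate / record.sampling_rate).astype(np.int64)
        scaled = np.minimum(scaled, len(x) - 1)
        beats = BeatAnnotation(scaled, list(beats.classes))
    out = replace(record, samples=x, sampling_rate=new_rate, beats=beats,
                  label_set=complement_labels(record.label_set))
    if pad:
        out = pad_or_truncate(out, cfg.pad_length)
    return out
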