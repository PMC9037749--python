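"""Native reader for WFDB-style records (.hea/.dat) and MIT annotation files.

Covers the subset of the format family that single-lead arrhythmia work
needs: text headers, signal formats 16 (interleaved little-endian int16)
and 212 (packed 12-bit pairs), and beat annotations stored in the MIT
annotation byte stream.  Writing WFDB binaries is out of scope.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

# MIT annotation type codes -> PhysioBank symbols (beat annotations only).
ANNOTATION_CODES = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 25: "B", 30: "?",
    34: "e", 35: "n", 38: "f", 41: "r",
}
BEAT_SYMBOLS = set(ANNOTATION_CODES.values())

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    filename: str
    fmt: int
    gain: float
    baseline: int
    description: str


@dataclass
class Header:
    record_name: str
    n_signals: int
    sampling_rate: float
    n_samples: int
    signals: list = field(default_factory=list)


def parse_header(text: str) -> Header:
    lines = [ln.strip() for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty WFDB header")
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    hdr = Header(name, n_sig, fs, n_samp)
    for ln in lines[1 : 1 + n_sig]:
        toks = ln.split()
        fname = toks[0]
        fmt = int(re.match(r"(\d+)", toks[1]).group(1))
        gain, baseline = 200.0, None
        if len(toks) > 2:
            m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?", toks[2])
            if m:
                gain = float(m.group(1)) or 200.0
                if m.group(2) is not None:
                    baseline = int(m.group(2))
        adc_zero = int(toks[4]) if len(toks) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(toks[8:]) if len(toks) > 8 else f"ch{len(hdr.signals)}"
        hdr.signals.append(SignalSpec(fname, fmt, gain, baseline, description))
    return hdr


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_triplets = len(b) // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    first = b[:, 0] + ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] + ((b[:, 1] & 0xF0) << 4)
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    out = np.empty(n_triplets * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    return out[:n_values]


def read_signals(header_path: str) -> tuple[Header, np.ndarray]:
    """Read all channels of a WFDB record; returns (header, (n, n_sig) mV array)."""
    with open(header_path) as fh:
        hdr = parse_header(fh.read())
    base_dir = os.path.dirname(os.path.abspath(header_path))
    # group signals by their .dat file (samples interleaved within a file)
    physical = np.empty((hdr.n_samples, hdr.n_signals))
    by_file: dict[str, list[int]] = {}
    for i, sig in enumerate(hdr.signals):
        by_file.setdefault(sig.filename, []).append(i)
    for fname, idxs in by_file.items():
        with open(os.path.join(base_dir, fname), "rb") as fh:
            raw = fh.read()
        fmt = hdr.signals[idxs[0]].fmt
        n_vals = hdr.n_samples * len(idxs)
        if fmt == 212:
            flat = _decode_212(raw, n_vals)
        elif fmt == 16:
            flat = np.frombuffer(raw, dtype="<i2")[:n_vals].astype(np.int32)
        else:
            raise ValueError(f"unsupported WFDB signal format {fmt}")
        if hdr.n_samples == 0:
            hdr.n_samples = len(flat) // len(idxs)
            physical = np.empty((hdr.n_samples, hdr.n_signals))
            flat = flat[: hdr.n_samples * len(idxs)]
        frames = flat.reshape(-1, len(idxs))
        for col, i in enumerate(idxs):
            sig = hdr.signals[i]
            physical[:, i] = (frames[:, col] - sig.baseline) / sig.gain
    return hdr, physical


def read_annotations(path: str) -> tuple[np.ndarray, list[str]]:
    """Decode an MIT annotation file into (sample positions, symbols).

    Only beat annotations are returned; rhythm/quality annotations are
    consumed and dropped.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    positions, symbols = [], []
    t = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code = w >> 10
        delta = w & 0x3FF
        i += 1
        if code == 0 and delta == 0:  # EOF
            break
        if code == _SKIP:
            if delta == 0:
                # next two words hold a 32-bit interval (PDP-11 order)
                hi, lo = int(words[i]), int(words[i + 1])
                t += (hi << 16) + lo
                i += 2
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += (delta + 1) // 2  # aux string padded to word boundary
            continue
        t += delta
        sym = ANNOTATION_CODES.get(code)
        if sym is not None:
            positions.append(t)
            symbols.append(sym)
    return np.asarray(positions, dtype=np.int64), symbols
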