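"""Seeded synthetic single-lead ECG with known beat-level truth.

Beat morphologies are parametric sums of Gaussian bumps (P, Q, R, S, T
waves).  Rhythm grammars place the beats:

* ``sinus`` — RR ~ base ± jitter; optional random ectopic events.  An
  SVEB shortens its preceding RR to U(0.55, 0.8)·base and is followed by
  a non-compensatory (roughly normal) cycle; a VEB shortens likewise but
  is followed by a compensatory pause (the flanking RRs sum to two
  cycles).
* ``af_like`` — i.i.d. irregular RRs, U(0.6, 1.1)·base, all beats N: a
  hard negative for RR-based features.
* ``bigeminy_S`` / ``bigeminy_V`` — alternating sinus/ectopic beats.
* ``mixed`` — sinus grammar with both ectopic classes enabled.

SVEB templates share the narrow QRS of sinus beats (only the P wave is
absent), so morphology alone cannot separate S from N — the RR-context
features have to carry that distinction, mirroring the clinical picture.
VEB templates have a wide, high-amplitude QRS with discordant T wave.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import BeatAnnotation, ECGRecord, derive_record_labels
from .preprocess import complement_labels

RHYTHMS = ("sinus", "af_like", "bigeminy_S", "bigeminy_V", "mixed")


@dataclass
class SynthSpec:
    rate: float = 125.0
    duration: float = 20.0
    base_rr: float = 0.8        # s, mean sinus cycle
    rr_jitter: float = 0.03     # s, sd of sinus RR
    p_ectopic_s: float = 0.0    # per-beat probability of an SVEB event
    p_ectopic_v: float = 0.0    # per-beat probability of a VEB event
    rhythm: str = "sinus"
    noise_sd: float = 0.03      # mV white noise
    wander_amp: float = 0.1     # mV baseline drift
    wander_freq: float = 0.3    # Hz
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_ectopic_s <= 1 or not 0 <= self.p_ectopic_v <= 1:
            raise ValueError("ectopic probabilities must lie in [0, 1]")
        if self.base_rr <= 0.25:
            raise ValueError("base_rr must exceed 0.25 s")
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}")


# ---------------------------------------------------------------------------
# beat morphology
# ---------------------------------------------------------------------------

# (center s, amplitude mV, width s) per wave, relative to the R peak
_WAVES = {
    "N": [(-0.18, 0.15, 0.025), (-0.028, -0.12, 0.012), (0.0, 1.0, 0.012),
          (0.030, -0.20, 0.014), (0.22, 0.30, 0.060)],
    # SVEB: sinus QRS and T, absent P wave
    "S": [(-0.028, -0.12, 0.012), (0.0, 1.0, 0.012),
          (0.030, -0.20, 0.014), (0.22, 0.30, 0.060)],
    # VEB: wide high QRS, discordant T, no P
    "V": [(-0.055, -0.15, 0.030), (0.0, 1.0, 0.035),
          (0.095, -0.35, 0.040), (0.30, -0.35, 0.070)],
}
_PRE, _POST = 0.30, 0.45  # template extent around the R peak, s


def beat_template(kind: str, rate: float) -> tuple[np.ndarray, int]:
    """Deterministic beat waveform; returns (samples, index of the R peak).

    Templates are peak-normalized to 1 mV.
    """
    if kind not in _WAVES:
        raise ValueError(f"unknown beat kind {kind!r}")
    t = np.arange(-_PRE, _POST, 1.0 / rate)
    y = np.zeros_like(t)
    for center, amp, width in _WAVES[kind]:
        y += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    y /= np.abs(y).max()
    return y, int(np.argmin(np.abs(t)))


def qrs_width(kind: str, rate: float = 500.0, frac: float = 0.05) -> float:
    """Width (s) of the template's QRS complex above `frac` of peak amplitude."""
    y, r_idx = beat_template(kind, rate)
    lo = int(r_idx - 0.12 * rate)
    hi = int(r_idx + 0.16 * rate)
    seg = np.abs(y[lo:hi])
    above = np.nonzero(seg > frac)[0]
    return (above[-1] - above[0]) / rate


# ---------------------------------------------------------------------------
# rhythm grammar
# ---------------------------------------------------------------------------


def _beat_sequence(spec: SynthSpec, rng: np.random.Generator):
    """Yield (time s, kind) beat events covering the record duration."""
    base, jit = spec.base_rr, spec.rr_jitter
    t_max = spec.duration - 0.35
    times, kinds = [0.4], ["N"]

    def sinus_rr():
        return max(0.3, base + jit * rng.standard_normal())

    if spec.rhythm == "af_like":
        while times[-1] < t_max:
            times.append(times[-1] + base * rng.uniform(0.6, 1.1))
            kinds.append("N")
    elif spec.rhythm in ("bigeminy_S", "bigeminy_V"):
        ect = spec.rhythm[-1]
        while times[-1] < t_max:
            if kinds[-1] == "N":
                rr = base * rng.uniform(0.55, 0.8)
                kinds.append(ect)
            else:
                short = times[-1] - times[-2]
                if ect == "V":
                    rr = 2 * base - short  # compensatory pause
                else:
                    rr = base * rng.uniform(1.0, 1.2)  # non-compensatory
                kinds.append("N")
            times.append(times[-1] + rr)
    else:  # sinus / mixed
        p_s = spec.p_ectopic_s
        p_v = spec.p_ectopic_v
        prev_short = None
        while times[-1] < t_max:
            if kinds[-1] == "V" and prev_short is not None:
                rr, kind = 2 * base - prev_short, "N"
                prev_short = None
            else:
                u = rng.random()
                if kinds[-1] == "N" and u < p_s:
                    rr, kind = base * rng.uniform(0.55, 0.8), "S"
                    prev_short = None
                elif kinds[-1] == "N" and u < p_s + p_v:
                    rr, kind = base * rng.uniform(0.55, 0.8), "V"
                    prev_short = rr
                else:
                    rr, kind = sinus_rr(), "N"
                    prev_short = None
            times.append(times[-1] + rr)
            kinds.append(kind)
    if times[-1] >= t_max:
        times, kinds = times[:-1], kinds[:-1]
    return times, kinds


def generate_record(spec: SynthSpec) -> ECGRecord:
    """Generate one record with truth annotations and a complemented label set."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    times, kinds = _beat_sequence(spec, rng)
    x = np.zeros(n)
    positions = []
    for t, kind in zip(times, kinds):
        tpl, r_idx = beat_template(kind, spec.rate)
        # small per-beat amplitude variation keeps N and S overlapping
        amp = rng.uniform(0.9, 1.1)
        start = int(round(t * spec.rate)) - r_idx
        lo, hi = max(0, start), min(n, start + len(tpl))
        x[lo:hi] += amp * tpl[lo - start : hi - start]
        positions.append(start + r_idx)
    phase = rng.uniform(0, 2 * np.pi)
    tgrid = np.arange(n) / spec.rate
    x += spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq * tgrid + phase)
    x += rng.normal(0, spec.noise_sd, n)
    beats = BeatAnnotation(np.asarray(positions, dtype=np.int64), list(kinds))
    label_set = complement_labels(derive_record_labels(beats))
    return ECGRecord(record_id=f"synth-{spec.seed}", samples=x,
                     sampling_rate=spec.rate, lead="II",
                     label_set=label_set, beats=beats)


# ---------------------------------------------------------------------------
# corpora
# ---------------------------------------------------------------------------

CATEGORIES = ("S_only", "V_only", "both", "neither")


def _category_of(record: ECGRecord) -> str:
    present = derive_record_labels(record.beats)
    has_s, has_v = "S" in present, "V" in present
    if has_s and has_v:
        return "both"
    if has_s:
        return "S_only"
    if has_v:
        return "V_only"
    return "neither"


def _spec_for_category(category: str, base: SynthSpec,
                       rng: np.random.Generator) -> SynthSpec:
    if category == "S_only":
        if rng.random() < 0.25:
            return replace(base, rhythm="bigeminy_S", p_ectopic_s=0, p_ectopic_v=0)
        return replace(base, rhythm="sinus", p_ectopic_s=0.12, p_ectopic_v=0)
    if category == "V_only":
        if rng.random() < 0.25:
            return replace(base, rhythm="bigeminy_V", p_ectopic_s=0, p_ectopic_v=0)
        return replace(base, rhythm="sinus", p_ectopic_s=0, p_ectopic_v=0.12)
    if category == "both":
        return replace(base, rhythm="mixed", p_ectopic_s=0.10, p_ectopic_v=0.10)
    if rng.random() < 0.3:
        return replace(base, rhythm="af_like", p_ectopic_s=0, p_ectopic_v=0)
    return replace(base, rhythm="sinus", p_ectopic_s=0, p_ectopic_v=0)


def generate_dataset(n_records: int, class_mix=(0.2, 0.2, 0.1, 0.5),
                     seed: int = 0, base_spec: SynthSpec | None = None) -> list[ECGRecord]:
    """Reproducible corpus with fixed fractions of S-only / V-only / both /
    neither records.

    Per-record seeds are derived from the master seed; a record is
    regenerated with a fresh sub-seed if its sampled rhythm failed to
    express the requested category.
    """
    mix = np.asarray(class_mix, dtype=np.float64)
    if mix.size != 4 or mix.sum() <= 0 or np.any(mix < 0):
        raise ValueError("class_mix must be four non-negative fractions")
    mix = mix / mix.sum()
    counts = np.floor(mix * n_records).astype(int)
    while counts.sum() < n_records:  # distribute rounding remainder
        counts[int(np.argmax(mix * n_records - counts))] += 1
    base = base_spec or SynthSpec()
    rng = np.random.default_rng(seed)
    records = []
    for category, count in zip(CATEGORIES, counts):
        for _ in range(count):
            for _attempt in range(30):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                spec = _spec_for_category(category, replace(base, seed=sub_seed), rng)
                rec = generate_record(spec)
                if _category_of(rec) == category:
                    break
            else:
                raise RuntimeError(f"could not realize category {category}")
            rec.record_id = f"synth-{seed}-{len(records):04d}-{category}"
            records.append(rec)
    return records
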