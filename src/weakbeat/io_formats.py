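"""Record and annotation I/O, label vocabularies, and AAMI class mapping.

Beat classes follow ANSI/AAMI EC57: N (normal and bundle-branch-block
beats), S (supraventricular ectopic), V (ventricular ectopic).  Fusion (F)
and ambiguous/paced (Q) beats are retained in annotations with an excluded
marker — they stay visible to RR-based features but are skipped by losses
and metrics.

Two on-disk formats are supported: WFDB-style records (.hea/.dat with MIT
annotation sidecars) and a plain-text columnar fallback (one header line,
one sample per line, beats in a ``.beats`` sidecar of ``index symbol``
pairs).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import wfdb_io

AAMI_CLASSES = ("N", "S", "V")
EXCLUDED_CLASSES = ("F", "Q", "X")  # X marks symbols with no known mapping
#: auxiliary rhythm tags consulted by the label-complementation rule
AUX_TAGS = ("SVTA", "IVR")
LABEL_VOCABULARY = AAMI_CLASSES + AUX_TAGS

#: PhysioBank beat symbol -> AAMI class (EC57 grouping)
PHYSIOBANK_TO_AAMI = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N", "B": "N", "n": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V", "r": "V",
    "F": "F",
    "Q": "Q", "/": "Q", "f": "Q", "?": "Q",
}


@dataclass
class BeatAnnotation:
    """Per-beat positions (sample indices) and class symbols."""

    positions: np.ndarray
    classes: list

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) != len(self.classes):
            raise ValueError("positions and classes must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("beat positions must be strictly increasing")

    def __len__(self):
        return len(self.positions)

    @property
    def evaluable(self) -> np.ndarray:
        """Boolean mask of beats that enter losses and metrics."""
        return np.array([c in AAMI_CLASSES for c in self.classes], dtype=bool)


@dataclass
class ECGRecord:
    """One lead of one recording plus its labels."""

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    lead: str = ""
    label_set: set = field(default_factory=set)
    beats: BeatAnnotation | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        unknown = set(self.label_set) - set(LABEL_VOCABULARY)
        if unknown:
            raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class LabelMapping:
    """Mapping from a source label vocabulary to AAMI classes."""

    source_vocabulary: str
    mapping: dict

    def apply(self, symbol: str) -> str:
        if symbol in self.mapping:
            return self.mapping[symbol]
        warnings.warn(f"unknown {self.source_vocabulary} symbol {symbol!r}; excluding")
        return "X"


def physiobank_mapping() -> LabelMapping:
    return LabelMapping("PhysioBank-symbol", dict(PHYSIOBANK_TO_AAMI))


def snomed_mapping() -> LabelMapping:
    """SNOMED CT code -> AAMI class / auxiliary tag, shipped as package data."""
    with resources.files("weakbeat.data").joinpath("snomed_aami.json").open() as fh:
        table = json.load(fh)
    return LabelMapping("SNOMED-code", table)


def map_beat_symbols(beats: BeatAnnotation, mapping: LabelMapping | None = None) -> BeatAnnotation:
    """Replace source beat symbols with AAMI classes (idempotent).

    F/Q symbols and unknown symbols are kept with excluded markers so that
    R-peak geometry is preserved.
    """
    if mapping is None:
        mapping = physiobank_mapping()
    # "N", "S", "V", "F" and "Q" double as PhysioBank symbols with the same
    # AAMI meaning, and "X" is passed through, so the op is idempotent.
    mapped = [sym if sym == "X" else mapping.apply(sym) for sym in beats.classes]
    return BeatAnnotation(beats.positions.copy(), mapped)


def derive_record_labels(beats: BeatAnnotation) -> set:
    """Record-level label set: AAMI classes present among evaluable beats."""
    return {c for c in beats.classes if c in AAMI_CLASSES}


# ---------------------------------------------------------------------------
# columnar plain-text format
# ---------------------------------------------------------------------------


def write_columnar(record: ECGRecord, path: str) -> None:
    labels = ",".join(sorted(record.label_set)) or "-"
    with open(path, "w") as fh:
        fh.write(f"# record_id={record.record_id} rate={record.sampling_rate!r} "
                 f"lead={record.lead or '-'} labels={labels}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    if record.beats is not None:
        with open(path + ".beats", "w") as fh:
            for pos, sym in zip(record.beats.positions, record.beats.classes):
                fh.write(f"{pos} {sym}\n")


def read_columnar(path: str) -> ECGRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        samples = np.array([float(ln) for ln in fh if ln.strip()])
    fields = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    labels = set() if fields["labels"] == "-" else set(fields["labels"].split(","))
    beats = None
    if os.path.exists(path + ".beats"):
        positions, classes = [], []
        with open(path + ".beats") as fh:
            for ln in fh:
                if ln.strip():
                    pos, sym = ln.split()
                    positions.append(int(pos))
                    classes.append(sym)
        beats = BeatAnnotation(np.asarray(positions, dtype=np.int64), classes)
    return ECGRecord(
        record_id=fields["record_id"],
        samples=samples,
        sampling_rate=float(fields["rate"]),
        lead="" if fields["lead"] == "-" else fields["lead"],
        label_set=labels,
        beats=beats,
    )


# ---------------------------------------------------------------------------
# record reading with lead preference
# ---------------------------------------------------------------------------

DEFAULT_LEAD_PREFERENCE = ("II", "MLII")


def read_record(path: str, lead_preference=DEFAULT_LEAD_PREFERENCE) -> ECGRecord:
    """Read a record from WFDB-style or columnar storage.

    For multi-lead WFDB records the preferred lead (lead II, else MLII, else
    the first channel) is selected.  Beat annotations are loaded from an
    ``.atr`` sidecar when present and kept in source symbols.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".hea"):
        hdr, physical = wfdb_io.read_signals(path)
        if hdr.n_signals == 0:
            raise ValueError(f"record {path} declares no channels")
        names = [s.description for s in hdr.signals]
        idx = 0
        for wanted in lead_preference:
            matches = [i for i, nm in enumerate(names) if nm.upper() == wanted.upper()]
            if matches:
                idx = matches[0]
                break
        beats = None
        ann_path = path[: -len(".hea")] + ".atr"
        if os.path.exists(ann_path):
            positions, symbols = wfdb_io.read_annotations(ann_path)
            beats = BeatAnnotation(positions, symbols)
        return ECGRecord(
            record_id=hdr.record_name,
            samples=physical[:, idx],
            sampling_rate=hdr.sampling_rate,
            lead=names[idx],
            label_set=set(),
            beats=beats,
        )
    return read_columnar(path)
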