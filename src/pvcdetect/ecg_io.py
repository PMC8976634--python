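"""ECG record ingestion, AAMI beat classes, and the train/test partition.

The MIT-BIH Arrhythmia Database annotates every heartbeat with a
single-character symbol.  Following AAMI EC57 practice these collapse to
five classes — N (normal/bundle-branch), S (supraventricular ectopic),
V (ventricular ectopic), F (fusion), Q (unknown/paced) — and for PVC
recognition the task is binarized to V vs. everything else.  Records
102, 104, 107 and 217 contain paced beats and are excluded; the
remaining 44 records split into 22 training and 22 test records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import wfdb

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

# WFDB beat symbol -> AAMI class (EC57 grouping).
AAMI_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N", "B": "N",
    "A": "S", "a": "S", "J": "S", "S": "S", "n": "S",
    "V": "V", "E": "V", "r": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q", "?": "Q",
}

#: Symbols that denote heartbeats (everything else — rhythm changes,
#: signal-quality flags, wave boundaries — is dropped on read).
BEAT_SYMBOLS = frozenset(AAMI_MAP)

# Paced records conventionally excluded from AAMI evaluation.
EXCLUDED_IDS = ("102", "104", "107", "217")

# Inter-patient partition: Data1 trains, Data2 tests.
DATA1_TRAIN_IDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)
DATA2_TEST_IDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


def map_aami_class(symbol: str) -> str:
    """Map a WFDB beat symbol to its AAMI class.

    Unknown beat codes fall into Q, AAMI's catch-all class, with a
    logged warning rather than an error.
    """
    try:
        return AAMI_MAP[symbol]
    except KeyError:
        logger.warning("unknown beat annotation symbol %r mapped to Q",
                       symbol)
        return "Q"


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat."""

    sample_index: int
    symbol: str
    aami_class: str
    is_pvc: bool

    @classmethod
    def from_symbol(cls, sample_index: int, symbol: str) -> "BeatAnnotation":
        aami = map_aami_class(symbol)
        return cls(int(sample_index), symbol, aami, aami == "V")


@dataclass
class ECGRecord:
    """A sampled ECG with per-beat annotations.

    ``signal`` has shape ``(n_leads, n_samples)`` in mV; ``annotations``
    are sorted by sample index and restricted to beat annotations.
    """

    record_id: str
    fs: float
    leads: list[str]
    signal: np.ndarray
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        idx = [a.sample_index for a in self.annotations]
        if idx != sorted(idx):
            raise ValueError("annotations must be sorted by sample index")
        if idx and idx[-1] >= self.signal.shape[1]:
            raise ValueError("annotation index beyond signal extent")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def r_indices(self) -> np.ndarray:
        return np.asarray([a.sample_index for a in self.annotations],
                          dtype=np.int64)

    def pvc_mask(self) -> np.ndarray:
        return np.asarray([a.is_pvc for a in self.annotations], dtype=bool)


@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    excluded_ids: list[str]


def read_record(path: str, lead_preference: str = "MLII") -> ECGRecord:
    """Read a WFDB record triplet; preferred lead is moved first.

    Signal values are gain-corrected to mV.  Only beat annotations are
    kept; a record with no beat annotations is returned with an empty
    annotation list and a warning.
    """
    header = wfdb.read_header(path)
    signal = wfdb.read_signal(path, header)
    leads = [s.description or f"ch{i}" for i, s in enumerate(header.signals)]
    if lead_preference in leads:
        j = leads.index(lead_preference)
        order = [j] + [i for i in range(len(leads)) if i != j]
        leads = [leads[i] for i in order]
        signal = signal[order]
    atr_path = (path[:-4] if path.endswith(".hea") else path) + ".atr"
    annotations: list[BeatAnnotation] = []
    try:
        pairs = wfdb.read_annotations(atr_path)
    except FileNotFoundError:
        pairs = []
    for sample, symbol in pairs:
        if symbol in BEAT_SYMBOLS and sample < signal.shape[1]:
            annotations.append(BeatAnnotation.from_symbol(sample, symbol))
    if not annotations:
        logger.warning("record %s has no beat annotations",
                       header.record_name)
    return ECGRecord(header.record_name, header.fs, leads, signal,
                     annotations)


def write_record(record: ECGRecord, directory: str) -> str:
    """Write a record as a format-16 WFDB triplet; returns the base path."""
    pairs = [(a.sample_index, a.symbol) for a in record.annotations]
    return wfdb.write_record(directory, record.record_id, record.signal,
                             record.fs, record.leads, pairs)


def build_split(available_ids: list[str] | None = None) -> DatasetSplit:
    """The canonical 22/22 inter-patient partition, restricted to
    `available_ids` when given (missing records are logged, paced
    records are always excluded)."""
    if available_ids is None:
        avail = set(DATA1_TRAIN_IDS) | set(DATA2_TEST_IDS)
    else:
        avail = {str(r) for r in available_ids} - set(EXCLUDED_IDS)
        missing = (set(DATA1_TRAIN_IDS) | set(DATA2_TEST_IDS)) - avail
        if missing:
            logger.info("records absent from split: %s",
                        ", ".join(sorted(missing)))
    return DatasetSplit(
        train_ids=[r for r in DATA1_TRAIN_IDS if r in avail],
        test_ids=[r for r in DATA2_TEST_IDS if r in avail],
        excluded_ids=list(EXCLUDED_IDS),
    )
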