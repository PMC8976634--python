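"""Window segmentation, the 10-feature vector, labels and normalization.

Records are cut into consecutive non-overlapping 20 s windows.  Each
window yields seven time-domain heart-rate-variability statistics over
its RR intervals —

* ``MeanRR``  mean RR interval (ms)
* ``SDRR``    population standard deviation of RR intervals (ms)
* ``SDSD``    population standard deviation of successive RR
  differences (ms)
* ``rMSSD``   root mean square of successive RR differences (ms)
* ``pRR10``/``pRR50``  percentage of successive differences whose
  magnitude exceeds 10 ms / 50 ms
* ``Ratio``   (max RR − min RR) / MeanRR

— and three QRS-morphology features averaged over the window's beats:
QRS width (ms), QR amplitude and RS amplitude (mV).  A window is
labeled PVC when at least 95 % of its beats are ventricular-ectopic.
Features are min–max normalized to [0, 1] with parameters learned on
training windows only; test-time values outside the training range are
clipped.

Population (divide-by-n) standard deviations keep the identity
``rMSSD**2 == SDSD**2 + mean(diff)**2`` exact, which in turn guarantees
``rMSSD >= SDSD``; the nested thresholds guarantee ``pRR10 >= pRR50``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .beat_detection import record_fiducials
from .ecg_io import BeatAnnotation, ECGRecord

logger = logging.getLogger(__name__)

#: Canonical feature-column order of every feature table in the package.
FEATURE_ORDER = ("SDSD", "Ratio", "rMSSD", "SDRR", "pRR10", "pRR50",
                 "MeanRR", "qrs_width", "qr_amplitude", "rs_amplitude")

PVC_LABEL = "PVC"
NON_PVC_LABEL = "non-PVC"
PVC_WINDOW_THRESHOLD = 0.95
WINDOW_SECONDS = 20.0
MIN_BEATS_PER_WINDOW = 3


class StatisticalFeatures(NamedTuple):
    SDSD: float
    Ratio: float
    rMSSD: float
    SDRR: float
    pRR10: float
    pRR50: float
    MeanRR: float


class MorphologicalFeatures(NamedTuple):
    qrs_width: float
    qr_amplitude: float
    rs_amplitude: float


@dataclass
class Window:
    """One segment of a record: bounds in samples plus contained beats."""

    index: int
    start: int
    stop: int
    beats: list[BeatAnnotation]
    beat_positions: list[int] = field(default_factory=list)


def segment_windows(record: ECGRecord,
                    window_s: float = WINDOW_SECONDS,
                    min_beats: int = MIN_BEATS_PER_WINDOW) -> list[Window]:
    """Cut a record into non-overlapping windows anchored at its start.

    A beat belongs to the window containing its R index.  The trailing
    partial window is discarded, as are windows with fewer than
    `min_beats` beats (not enough RR intervals for the statistics).
    """
    if not record.annotations:
        raise ValueError("record has no beats")
    span = int(round(window_s * record.fs))
    n_windows = record.n_samples // span
    windows: list[Window] = []
    dropped = 0
    for k in range(n_windows):
        start, stop = k * span, (k + 1) * span
        members = [(i, a) for i, a in enumerate(record.annotations)
                   if start <= a.sample_index < stop]
        if len(members) < min_beats:
            dropped += 1
            continue
        windows.append(Window(k, start, stop,
                              [a for _, a in members],
                              [i for i, _ in members]))
    if dropped:
        logger.info("record %s: dropped %d window(s) with < %d beats",
                    record.record_id, dropped, min_beats)
    return windows


def rr_intervals_ms(beats: list[BeatAnnotation], fs: float) -> np.ndarray:
    """RR intervals (ms) between consecutive beats inside one window."""
    idx = np.asarray([b.sample_index for b in beats], dtype=np.float64)
    return np.diff(idx) * 1000.0 / fs


def statistical_features(intervals_ms: np.ndarray) -> StatisticalFeatures:
    """The seven time-domain statistics of one window's RR series."""
    rr = np.asarray(intervals_ms, dtype=np.float64)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    d = np.diff(rr)
    mean_rr = float(np.mean(rr))
    sdrr = float(np.std(rr))           # population SD
    sdsd = float(np.std(d))
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    prr10 = 100.0 * float(np.mean(np.abs(d) > 10.0))
    prr50 = 100.0 * float(np.mean(np.abs(d) > 50.0))
    ratio = float((np.max(rr) - np.min(rr)) / mean_rr)
    return StatisticalFeatures(sdsd, ratio, rmssd, sdrr, prr10, prr50,
                               mean_rr)


def morphological_features(fiducials, fs: float) -> MorphologicalFeatures:
    """Mean QRS width / QR amplitude / RS amplitude over a window's beats."""
    valid = [f for f in fiducials if f is not None]
    if not valid:
        raise ValueError("no valid fiducials in window")
    widths = [(f.s_index - f.q_index) * 1000.0 / fs for f in valid]
    qr = [f.r_amp - f.q_amp for f in valid]
    rs = [f.r_amp - f.s_amp for f in valid]
    return MorphologicalFeatures(float(np.mean(widths)), float(np.mean(qr)),
                                 float(np.mean(rs)))


def label_window(beats: list[BeatAnnotation],
                 threshold: float = PVC_WINDOW_THRESHOLD) -> str:
    """PVC iff at least 95 % of the window's beats are ventricular."""
    if not beats:
        raise ValueError("empty window")
    frac = sum(b.is_pvc for b in beats) / len(beats)
    return PVC_LABEL if frac >= threshold else NON_PVC_LABEL


def extract_features(record: ECGRecord,
                     window_s: float = WINDOW_SECONDS,
                     threshold: float = PVC_WINDOW_THRESHOLD,
                     use_annotations: bool = True) -> pd.DataFrame:
    """Per-window feature table for one record.

    Columns: ``record_id``, ``window_index``, the ten features in
    :data:`FEATURE_ORDER`, ``label``, ``n_beats``, ``pvc_beat_fraction``.
    """
    _, fiducials = record_fiducials(record,
                                    use_annotations=use_annotations)
    rows = []
    for w in segment_windows(record, window_s):
        rr = rr_intervals_ms(w.beats, record.fs)
        stats = statistical_features(rr)
        try:
            morph = morphological_features(
                [fiducials[i] for i in w.beat_positions], record.fs)
        except ValueError:
            continue
        frac = sum(b.is_pvc for b in w.beats) / len(w.beats)
        rows.append({
            "record_id": record.record_id,
            "window_index": w.index,
            **stats._asdict(),
            **morph._asdict(),
            "label": label_window(w.beats, threshold),
            "n_beats": len(w.beats),
            "pvc_beat_fraction": frac,
        })
    cols = (["record_id", "window_index"] + list(FEATURE_ORDER)
            + ["label", "n_beats", "pvc_beat_fraction"])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class NormalizationParams:
    """Per-feature min/max learned on training windows (frozen for test)."""

    feature_names: tuple[str, ...]
    fmin: np.ndarray
    fmax: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Mask of features whose training range collapsed to a point."""
        return self.fmax == self.fmin

    def to_dict(self) -> dict:
        return {"feature_names": list(self.feature_names),
                "fmin": self.fmin.tolist(), "fmax": self.fmax.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["feature_names"]),
                   np.asarray(d["fmin"], dtype=np.float64),
                   np.asarray(d["fmax"], dtype=np.float64))


def fit_normalization(train_features: pd.DataFrame) -> NormalizationParams:
    """Learn per-feature min and max over the training windows only."""
    if len(train_features) < 2:
        raise ValueError("need at least 2 training windows")
    values = train_features.loc[:, list(FEATURE_ORDER)].to_numpy(
        dtype=np.float64)
    params = NormalizationParams(FEATURE_ORDER, values.min(axis=0),
                                 values.max(axis=0))
    for name, deg in zip(FEATURE_ORDER, params.degenerate):
        if deg:
            logger.warning("feature %s is constant on the training set",
                           name)
    return params


def apply_normalization(features: pd.DataFrame,
                        params: NormalizationParams) -> np.ndarray:
    """Min–max scale features to [0, 1], clipping out-of-range values.

    Degenerate (constant-on-train) features map to 0.
    """
    values = features.loc[:, list(FEATURE_ORDER)].to_numpy(dtype=np.float64)
    span = params.fmax - params.fmin
    safe = np.where(params.degenerate, 1.0, span)
    scaled = (values - params.fmin) / safe
    scaled[:, params.degenerate] = 0.0
    return np.clip(scaled, 0.0, 1.0)
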