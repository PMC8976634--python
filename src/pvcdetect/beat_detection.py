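"""R-peak detection and Q/S fiducial location.

The R detector follows the classic Pan–Tompkins recipe: band-pass
filter (5–15 Hz), differentiate, square, moving-window integrate, then
pick peaks above an adaptive threshold with a 200 ms refractory period.
On annotated databases the annotated R positions are normally trusted
instead (aligned to the local signal maximum); the detector exists for
raw, unannotated signals and for validating the generator.

Q and S fiducials are the signal minima flanking R within an 80 ms
half-window, widened to 150 ms when the minimum sits on the window edge
(wide PVC complexes).  The QRS width, QR amplitude and RS amplitude
used as morphological features all derive from these fiducials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

REFRACTORY_S = 0.2
_QS_HALF_MS = 80.0
_QS_WIDE_MS = 150.0


@dataclass(frozen=True)
class BeatFiducials:
    r_index: int
    q_index: int
    s_index: int
    r_amp: float
    q_amp: float
    s_amp: float

    def __post_init__(self) -> None:
        if not self.q_index < self.r_index < self.s_index:
            raise ValueError("fiducials must satisfy q < r < s")


def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Detect R peaks in a single-lead signal (mV); returns sample indices.

    Strictly increasing, at least 200 ms apart.  A flat signal yields
    an empty array.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if len(x) < int(2 * fs):
        raise ValueError("signal must be at least 2 s long")
    if np.ptp(x) == 0:
        return np.asarray([], dtype=np.int64)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    squared = np.gradient(filtered) ** 2
    win = max(1, int(0.150 * fs))
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    distance = max(1, int(REFRACTORY_S * fs))
    peaks, props = sps.find_peaks(integrated, distance=distance,
                                  height=1e-12)
    if len(peaks) == 0:
        return np.asarray([], dtype=np.int64)
    # Adaptive threshold: candidate peaks are QRS complexes plus the
    # residue of P/T waves and noise.  Their integrated energies are
    # separated by orders of magnitude, so a two-means split of the log
    # energies recovers the QRS cluster; when the energies span less
    # than a factor of 4 the peaks form one beat cluster and all pass.
    log_h = np.log(props["peak_heights"])
    keep = np.ones(len(peaks), dtype=bool)
    for _ in range(4):  # peel off junk / P / T clusters one at a time
        lh = log_h[keep]
        if lh.max() - lh.min() <= np.log(4.0):
            break  # one homogeneous beat cluster left
        c0, c1 = lh.min(), lh.max()
        for _ in range(30):
            upper = lh > (c0 + c1) / 2
            if not upper.any() or upper.all():
                break
            c0, c1 = lh[~upper].mean(), lh[upper].mean()
        new_keep = keep & (log_h > (c0 + c1) / 2)
        if new_keep.sum() in (0, keep.sum()):
            break
        keep = new_keep
    peaks = peaks[keep]

    # refine each detection to the local maximum of the raw signal
    half = int(0.05 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    # re-enforce the refractory period after refinement
    keep = [refined[0]]
    for p in refined[1:]:
        if p - keep[-1] >= distance:
            keep.append(p)
        elif x[p] > x[keep[-1]]:
            keep[-1] = p
    return np.asarray(keep, dtype=np.int64)


def align_to_peak(signal: np.ndarray, index: int, fs: float,
                  tol_ms: float = 100.0) -> int:
    """Snap an annotated R index to the local signal maximum within
    ±`tol_ms`."""
    x = np.asarray(signal, dtype=np.float64).ravel()
    half = int(tol_ms / 1000.0 * fs)
    lo, hi = max(0, index - half), min(len(x), index + half + 1)
    return lo + int(np.argmax(x[lo:hi]))


def _argmin_window(x: np.ndarray, lo: int, hi: int) -> int:
    return lo + int(np.argmin(x[lo:hi]))


def _nearest_local_min(x: np.ndarray, lo: int, hi: int, r: int) -> int:
    """Interior local minimum closest to R in ``x[lo:hi]``.

    Used for the widened (wide-QRS) search: the raw argmin there can sit
    on the window edge when a neighbouring beat's T wave leaks in, while
    the Q/S trough is the turning point nearest the R peak.  The segment
    is lightly smoothed so sample noise does not fabricate minima; falls
    back to the plain argmin when no interior minimum exists.
    """
    seg = x[lo:hi]
    if len(seg) >= 5:
        seg = np.convolve(seg, np.ones(3) / 3.0, mode="same")
    interior = np.nonzero((seg[1:-1] <= seg[:-2])
                          & (seg[1:-1] <= seg[2:]))[0] + 1
    if len(interior) == 0:
        return _argmin_window(x, lo, hi)
    cand = lo + interior
    return int(cand[np.argmin(np.abs(cand - r))])


def locate_qs(signal: np.ndarray, fs: float, r_index: int,
              prev_r: int | None = None,
              next_r: int | None = None) -> BeatFiducials:
    """Locate the Q and S troughs around a known R peak.

    The search half-window is 80 ms, widened to 150 ms when the minimum
    falls on the window edge (wide PVC QRS).  Search windows never
    cross the adjacent R peaks.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    half = int(_QS_HALF_MS / 1000.0 * fs)
    wide = int(_QS_WIDE_MS / 1000.0 * fs)
    if r_index - half < 0 or r_index + half >= len(x):
        raise ValueError("r_index too close to the record boundary")

    q_floor = 0 if prev_r is None else (prev_r + r_index) // 2 + 1
    s_ceil = len(x) if next_r is None else (next_r + r_index) // 2

    lo = max(q_floor, r_index - half)
    q_idx = _argmin_window(x, lo, r_index)
    if q_idx == lo and lo > q_floor:  # trough on edge: widen for wide QRS
        lo = max(q_floor, r_index - wide)
        q_idx = _nearest_local_min(x, lo, r_index, r_index)

    hi = min(s_ceil, r_index + half + 1)
    s_idx = _argmin_window(x, r_index + 1, hi)
    if s_idx == hi - 1 and hi < s_ceil:
        hi = min(s_ceil, r_index + wide + 1)
        s_idx = _nearest_local_min(x, r_index + 1, hi, r_index)

    return BeatFiducials(int(r_index), int(q_idx), int(s_idx),
                         float(x[r_index]), float(x[q_idx]), float(x[s_idx]))


def record_fiducials(record, use_annotations: bool = True,
                     align: bool = True
                     ) -> tuple[np.ndarray, list[BeatFiducials | None]]:
    """R indices and per-beat fiducials for a whole record.

    With ``use_annotations`` the annotated R indices are used verbatim
    (optionally aligned to the local maximum); otherwise the Pan–Tompkins
    detector runs.  Returns the R-index array and a parallel fiducial
    list; beats too close to the record boundary get ``None``.
    """
    x = record.signal[0]
    if use_annotations and record.annotations:
        r_idx = record.r_indices()
        if align:
            r_idx = np.asarray([align_to_peak(x, int(r), record.fs)
                                for r in r_idx], dtype=np.int64)
    else:
        r_idx = detect_r_peaks(x, record.fs)
    out: list[BeatFiducials | None] = []
    for i, r in enumerate(r_idx):
        prev_r = int(r_idx[i - 1]) if i > 0 else None
        next_r = int(r_idx[i + 1]) if i + 1 < len(r_idx) else None
        try:
            out.append(locate_qs(x, record.fs, int(r), prev_r, next_r))
        except ValueError:
            out.append(None)
    return r_idx, out
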