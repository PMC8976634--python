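"""Seeded generator of annotated synthetic single-lead ECG records.

Each heartbeat is rendered as a sum of Gaussian wavelets.  A normal
beat carries P, Q, R, S and T waves with a narrow (~80 ms) QRS; a
premature ventricular contraction (PVC) has no P wave, a wide (~160 ms,
i.e. > 120 ms) low-slung QRS and an enlarged inverted T wave.  A PVC
shortens the RR interval that precedes it (prematurity) and lengthens
the one that follows (compensatory pause).  The generator emits an
:class:`~pvcdetect.ecg_io.ECGRecord` with ground-truth R-wave indices
and 'N'/'V' annotation symbols, so every downstream stage can be tested
without the MIT-BIH download.

All randomness flows from a single seeded :class:`numpy.random.Generator`;
identical configs give bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ecg_io import BeatAnnotation, ECGRecord

# Wavelet tables: (offset ms from R, amplitude mV, sigma ms).
NORMAL_WAVES = (
    (-200.0, 0.15, 25.0),   # P
    (-40.0, -0.10, 8.0),    # Q
    (0.0, 1.00, 12.0),      # R
    (40.0, -0.20, 8.0),     # S
    (250.0, 0.30, 40.0),    # T
)
# PVC: no P, Q/R/S rescaled ~20% and doubled in width, large inverted T.
PVC_WAVES = (
    (-80.0, -0.12, 16.0),   # Q
    (0.0, 0.80, 24.0),      # R
    (80.0, -0.24, 16.0),    # S
    (300.0, -0.45, 60.0),   # T
)

_LEAD_PAD_S = 0.5   # silence before the first and after the last beat


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic record generator.

    ``pvc_prematurity`` multiplies the RR interval preceding a PVC
    (< 1), ``compensatory_factor`` the interval following it (> 1).
    QRS widths are the Q-to-S fiducial distances of the rendered
    templates; the PVC width must exceed the 120 ms clinical threshold
    while the normal width stays below it.
    """

    n_beats: int = 200
    pvc_fraction: float = 0.0
    fs: float = 360.0
    mean_rr: float = 800.0
    rr_jitter_sd: float = 20.0
    normal_qrs_width: float = 80.0
    pvc_qrs_width: float = 160.0
    pvc_prematurity: float = 0.7
    compensatory_factor: float = 1.3
    noise_sd: float = 0.0
    forbid_consecutive_pvcs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not 0.0 <= self.pvc_fraction <= 1.0:
            raise ValueError("pvc_fraction must lie in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be non-negative")
        if not self.normal_qrs_width < 120.0 <= self.pvc_qrs_width:
            raise ValueError(
                "QRS widths must satisfy normal_qrs_width < 120 ms "
                "<= pvc_qrs_width")
        if not self.pvc_prematurity < 1.0:
            raise ValueError("pvc_prematurity must be < 1")
        if not self.compensatory_factor > 1.0:
            raise ValueError("compensatory_factor must be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _scaled_waves(base, width_scale: float):
    return [(off * width_scale, amp, sig * width_scale)
            for off, amp, sig in base]


def generate_record(config: SynthConfig,
                    record_id: str | None = None) -> ECGRecord:
    """Generate one annotated synthetic record.

    PVC placement is i.i.d. Bernoulli(``pvc_fraction``) per beat (with
    an optional no-two-consecutive constraint); RR intervals are
    ``mean_rr`` plus Gaussian jitter, modulated by prematurity and
    compensatory pauses around PVCs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_beats

    is_pvc = rng.random(n) < config.pvc_fraction
    if config.forbid_consecutive_pvcs:
        for i in range(1, n):
            if is_pvc[i] and is_pvc[i - 1]:
                is_pvc[i] = False

    # rr[i] is the interval preceding beat i (rr[0] unused).
    rr = config.mean_rr + rng.normal(0.0, config.rr_jitter_sd, size=n)
    rr = np.maximum(rr, 0.3 * config.mean_rr)
    for i in range(1, n):
        if is_pvc[i]:
            rr[i] *= config.pvc_prematurity
        elif is_pvc[i - 1]:
            rr[i] *= config.compensatory_factor

    r_times_ms = 1000.0 * _LEAD_PAD_S + np.concatenate(
        ([0.0], np.cumsum(rr[1:])))
    r_indices = np.rint(r_times_ms * config.fs / 1000.0).astype(np.int64)

    n_samples = int(r_indices[-1] + _LEAD_PAD_S * config.fs) + 1
    signal = np.zeros(n_samples)
    t_ms = np.arange(n_samples) * (1000.0 / config.fs)

    normal_waves = _scaled_waves(NORMAL_WAVES,
                                 config.normal_qrs_width / 80.0)
    pvc_waves = _scaled_waves(PVC_WAVES, config.pvc_qrs_width / 160.0)

    for r_idx, pvc in zip(r_indices, is_pvc):
        waves = pvc_waves if pvc else normal_waves
        center_ms = r_idx * (1000.0 / config.fs)
        # render only a local neighbourhood of the beat
        lo = max(0, int(r_idx - 0.5 * config.fs))
        hi = min(n_samples, int(r_idx + 0.6 * config.fs))
        seg = t_ms[lo:hi] - center_ms
        for off, amp, sig in waves:
            signal[lo:hi] += amp * np.exp(-0.5 * ((seg - off) / sig) ** 2)

    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n_samples)

    annotations = [
        BeatAnnotation.from_symbol(idx, "V" if pvc else "N")
        for idx, pvc in zip(r_indices, is_pvc)
    ]
    return ECGRecord(
        record_id=record_id or f"synth{config.seed}",
        fs=config.fs,
        leads=["MLII"],
        signal=signal[np.newaxis, :],
        annotations=annotations,
    )
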