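"""Minimal reader/writer for PhysioNet WFDB record triplets.

Supports the pieces of the format family that arrhythmia-database work
actually touches: ASCII ``.hea`` headers, signal files in format 212
(two 12-bit samples packed into three bytes, as used by the MIT-BIH
Arrhythmia Database) and format 16 (little-endian int16), and MIT-format
``.atr`` annotation files.  Samples are converted to physical units
(mV) with each signal's gain and baseline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

# MIT annotation code numbers <-> display symbols (the subset with
# defined single-character mnemonics).
CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE: dict[str, int] = {s: c for c, s in CODE_TO_SYMBOL.items()}

# Pseudo-annotation codes that carry side information rather than events.
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class SignalSpec:
    file_name: str
    fmt: int
    gain: float = 200.0
    baseline: int = 0
    units: str = "mV"
    adc_res: int = 12
    adc_zero: int = 0
    description: str = ""


@dataclass
class Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalSpec] = field(default_factory=list)


def read_header(path: str) -> Header:
    """Parse a ``.hea`` file. `path` may omit the extension."""
    if not path.endswith(".hea"):
        path = path + ".hea"
    with open(path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    rec = lines[0].split()
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    header = Header(name, n_sig, fs, n_samples)
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_res = int(parts[3]) if len(parts) > 3 else 12
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(parts[8:]) if len(parts) > 8 else ""
        header.signals.append(
            SignalSpec(parts[0], fmt, gain, baseline, units, adc_res,
                       adc_zero, desc))
    return header


def _read_fmt212(raw: bytes, n_sig: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: 3 * (len(b) // 3)].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    first[first > 2047] -= 4096
    second[second > 2047] -= 4096
    interleaved = np.empty(2 * len(b), dtype=np.int32)
    interleaved[0::2] = first
    interleaved[1::2] = second
    n = len(interleaved) // n_sig
    return interleaved[: n * n_sig].reshape(n, n_sig).T


def read_signal(record_path: str, header: Header) -> np.ndarray:
    """Return the physical signal, shape ``(n_sig, n_samples)``, in mV."""
    directory = os.path.dirname(record_path)
    dat_path = os.path.join(directory, header.signals[0].file_name)
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    fmt = header.signals[0].fmt
    if fmt == 212:
        adc = _read_fmt212(raw, header.n_sig)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        n = len(flat) // header.n_sig
        adc = flat[: n * header.n_sig].reshape(n, header.n_sig).T
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    if header.n_samples:
        adc = adc[:, : header.n_samples]
    physical = np.empty(adc.shape, dtype=np.float64)
    for i, spec in enumerate(header.signals):
        physical[i] = (adc[i] - spec.baseline) / spec.gain
    return physical


def read_annotations(path: str) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into ``(sample, symbol)`` pairs."""
    with open(path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw, dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code, data = word >> 10, word & 0x3FF
        i += 1
        if code == 0 and data == 0:  # EOF
            break
        if code == _SKIP:
            # 4-byte interval, high 16 bits first (PDP-11 long order)
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += (data + 1) // 2  # aux string, padded to even length
        else:
            t += data
            out.append((t, CODE_TO_SYMBOL.get(code, "Q")))
    return out


def write_annotations(path: str, annotations: list[tuple[int, str]]) -> None:
    words: list[int] = []
    prev = 0
    for sample, symbol in annotations:
        code = SYMBOL_TO_CODE.get(symbol, SYMBOL_TO_CODE["Q"])
        interval = sample - prev
        if interval < 0:
            raise ValueError("annotations must be sorted by sample index")
        if interval > 0x3FF:
            words.append(_SKIP << 10)
            words.append((interval >> 16) & 0xFFFF)
            words.append(interval & 0xFFFF)
            interval = 0
        words.append((code << 10) | interval)
        prev = sample
    words.append(0)  # EOF
    np.asarray(words, dtype="<u2").tofile(path)


def write_record(directory: str, record_name: str, signal: np.ndarray,
                 fs: float, lead_names: list[str],
                 annotations: list[tuple[int, str]] | None = None,
                 gain: float = 200.0) -> str:
    """Write a format-16 ``.hea``/``.dat`` pair (and ``.atr`` if given).

    `signal` is physical (mV), shape ``(n_sig, n_samples)``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_sig, n_samples = signal.shape
    os.makedirs(directory, exist_ok=True)
    adc = np.rint(signal * gain).astype(np.int32)
    adc = np.clip(adc, -32768, 32767).astype("<i2")
    dat_name = f"{record_name}.dat"
    adc.T.reshape(-1).tofile(os.path.join(directory, dat_name))
    lines = [f"{record_name} {n_sig} {fs:g} {n_samples}"]
    for lead in lead_names:
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {lead}")
    with open(os.path.join(directory, f"{record_name}.hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if annotations is not None:
        write_annotations(os.path.join(directory, f"{record_name}.atr"),
                          annotations)
    return os.path.join(directory, record_name)
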