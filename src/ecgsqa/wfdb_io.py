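"""Minimal WFDB record I/O for ambulatory ECG databases.

Reads the subset of the WFDB format needed to ingest MIT-BIH-style records:
a plain-text ``.hea`` header naming the signals and a ``.dat`` file in
format 212 (packed 12-bit pairs, the MIT-BIH encoding) or format 16
(little-endian int16).  Channels are selected by lead name (e.g. "MLII" /
"II"); samples are converted to millivolts with the header's gain and
baseline.  A matching writer exists so round-trip fixtures can be built in
tests without shipping binary data.

Annotation files and multi-segment records are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SignalInfo", "WfdbRecord", "read_record", "write_record", "select_lead"]


@dataclass(frozen=True)
class SignalInfo:
    """Per-signal header fields (subset)."""

    filename: str
    fmt: int
    gain: float  # ADC units per mV
    baseline: int
    description: str


@dataclass(frozen=True)
class WfdbRecord:
    name: str
    fs: float
    n_samples: int
    signals: tuple[SignalInfo, ...]
    data_mv: np.ndarray  # (n_samples, n_signals), millivolts


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[SignalInfo]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    infos: list[SignalInfo] = []
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        filename, fmt_field = parts[0], parts[1]
        fmt = int(fmt_field.split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(parts) > 2:
            g = parts[2]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")").split(")")[0])
            g = g.split("/")[0]
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        description = " ".join(parts[8:]) if len(parts) > 8 else f"sig{len(infos)}"
        infos.append(SignalInfo(filename=filename, fmt=fmt, gain=gain,
                                baseline=baseline, description=description))
    return name, n_sig, fs, n_samp, infos


def _read_dat_212(raw: bytes, n_samples: int, n_sig: int) -> np.ndarray:
    """Unpack format 212: two 12-bit samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_total = n_samples * n_sig
    n_pairs = (n_total + 1) // 2
    b = b[: n_pairs * 3].reshape(-1, 3)
    first = ((b[:, 1].astype(np.int32) & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1].astype(np.int32) & 0xF0) << 4) | b[:, 2]
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(n_pairs * 2, dtype=np.int32)
    flat[0::2] = first
    flat[1::2] = second
    return flat[:n_total].reshape(n_samples, n_sig)


def _write_dat_212(adc: np.ndarray) -> bytes:
    flat = adc.reshape(-1).astype(np.int32)
    if flat.size % 2:
        flat = np.concatenate([flat, np.zeros(1, dtype=np.int32)])
    a = flat[0::2] & 0xFFF
    b = flat[1::2] & 0xFFF
    out = np.empty((a.size, 3), dtype=np.uint8)
    out[:, 0] = a & 0xFF
    out[:, 1] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[:, 2] = b & 0xFF
    return out.tobytes()


def read_record(path: str | Path) -> WfdbRecord:
    """Read a WFDB record given its path without extension."""
    path = Path(path)
    name, n_sig, fs, n_samp, infos = _parse_header(path.with_suffix(".hea"))
    fmts = {i.fmt for i in infos}
    files = {i.filename for i in infos}
    if len(fmts) > 1 or len(files) > 1:
        raise ValueError("multi-file or mixed-format records are unsupported")
    fmt = fmts.pop()
    raw = (path.parent / files.pop()).read_bytes()
    if fmt == 212:
        adc = _read_dat_212(raw, n_samp, n_sig)
    elif fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")[: n_samp * n_sig].reshape(n_samp, n_sig)
    else:
        raise ValueError(f"unsupported WFDB format {fmt}")
    data = np.empty((n_samp, n_sig), dtype=float)
    for k, info in enumerate(infos):
        data[:, k] = (adc[:, k] - info.baseline) / info.gain
    return WfdbRecord(name=name, fs=fs, n_samples=n_samp, signals=tuple(infos),
                      data_mv=data)


def write_record(directory: str | Path, name: str, data_mv: np.ndarray, fs: float,
                 lead_names: list[str], fmt: int = 212, gain: float = 200.0) -> Path:
    """Write a WFDB record (header + dat); returns the header path."""
    directory = Path(directory)
    data_mv = np.atleast_2d(np.asarray(data_mv, dtype=float))
    if data_mv.shape[0] < data_mv.shape[1]:
        data_mv = data_mv.T
    n_samp, n_sig = data_mv.shape
    if len(lead_names) != n_sig:
        raise ValueError("one lead name per signal required")
    adc = np.round(data_mv * gain).astype(np.int32)
    limit = 2047 if fmt == 212 else 32767
    adc = np.clip(adc, -limit - 1, limit)
    dat_name = f"{name}.dat"
    if fmt == 212:
        payload = _write_dat_212(adc)
    elif fmt == 16:
        payload = adc.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported WFDB format {fmt}")
    (directory / dat_name).write_bytes(payload)
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for lead in lead_names:
        lines.append(f"{dat_name} {fmt} {gain:g}(0) 12 0 0 0 0 {lead}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def select_lead(record: WfdbRecord, lead: str = "II") -> np.ndarray:
    """Extract one channel by lead name; "II" also matches "MLII"."""
    wanted = lead.upper()
    for k, info in enumerate(record.signals):
        desc = info.description.upper()
        if desc == wanted or (wanted == "II" and desc in ("MLII", "LEAD II")):
            return record.data_mv[:, k].copy()
    raise KeyError(f"lead {lead!r} not found in record {record.name} "
                   f"(has {[s.description for s in record.signals]})")
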