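"""Preprocessing of raw ECG into 4-second, 128 Hz, 512-sample segments.

Raw recordings pass through a second-order Butterworth band-pass (0.5-40 Hz,
removing baseline drift below 0.5 Hz and high-frequency noise above 40 Hz),
are resampled to the 128 Hz working rate if needed, and are cut into
non-overlapping 4-second windows.  Ambulatory databases sampled at 360 Hz
(e.g. MIT-BIH Arrhythmia records) are handled by polyphase rational
resampling; filtering is applied after resampling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .synthetic import FS_HZ, SEGMENT_SAMPLES

__all__ = [
    "PhaseMode",
    "FilterSpec",
    "bandpass_filter",
    "resample_to_128",
    "segment_record",
    "preprocess_record",
    "read_text_record",
    "write_text_record",
]


class PhaseMode(enum.Enum):
    """Filtering mode: forward-backward (offline) or causal (streaming)."""

    ZERO_PHASE = "zero_phase"
    CAUSAL = "causal"


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass realized as cascaded second-order high- and low-pass
    Butterworth sections."""

    order: int = 2
    highpass_cutoff_hz: float = 0.5
    lowpass_cutoff_hz: float = 40.0
    phase_mode: PhaseMode = PhaseMode.ZERO_PHASE

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz:
            raise ValueError("cutoffs must satisfy 0 < highpass < lowpass")


def bandpass_filter(
    samples: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Remove baseline drift and high-frequency noise from a voltage series.

    Applies a second-order Butterworth high-pass at 0.5 Hz followed by a
    second-order low-pass at 40 Hz.  Zero-phase mode filters forward and
    backward (no phase distortion, squared magnitude response); causal mode
    filters once, as a streaming device would.
    """
    samples = np.asarray(samples, dtype=float)
    if spec.lowpass_cutoff_hz >= fs / 2:
        raise ValueError("lowpass cutoff must be below the Nyquist frequency")
    if samples.size < 3 * spec.order:
        raise ValueError("input too short for the requested filter order")

    sos_hp = signal.butter(spec.order, spec.highpass_cutoff_hz, "highpass", fs=fs, output="sos")
    sos_lp = signal.butter(spec.order, spec.lowpass_cutoff_hz, "lowpass", fs=fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    if spec.phase_mode is PhaseMode.ZERO_PHASE:
        return signal.sosfiltfilt(sos, samples)
    return signal.sosfilt(sos, samples)


def resample_to_128(samples: np.ndarray, fs_in: float) -> np.ndarray:
    """Downsample a voltage series to the 128 Hz working rate.

    Uses polyphase rational resampling (e.g. 360 -> 128 Hz is 16/45); content
    below the output Nyquist of 64 Hz is preserved.  Upsampling is not
    supported: segments below 128 Hz carry no 0-64 Hz band to recover.
    """
    samples = np.asarray(samples, dtype=float)
    if fs_in < FS_HZ:
        raise ValueError(f"fs_in must be >= {FS_HZ} Hz; upsampling is unsupported")
    if fs_in == FS_HZ:
        return samples.copy()
    frac = Fraction(FS_HZ / fs_in).limit_denominator(1000)
    return signal.resample_poly(samples, frac.numerator, frac.denominator)


def segment_record(samples: np.ndarray, fs: float = FS_HZ) -> list[np.ndarray]:
    """Cut a 128 Hz record into consecutive non-overlapping 512-sample
    segments, dropping any trailing remainder."""
    if fs != FS_HZ:
        raise ValueError(f"segment_record expects fs = {FS_HZ} Hz")
    samples = np.asarray(samples, dtype=float)
    n_seg = samples.size // SEGMENT_SAMPLES
    return [
        samples[i * SEGMENT_SAMPLES : (i + 1) * SEGMENT_SAMPLES].copy()
        for i in range(n_seg)
    ]


def preprocess_record(
    samples: np.ndarray, fs_in: float, spec: FilterSpec = FilterSpec()
) -> list[np.ndarray]:
    """Full raw-record pipeline: resample to 128 Hz, band-pass, window."""
    x = resample_to_128(samples, fs_in)
    x = bandpass_filter(x, FS_HZ, spec)
    return segment_record(x, FS_HZ)


def read_text_record(path) -> tuple[np.ndarray, float]:
    """Read a plain-text record: '# fs=<Hz>' header, one sample (mV) per
    line.  Returns (samples, fs); fs defaults to 128 Hz without a header."""
    fs = float(FS_HZ)
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs" in line and "=" in line:
                    fs = float(line.split("=", 1)[1].strip())
                continue
            values.append(float(line))
    return np.array(values), fs


def write_text_record(path, samples: np.ndarray, fs: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        for v in np.asarray(samples).ravel():
            fh.write(f"{v:.6g}\n")
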