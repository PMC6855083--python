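"""Time-frequency representation of a 512-sample segment.

The first-stage classifier consumes a short-time Fourier spectrogram of the
4-second segment: 16-sample symmetric Hamming frames hopped by 8 samples
(50% overlap) and zero-padded to a 512-point FFT, giving 257 frequency rows
(0-64 Hz at 0.25 Hz spacing) by 63 time columns.  Values are log10
magnitudes with a small floor so silent segments stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import FS_HZ, SEGMENT_SAMPLES

__all__ = ["Spectrogram", "stft_spectrum", "standardize_spectrogram",
           "N_FREQ_BINS", "N_FRAMES", "FREQ_RESOLUTION_HZ"]

#: STFT geometry: frame length, hop, FFT length.
_FRAME_LEN = 16
_HOP = 8
_NFFT = 512

N_FREQ_BINS = _NFFT // 2 + 1  # 257
N_FRAMES = (SEGMENT_SAMPLES - _FRAME_LEN) // _HOP + 1  # 63
FREQ_RESOLUTION_HZ = FS_HZ / _NFFT  # 0.25

#: Magnitude floor before the log, keeping zero spectra finite.
EPS = 1e-10


@dataclass(frozen=True)
class Spectrogram:
    """257 x 63 log-magnitude time-frequency matrix of one segment."""

    values: np.ndarray
    freq_resolution_hz: float = FREQ_RESOLUTION_HZ
    frame_hop_s: float = _HOP / FS_HZ

    def __post_init__(self) -> None:
        if self.values.shape != (N_FREQ_BINS, N_FRAMES):
            raise ValueError(
                f"spectrogram must be {N_FREQ_BINS}x{N_FRAMES}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")


def stft_spectrum(samples: np.ndarray) -> Spectrogram:
    """Compute the 257 x 63 log-magnitude spectrogram of a 512-sample segment.

    Frequency row k corresponds to k * 0.25 Hz; a pure sinusoid at f Hz
    concentrates in row round(f / 0.25).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape != (SEGMENT_SAMPLES,):
        raise ValueError(f"expected exactly {SEGMENT_SAMPLES} samples, got {samples.shape}")
    win = signal.windows.hamming(_FRAME_LEN, sym=True)
    _, _, Z = signal.stft(
        samples,
        fs=FS_HZ,
        window=win,
        nperseg=_FRAME_LEN,
        noverlap=_FRAME_LEN - _HOP,
        nfft=_NFFT,
        boundary=None,
        padded=False,
    )
    return Spectrogram(values=np.log10(np.abs(Z) + EPS))


def standardize_spectrogram(spec: Spectrogram) -> Spectrogram:
    """Z-score all entries jointly (zero mean, unit variance).

    Constant matrices map to zeros: the variance is floored to avoid a
    divide-by-zero on degenerate inputs.
    """
    v = spec.values
    mu = v.mean()
    sd = v.std()
    if sd < 1e-12:
        return Spectrogram(values=np.zeros_like(v))
    return Spectrogram(values=(v - mu) / sd)
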