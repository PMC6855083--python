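"""Synthetic dynamic-ECG segments with controlled interference.

Generates labelled 4-second, 128 Hz single-lead segments: a clean PQRST
trace built from a sum of five Gaussians repeated at jittered RR intervals,
optionally contaminated by motion artifacts (irregular low-frequency waves,
< 7 Hz) and/or myoelectric noise (broadband muscle activity, realized as
30-63 Hz band-limited noise — the upper reach of the physiological 30-300 Hz
band is folded away by the 128 Hz sampling rate).  Every segment carries its
ground-truth noise events, so the rule-based labeller and both classifier
stages can be validated without access to real Holter recordings.

All randomness flows from explicit integer seeds; a dataset is bit-identical
when regenerated from the same master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .rules import (
    SEGMENT_DURATION_S,
    NoiseEvent,
    NoiseKind,
    QualityClass,
    label_segment,
)

__all__ = [
    "FS_HZ",
    "SEGMENT_SAMPLES",
    "WaveParams",
    "CleanEcgParams",
    "SyntheticSegment",
    "DatasetSpec",
    "generate_clean_segment",
    "generate_motion_artifact",
    "generate_myoelectric_noise",
    "compose_segment",
    "generate_dataset",
]

#: Segment sampling rate in Hz.
FS_HZ = 128

#: Samples per 4-second segment.
SEGMENT_SAMPLES = 512

# Filter-warmup samples discarded from the head of causal noise realizations.
_WARMUP = 256


@dataclass(frozen=True)
class WaveParams:
    """One PQRST deflection as a Gaussian bump.

    amplitude is a fraction of the R height (signed), width_s the Gaussian
    standard deviation, offset_s the centre relative to the R peak.
    """

    amplitude: float
    width_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("wave width_s must be positive")


# Typical lead-II morphology: small upright P, narrow QRS with shallow Q/S,
# broad upright T.  Amplitudes are fractions of the R height.
DEFAULT_WAVES: Mapping[str, WaveParams] = {
    "P": WaveParams(0.15, 0.025, -0.20),
    "Q": WaveParams(-0.10, 0.010, -0.035),
    "R": WaveParams(1.00, 0.012, 0.0),
    "S": WaveParams(-0.15, 0.010, 0.035),
    "T": WaveParams(0.30, 0.070, 0.30),
}


@dataclass(frozen=True)
class CleanEcgParams:
    """Parameters of the clean-beat generator.

    heart_rate_bpm must lie in the physiological 40-180 range;
    r_amplitude_mv is the baseline-to-R-peak height (clinical single-lead
    ECG amplitudes span roughly 0.05-5 mV); rr_jitter_frac is the
    fractional standard deviation of the beat-to-beat interval.
    """

    heart_rate_bpm: float = 60.0
    r_amplitude_mv: float = 1.0
    waves: Mapping[str, WaveParams] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    rr_jitter_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate_bpm <= 180.0:
            raise ValueError("heart_rate_bpm must lie in [40, 180]")
        if self.r_amplitude_mv < 0:
            raise ValueError("r_amplitude_mv must be non-negative")
        if self.rr_jitter_frac < 0:
            raise ValueError("rr_jitter_frac must be non-negative")


@dataclass(frozen=True)
class SyntheticSegment:
    """A 4-second, 128 Hz segment with ground truth.

    samples: 512 voltages in mV; r_height_mv: clean baseline-to-R height;
    events: injected noise events; true_class: label implied by the events.
    """

    samples: np.ndarray
    r_height_mv: float
    events: tuple[NoiseEvent, ...]
    true_class: QualityClass

    def __post_init__(self) -> None:
        if self.samples.shape != (SEGMENT_SAMPLES,):
            raise ValueError(f"samples must have shape ({SEGMENT_SAMPLES},)")


def generate_clean_segment(params: CleanEcgParams, seed: int) -> SyntheticSegment:
    """Generate one noise-free PQRST segment.

    R peaks are laid down at jittered RR intervals covering the window with
    margin, and each beat adds its five Gaussian deflections.  The returned
    ``r_height_mv`` is the measured baseline-to-maximum of the trace (the R
    peak, for any physiological morphology) and anchors the severity rules
    downstream.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(SEGMENT_SAMPLES) / FS_HZ

    rr = 60.0 / params.heart_rate_bpm
    # R-peak times extend one beat beyond each edge so edge beats are partial,
    # not missing.
    r_times = []
    pos = -rr * rng.random()
    while pos < SEGMENT_DURATION_S + rr:
        r_times.append(pos)
        step = rr * (1.0 + params.rr_jitter_frac * rng.standard_normal())
        pos += max(step, 0.3 * rr)

    samples = np.zeros(SEGMENT_SAMPLES)
    for r_t in r_times:
        for wave in params.waves.values():
            centre = r_t + wave.offset_s
            samples += wave.amplitude * np.exp(-0.5 * ((t - centre) / wave.width_s) ** 2)
    samples *= params.r_amplitude_mv

    r_height = float(samples.max()) if samples.size else 0.0
    return SyntheticSegment(
        samples=samples,
        r_height_mv=max(r_height, 0.0),
        events=(),
        true_class=QualityClass.LOW,
    )


def _normalize_peak(x: np.ndarray, peak_amp_mv: float) -> np.ndarray:
    """Scale x so max |x| equals peak_amp_mv exactly (zeros if peak is 0)."""
    if peak_amp_mv == 0.0:
        return np.zeros_like(x)
    m = np.max(np.abs(x))
    if m == 0.0:
        raise RuntimeError("degenerate all-zero noise realization")
    return x * (peak_amp_mv / m)


def generate_motion_artifact(duration_s: float, peak_amp_mv: float, seed: int) -> np.ndarray:
    """Simulate an electrode-motion artifact burst.

    A random walk is low-passed at 5 Hz and shaped by a slowly varying
    (0.5 Hz) random envelope, giving the irregular abrupt waves seen when
    electrode-skin contact shifts; essentially all periodogram power lies
    below 7 Hz.  The series is scaled so its maximum absolute value equals
    ``peak_amp_mv``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if peak_amp_mv < 0:
        raise ValueError("peak_amp_mv must be non-negative")
    n = int(round(duration_s * FS_HZ))
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal(n + _WARMUP))
    sos = signal.butter(4, 5.0, "low", fs=FS_HZ, output="sos")
    base = signal.sosfilt(sos, walk - walk.mean())
    env_sos = signal.butter(2, 0.5, "low", fs=FS_HZ, output="sos")
    envelope = np.abs(signal.sosfilt(env_sos, rng.standard_normal(n + _WARMUP)))
    x = (base * (0.2 + envelope))[_WARMUP:]
    x = x - x.mean()
    return _normalize_peak(x, peak_amp_mv)


def generate_myoelectric_noise(duration_s: float, peak_amp_mv: float, seed: int) -> np.ndarray:
    """Simulate myoelectric (EMG) noise.

    White Gaussian noise band-passed to 30-63 Hz: the sampled-signal
    realization of broadband muscle activity, whose spectral content above
    the 64 Hz Nyquist limit cannot survive 128 Hz digitization.  Scaled so
    max |x| equals ``peak_amp_mv``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if peak_amp_mv < 0:
        raise ValueError("peak_amp_mv must be non-negative")
    n = int(round(duration_s * FS_HZ))
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [30.0, 63.0], "bandpass", fs=FS_HZ, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + _WARMUP))[_WARMUP:]
    return _normalize_peak(x, peak_amp_mv)


_NOISE_GENERATORS = {
    NoiseKind.MOTION: generate_motion_artifact,
    NoiseKind.MYOELECTRIC: generate_myoelectric_noise,
}


def compose_segment(
    clean: SyntheticSegment,
    events: Sequence[NoiseEvent],
    seed: int,
) -> SyntheticSegment:
    """Add noise events to a clean segment and label the result.

    Each event contributes an independent noise realization scaled so its
    peak equals ``peak_ratio * r_height_mv``, inserted only inside
    ``[start_s, end_s)``.  Events must not overlap in time (within one
    4-second window, coexisting interference types are not modelled).
    """
    events = tuple(events)
    ordered = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise ValueError("noise events must be pairwise non-overlapping")
    if events and clean.r_height_mv <= 0:
        raise ValueError("cannot scale noise against a zero R height")

    samples = clean.samples.copy()
    for k, ev in enumerate(events):
        i0 = int(round(ev.start_s * FS_HZ))
        i1 = int(round(ev.end_s * FS_HZ))
        gen = _NOISE_GENERATORS[ev.kind]
        noise = gen((i1 - i0) / FS_HZ, ev.peak_ratio * clean.r_height_mv, seed + 7919 * (k + 1))
        samples[i0:i1] += noise

    true_class = (
        label_segment(events, clean.r_height_mv) if events else QualityClass.LOW
    )
    return SyntheticSegment(
        samples=samples,
        r_height_mv=clean.r_height_mv,
        events=events,
        true_class=true_class,
    )


@dataclass(frozen=True)
class DatasetSpec:
    """Composition and parameter ranges of a synthetic dataset.

    Per-class counts plus uniform sampling ranges for heart rate, R height,
    noise peak ratios (mild strictly inside (0, 0.5), severe at or above
    0.5), and event duration (above the 2 s dominance threshold so every
    noisy segment is labelled by its injected type).
    """

    counts: Mapping[QualityClass, int]
    heart_rate_range: tuple[float, float] = (50.0, 100.0)
    r_amplitude_range: tuple[float, float] = (0.6, 2.0)
    mild_ratio_range: tuple[float, float] = (0.2, 0.4)
    severe_ratio_range: tuple[float, float] = (0.6, 0.9)
    event_duration_range: tuple[float, float] = (2.2, 3.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for c, n in self.counts.items():
            if n < 0:
                raise ValueError(f"count for {c} must be non-negative")
        lo, hi = self.mild_ratio_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("mild_ratio_range must lie strictly inside (0, 0.5)")
        lo, hi = self.severe_ratio_range
        if not (0.5 <= lo <= hi):
            raise ValueError("severe_ratio_range must lie in [0.5, inf)")
        lo, hi = self.event_duration_range
        if not (2.0 < lo <= hi <= SEGMENT_DURATION_S):
            raise ValueError("event_duration_range must lie in (2, 4]")


_CLASS_NOISE = {
    QualityClass.MILD_MYO: (NoiseKind.MYOELECTRIC, "mild"),
    QualityClass.SEVERE_MYO: (NoiseKind.MYOELECTRIC, "severe"),
    QualityClass.MILD_MOTION: (NoiseKind.MOTION, "mild"),
    QualityClass.SEVERE_MOTION: (NoiseKind.MOTION, "severe"),
}


def _segment_seed(master: int, cls: QualityClass, index: int) -> int:
    ss = np.random.SeedSequence([master, int(cls), index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(spec: DatasetSpec) -> list[SyntheticSegment]:
    """Generate a labelled dataset with exactly the requested class counts.

    Segments are emitted grouped by class in enum order; every segment's
    ``true_class`` is re-derived through the labeller from its ground-truth
    events, so generator and labeller cannot silently drift apart.
    """
    out: list[SyntheticSegment] = []
    for cls in QualityClass:
        n = int(spec.counts.get(cls, 0))
        for i in range(n):
            seg_seed = _segment_seed(spec.seed, cls, i)
            rng = np.random.default_rng(seg_seed)
            params = CleanEcgParams(
                heart_rate_bpm=rng.uniform(*spec.heart_rate_range),
                r_amplitude_mv=rng.uniform(*spec.r_amplitude_range),
            )
            clean = generate_clean_segment(params, seg_seed + 1)
            if cls is QualityClass.LOW:
                out.append(clean)
                continue
            kind, severity = _CLASS_NOISE[cls]
            ratio_range = (
                spec.mild_ratio_range if severity == "mild" else spec.severe_ratio_range
            )
            duration = rng.uniform(*spec.event_duration_range)
            start = rng.uniform(0.0, SEGMENT_DURATION_S - duration)
            event = NoiseEvent(
                kind=kind,
                start_s=start,
                end_s=start + duration,
                peak_ratio=rng.uniform(*ratio_range),
            )
            seg = compose_segment(clean, [event], seg_seed + 2)
            if seg.true_class is not cls:  # pragma: no cover - generator contract
                raise RuntimeError(
                    f"generated segment labelled {seg.true_class}, expected {cls}"
                )
            out.append(seg)
    return out
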