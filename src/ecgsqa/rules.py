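"""Rule-based quality labelling of 4-second dynamic-ECG segments.

A segment is assigned one of five interference classes — low interference,
mild/severe myoelectric noise, mild/severe motion artifact — from the noise
events it contains.  The rule set mirrors how cardiologists annotate Holter
segments: an interference type must dominate the 4-second window (total
duration above 2 s) to become the label, and its severity is judged by the
peak noise amplitude relative to the height of a clean R wave.  The five
classes collapse onto three clinical levels (low / mild / severe), and mixed
findings within a longer stretch of record are resolved by always reporting
the highest level present.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "NoiseKind",
    "QualityClass",
    "QualityLevel",
    "NoiseEvent",
    "label_segment",
    "class_to_level",
    "resolve_mixed_interference",
    "DOMINANCE_DURATION_S",
    "SEVERE_RATIO_THRESHOLD",
    "SEGMENT_DURATION_S",
]

#: An interference type labels the segment only if it occupies more than
#: this many seconds of the 4-second window.
DOMINANCE_DURATION_S = 2.0

#: Noise peaks at or above this fraction of the R-wave height are "severe";
#: below it, "mild".  The boundary itself is closed upward: equality counts
#: as severe, the clinically cautious reading.
SEVERE_RATIO_THRESHOLD = 0.5

#: Length of one analysis window in seconds.
SEGMENT_DURATION_S = 4.0


class NoiseKind(enum.Enum):
    """Interference type present in a dynamic ECG segment."""

    MOTION = "motion"
    MYOELECTRIC = "myoelectric"


class QualityClass(enum.IntEnum):
    """Five-way segment label; integer codes are the serialization order."""

    LOW = 0
    MILD_MYO = 1
    SEVERE_MYO = 2
    MILD_MOTION = 3
    SEVERE_MOTION = 4


class QualityLevel(enum.IntEnum):
    """Clinical interference level, totally ordered by severity."""

    LOW = 0
    MILD = 1
    SEVERE = 2


@dataclass(frozen=True)
class NoiseEvent:
    """One contiguous interference interval inside a 4-second segment.

    Parameters
    ----------
    kind:
        Interference type (motion artifact or myoelectric noise).
    start_s, end_s:
        Interval endpoints in seconds within ``[0, 4]``.
    peak_ratio:
        Maximum absolute noise amplitude divided by the segment's clean
        R-wave height (dimensionless, >= 0).
    """

    kind: NoiseKind
    start_s: float
    end_s: float
    peak_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_s < self.end_s <= SEGMENT_DURATION_S:
            raise ValueError(
                f"event interval [{self.start_s}, {self.end_s}] must satisfy "
                f"0 <= start < end <= {SEGMENT_DURATION_S}"
            )
        if self.peak_ratio < 0.0:
            raise ValueError("peak_ratio must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def label_segment(events: Iterable[NoiseEvent], r_height_mv: float) -> QualityClass:
    """Assign the five-class quality label implied by a segment's noise events.

    The label is LOW unless some interference type's total duration exceeds
    2 s.  When one type dominates, severity follows the largest peak ratio of
    that type: >= 0.5 of the R height is severe, below is mild.  If both
    types dominate (rare by construction), the longer total duration wins,
    with motion breaking an exact tie.

    Parameters
    ----------
    events:
        Noise events within the segment.
    r_height_mv:
        Clean R-wave height in mV used as the amplitude reference; must be
        positive.

    Returns
    -------
    QualityClass
    """
    if r_height_mv <= 0.0:
        raise ValueError("r_height_mv must be positive")
    events = list(events)

    totals = {kind: 0.0 for kind in NoiseKind}
    peaks = {kind: 0.0 for kind in NoiseKind}
    for ev in events:
        totals[ev.kind] += ev.duration_s
        peaks[ev.kind] = max(peaks[ev.kind], ev.peak_ratio)

    dominant = [k for k in NoiseKind if totals[k] > DOMINANCE_DURATION_S]
    if not dominant:
        return QualityClass.LOW
    if len(dominant) == 2:
        # Longer total duration wins; exact tie -> motion (fixed tie-break).
        if totals[NoiseKind.MOTION] >= totals[NoiseKind.MYOELECTRIC]:
            winner = NoiseKind.MOTION
        else:
            winner = NoiseKind.MYOELECTRIC
    else:
        winner = dominant[0]

    severe = peaks[winner] >= SEVERE_RATIO_THRESHOLD
    if winner is NoiseKind.MOTION:
        return QualityClass.SEVERE_MOTION if severe else QualityClass.MILD_MOTION
    return QualityClass.SEVERE_MYO if severe else QualityClass.MILD_MYO


_CLASS_TO_LEVEL = {
    QualityClass.LOW: QualityLevel.LOW,
    QualityClass.MILD_MYO: QualityLevel.MILD,
    QualityClass.MILD_MOTION: QualityLevel.MILD,
    QualityClass.SEVERE_MYO: QualityLevel.SEVERE,
    QualityClass.SEVERE_MOTION: QualityLevel.SEVERE,
}


def class_to_level(c: QualityClass) -> QualityLevel:
    """Collapse the five-class label onto the three clinical levels."""
    return _CLASS_TO_LEVEL[QualityClass(c)]


def resolve_mixed_interference(levels_present: Iterable[QualityLevel]) -> QualityLevel:
    """Aggregate levels found across a stretch of record to a single level.

    The highest interference level present is reported, even if it lasted
    under 2 s: a reviewer shown "low" must be able to trust that nothing
    worse was seen.
    """
    levels = [QualityLevel(v) for v in levels_present]
    if not levels:
        raise ValueError("levels_present must be non-empty")
    return max(levels)
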