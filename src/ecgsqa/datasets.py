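"""Dataset persistence: HDF5 container and delimited-text export.

The HDF5 layout holds the sample matrix (n x 512, mV), integer class
labels, ground-truth R heights and a flat event table indexed by segment.
The text export is one segment per row (label, R height, then 512 samples,
comma-separated) for quick inspection with standard tools; it does not
carry the event table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .rules import NoiseEvent, NoiseKind, QualityClass
from .synthetic import SEGMENT_SAMPLES, SyntheticSegment

__all__ = ["write_dataset", "read_dataset", "export_csv"]

_KIND_CODE = {NoiseKind.MOTION: 0, NoiseKind.MYOELECTRIC: 1}
_CODE_KIND = {v: k for k, v in _KIND_CODE.items()}


def write_dataset(path: str | Path, segments: Sequence[SyntheticSegment]) -> None:
    """Write segments (samples, labels, R heights, event table) to HDF5."""
    seg_idx, kinds, starts, ends, ratios = [], [], [], [], []
    for i, s in enumerate(segments):
        for ev in s.events:
            seg_idx.append(i)
            kinds.append(_KIND_CODE[ev.kind])
            starts.append(ev.start_s)
            ends.append(ev.end_s)
            ratios.append(ev.peak_ratio)
    # track_times=False keeps rewrites of the same data byte-identical
    with h5py.File(path, "w") as f:
        f.attrs["n_segments"] = len(segments)
        f.create_dataset("samples", data=np.stack([s.samples for s in segments])
                         if segments else np.empty((0, SEGMENT_SAMPLES)),
                         track_times=False)
        f.create_dataset("labels", data=np.array([int(s.true_class) for s in segments],
                                                 dtype=np.int8), track_times=False)
        f.create_dataset("r_height_mv", data=np.array([s.r_height_mv for s in segments]),
                         track_times=False)
        ev = f.create_group("events")
        ev.create_dataset("segment", data=np.array(seg_idx, dtype=np.int64),
                          track_times=False)
        ev.create_dataset("kind", data=np.array(kinds, dtype=np.int8), track_times=False)
        ev.create_dataset("start_s", data=np.array(starts), track_times=False)
        ev.create_dataset("end_s", data=np.array(ends), track_times=False)
        ev.create_dataset("peak_ratio", data=np.array(ratios), track_times=False)


def read_dataset(path: str | Path) -> list[SyntheticSegment]:
    """Read a dataset written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        labels = f["labels"][...]
        r_heights = f["r_height_mv"][...]
        ev_seg = f["events/segment"][...]
        ev_kind = f["events/kind"][...]
        ev_start = f["events/start_s"][...]
        ev_end = f["events/end_s"][...]
        ev_ratio = f["events/peak_ratio"][...]
    events_per_segment: dict[int, list[NoiseEvent]] = {}
    for s_i, k, a, b, r in zip(ev_seg, ev_kind, ev_start, ev_end, ev_ratio):
        events_per_segment.setdefault(int(s_i), []).append(
            NoiseEvent(kind=_CODE_KIND[int(k)], start_s=float(a), end_s=float(b),
                       peak_ratio=float(r))
        )
    return [
        SyntheticSegment(
            samples=samples[i],
            r_height_mv=float(r_heights[i]),
            events=tuple(events_per_segment.get(i, ())),
            true_class=QualityClass(int(labels[i])),
        )
        for i in range(samples.shape[0])
    ]


def export_csv(path: str | Path, segments: Sequence[SyntheticSegment]) -> None:
    """One segment per row: label code, R height, 512 samples."""
    with open(path, "w") as fh:
        for s in segments:
            vals = ",".join(f"{v:.6g}" for v in s.samples)
            fh.write(f"{int(s.true_class)},{s.r_height_mv:.6g},{vals}\n")
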