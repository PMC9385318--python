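"""Non-overlapping fixed-length windowing and preictal/interictal labeling.

Recordings are tiled with 5-second windows (the trailing remainder is
dropped).  Given the seizure annotation and a *qualifying window* — the
assumed preictal duration before each onset — every window receives exactly
one label:

``discarded``
    overlaps a seizure interval (ictal data carry no predictive value);
``preictal``
    lies wholly inside ``[onset - qw, onset)`` of some seizure;
``interictal``
    everything else, including post-seizure time.

Precedence when rules collide is discarded > preictal > interictal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .types import LabeledSegment, Recording, SeizureAnnotation

#: default qualifying-window lengths, minutes
DEFAULT_QUALIFYING_WINDOWS_MIN: tuple[float, ...] = (15.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class QualifyingWindow:
    """Assumed preictal duration before each seizure onset."""

    length_min: float

    def __post_init__(self) -> None:
        if not self.length_min > 0:
            raise ValueError("qualifying window must be positive")

    @property
    def length_s(self) -> float:
        return self.length_min * 60.0


def segment_recording(
    rec: Recording, window_s: float = 5.0, overlap: float = 0.0
) -> list[LabeledSegment]:
    """Tile ``rec`` with unlabeled windows of ``window_s`` seconds.

    Only non-overlapping tiling is supported (``overlap`` is accepted for
    interface compatibility and must be 0).  A recording shorter than one
    window yields an empty list.
    """
    if overlap != 0.0:
        raise NotImplementedError("overlapping segmentation is not supported")
    n_win = int(round(window_s * rec.fs))
    if n_win < 1:
        raise ValueError("window shorter than one sample")
    out = []
    for i in range(rec.n_samples // n_win):
        start = i * n_win
        out.append(
            LabeledSegment(
                record_id=rec.record_id,
                index=i,
                start_sample=start,
                n_samples=n_win,
                start_s=start / rec.fs,
                duration_s=n_win / rec.fs,
            )
        )
    return out


def label_segments(
    segments: list[LabeledSegment],
    annotation: SeizureAnnotation,
    qw: QualifyingWindow,
) -> list[LabeledSegment]:
    """Assign preictal/interictal/discarded labels for one recording.

    The qualifying window of each seizure is clipped at the recording start;
    a segment must lie *wholly* inside a qualifying window to be preictal
    (a window-straddling segment stays interictal).
    """
    out = []
    for seg in segments:
        s0, s1 = seg.start_s, seg.end_s
        label = "interictal"
        for start, end in annotation.intervals:
            if s0 < end and s1 > start:  # overlaps ictal interval
                label = "discarded"
                break
        if label != "discarded":
            for start, _ in annotation.intervals:
                w0 = max(0.0, start - qw.length_s)
                if s0 >= w0 and s1 <= start:
                    label = "preictal"
                    break
        out.append(replace(seg, label=label))
    return out


def segments_to_frame(segments: list[LabeledSegment]) -> pd.DataFrame:
    """Segment table (record_id, index, start_s, label) for CSV export."""
    return pd.DataFrame(
        {
            "record_id": [s.record_id for s in segments],
            "index": [s.index for s in segments],
            "start_s": [s.start_s for s in segments],
            "label": [s.label for s in segments],
        }
    )


def label_counts(segments: list[LabeledSegment]) -> dict[str, int]:
    counts = {"preictal": 0, "interictal": 0, "discarded": 0}
    for seg in segments:
        counts[seg.label] += 1
    return counts
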