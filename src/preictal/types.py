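"""Core domain containers shared across the pipeline.

A :class:`Recording` is the in-memory form of one continuous multichannel EEG
file: a channels x samples matrix plus sampling rate and ordered channel
labels.  :class:`SeizureAnnotation` carries the clinician-marked (start, end)
seizure intervals for one recording, in seconds from the recording's own
start (0-based, half-open ``[start_s, end_s)``).  :class:`LabeledSegment`
identifies one fixed-length analysis window and its class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

SegmentLabel = Literal["preictal", "interictal", "discarded"]

#: label values, in precedence order (highest first)
LABELS: tuple[str, ...] = ("discarded", "preictal", "interictal")


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


class UnsupportedDialectError(FormatError):
    """The file is syntactically valid but uses an unsupported variant
    (e.g. per-channel sampling rates differing within one EDF)."""


class NoCommonChannelsError(ValueError):
    """Channel harmonization found an empty intersection."""


@dataclass
class Recording:
    """One continuous multichannel recording.

    Parameters
    ----------
    record_id : str
        Identifier, typically the file stem (e.g. ``chb01_03``).
    channel_labels : list of str
        Unique channel names, in signal-matrix row order.
    fs : float
        Sampling rate in Hz, shared by every channel.
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in the file's physical units (CHB-MIT: microvolts).
    """

    record_id: str
    channel_labels: list[str]
    fs: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.signal.shape[0] == 0:
            raise ValueError("recording must have at least one channel")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def subset_channels(self, labels: Sequence[str]) -> "Recording":
        """Return a copy restricted to ``labels``, in the given order."""
        idx = [self.channel_labels.index(lb) for lb in labels]
        return Recording(
            record_id=self.record_id,
            channel_labels=list(labels),
            fs=self.fs,
            signal=self.signal[idx],
        )


@dataclass
class SeizureAnnotation:
    """Seizure intervals for one recording, seconds from recording start."""

    record_id: str
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e)) for s, e in self.intervals]
        for s, e in ivs:
            if not (0 <= s < e):
                raise ValueError(f"invalid seizure interval ({s}, {e})")
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("seizure intervals overlap")
        self.intervals = ivs

    @property
    def n_seizures(self) -> int:
        return len(self.intervals)


@dataclass
class LabeledSegment:
    """One analysis window inside a recording.

    ``label`` is None until :func:`preictal.segmentation.label_segments`
    assigns one of ``preictal | interictal | discarded``.
    """

    record_id: str
    index: int
    start_sample: int
    n_samples: int
    start_s: float
    duration_s: float
    label: SegmentLabel | None = None

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s
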