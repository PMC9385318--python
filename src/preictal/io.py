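"""Reading recordings and seizure annotations.

EDF files are read through MNE and returned in the file's own physical units
(MNE internally converts EEG channels to volts; the conversion is undone
using the per-signal physical-dimension field of the EDF header).  Seizure
annotations come either from CHB-MIT-style plain-text summary files or from
a JSON sidecar ``{"record_id": ..., "intervals": [[start_s, end_s], ...]}``
used as the internal canonical form.

A deliberately small 16-bit EDF writer is included so that synthetic
fixtures can be round-tripped through the same reader as real data.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from pathlib import Path

import numpy as np

from .types import (
    FormatError,
    NoCommonChannelsError,
    Recording,
    SeizureAnnotation,
    UnsupportedDialectError,
)

# physical-dimension strings understood when undoing MNE's SI conversion
_UNIT_TO_VOLTS = {"v": 1.0, "mv": 1e-3, "uv": 1e-6, "µv": 1e-6}


def _edf_header_fields(path: Path) -> tuple[int, list[int], float]:
    """Return (n_signals, samples-per-record per signal, record duration)."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            record_dur = float(header[244:252].decode("ascii"))
            ns = int(header[252:256].decode("ascii"))
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        sig_header = fh.read(ns * 256)
        if len(sig_header) < ns * 256:
            raise FormatError(f"{path}: truncated EDF signal headers")
        off = ns * 216  # label..dig-max fields precede samples-per-record
        try:
            spr = [
                int(sig_header[off + i * 8 : off + (i + 1) * 8].decode("ascii"))
                for i in range(ns)
            ]
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed samples-per-record") from exc
    return ns, spr, record_dur


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Amplitudes are returned in the file's physical units.  Files whose
    channels carry different sampling rates are rejected (no silent
    resampling); EDF annotation channels are not supported.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ns, spr, _ = _edf_header_fields(path)
    if ns == 0:
        raise FormatError(f"{path}: EDF file declares zero signals")
    if len(set(spr)) > 1:
        raise UnsupportedDialectError(
            f"{path}: channels with differing sampling rates "
            f"(samples-per-record {sorted(set(spr))}); resampling is not applied"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for broken files
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc

    data = raw.get_data()  # SI units (volts for EEG-typed channels)
    orig_units = getattr(raw, "_orig_units", {}) or {}
    for i, ch in enumerate(raw.ch_names):
        unit = str(orig_units.get(ch, "")).strip().lower()
        factor = _UNIT_TO_VOLTS.get(unit)
        if factor is not None:
            data[i] = data[i] / factor
    return Recording(
        record_id=path.stem,
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        signal=data,
    )


# --------------------------------------------------------------------------
# CHB-MIT summary dialect
# --------------------------------------------------------------------------

_RE_FILE = re.compile(r"^File Name:\s*(\S+)", re.IGNORECASE)
_RE_NSEIZ = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.IGNORECASE)
_RE_START = re.compile(
    r"^Seizure\s*(?:\d+\s*)?Start Time:\s*([\d.]+)\s*sec", re.IGNORECASE
)
_RE_END = re.compile(
    r"^Seizure\s*(?:\d+\s*)?End Time:\s*([\d.]+)\s*sec", re.IGNORECASE
)


def parse_seizure_summary(text: str) -> list[SeizureAnnotation]:
    """Parse a CHB-MIT ``chbXX-summary.txt``-style listing.

    One :class:`SeizureAnnotation` is returned per ``File Name:`` block, in
    file order; blocks declaring zero seizures yield empty interval lists.
    """
    annotations: list[SeizureAnnotation] = []
    record_id: str | None = None
    intervals: list[tuple[float, float]] = []
    pending_start: float | None = None
    declared: int | None = None

    def _flush() -> None:
        nonlocal record_id, intervals, pending_start, declared
        if record_id is None:
            return
        if pending_start is not None:
            raise ValueError(
                f"{record_id}: seizure start {pending_start} without an end time"
            )
        if declared is not None and declared != len(intervals):
            raise ValueError(
                f"{record_id}: declared {declared} seizures, parsed {len(intervals)}"
            )
        annotations.append(
            SeizureAnnotation(record_id=record_id, intervals=intervals)
        )
        record_id, intervals, pending_start, declared = None, [], None, None

    for line in text.splitlines():
        line = line.strip()
        if m := _RE_FILE.match(line):
            _flush()
            record_id = Path(m.group(1)).stem
        elif m := _RE_NSEIZ.match(line):
            declared = int(m.group(1))
        elif m := _RE_START.match(line):
            if pending_start is not None:
                raise ValueError("seizure start without an end for the previous one")
            pending_start = float(m.group(1))
        elif m := _RE_END.match(line):
            if pending_start is None:
                raise ValueError("seizure end time without a start time")
            end = float(m.group(1))
            if end <= pending_start:
                raise ValueError(
                    f"seizure end {end} not after start {pending_start}"
                )
            intervals.append((pending_start, end))
            pending_start = None
    _flush()
    return annotations


def read_annotation_json(path: str | Path) -> SeizureAnnotation:
    with open(path) as fh:
        obj = json.load(fh)
    return SeizureAnnotation(
        record_id=obj["record_id"],
        intervals=[tuple(iv) for iv in obj["intervals"]],
    )


def write_annotation_json(ann: SeizureAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"record_id": ann.record_id,
             "intervals": [list(iv) for iv in ann.intervals]},
            fh, indent=1,
        )


# --------------------------------------------------------------------------
# Channel harmonization
# --------------------------------------------------------------------------

def harmonize_channels(recordings: list[Recording]) -> list[str]:
    """Channels present in *every* recording, ordered as in the first.

    Long-term monitoring sessions change montage between files; channels not
    available throughout are dropped so every file contributes the same
    feature columns.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    common = set(recordings[0].channel_labels)
    for rec in recordings[1:]:
        common &= set(rec.channel_labels)
    if not common:
        raise NoCommonChannelsError(
            "no channel label is shared by all recordings"
        )
    return [ch for ch in recordings[0].channel_labels if ch in common]


# --------------------------------------------------------------------------
# Minimal EDF writer (16-bit, one fixed-duration data record per second)
# --------------------------------------------------------------------------

def _ascii(value: str, width: int) -> bytes:
    out = value.encode("ascii", errors="replace")[:width]
    return out.ljust(width)


def write_edf(
    rec: Recording,
    path: str | Path,
    physical_dim: str = "uV",
    record_duration_s: float = 1.0,
) -> None:
    """Write ``rec`` as a 16-bit EDF file.

    The physical range is taken from the data (symmetric), digital range is
    the full int16 span, so the quantization step is ``2*max|x| / 65535``.
    Trailing samples that do not fill a whole data record are dropped.
    """
    if rec.n_channels == 0:
        raise ValueError("cannot write an EDF file with zero channels")
    sig = rec.signal
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal contains non-finite amplitudes")
    spr = int(round(rec.fs * record_duration_s))
    if spr < 1:
        raise ValueError("record duration shorter than one sample")
    n_records = sig.shape[1] // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record")

    phys_max = float(np.max(np.abs(sig))) if sig.size else 1.0
    if phys_max == 0.0:
        phys_max = 1.0
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(
        np.round((sig + phys_max) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    ns = rec.n_channels
    start = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),                      # patient id
        _ascii(f"Startdate 01-JAN-2000 X X {rec.record_id}", 80),
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(str(256 * (1 + ns)), 8),
        _ascii("", 44),
        _ascii(str(n_records), 8),
        _ascii(f"{record_duration_s:g}", 8),
        _ascii(str(ns), 4),
    ])
    fields = [
        [_ascii(lb, 16) for lb in rec.channel_labels],
        [_ascii("EEG", 80)] * ns,                   # transducer
        [_ascii(physical_dim, 8)] * ns,
        [_ascii(f"{-phys_max:.6g}", 8)] * ns,
        [_ascii(f"{phys_max:.6g}", 8)] * ns,
        [_ascii(str(dig_min), 8)] * ns,
        [_ascii(str(dig_max), 8)] * ns,
        [_ascii("", 80)] * ns,                      # prefiltering
        [_ascii(str(spr), 8)] * ns,
        [_ascii("", 32)] * ns,                      # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.writelines(group)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def edf_quantization_step(rec: Recording) -> float:
    """Worst-case amplitude error introduced by :func:`write_edf`."""
    phys_max = float(np.max(np.abs(rec.signal))) or 1.0
    return 2 * phys_max / 65535
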