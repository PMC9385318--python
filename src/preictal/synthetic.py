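"""Seeded generator of EEG-like multichannel recordings with known seizures.

The background is per-channel band-limited 1/f Gaussian noise (flattened
below 1 Hz), optionally mixed with a shared component to mimic volume
conduction between scalp electrodes.  Seizures are injected as
high-amplitude 4 Hz oscillations.  Ahead of each seizure a *preictal
signature* with a controllable effect size is applied:

* ``variance_ratio`` — preictal variance is rescaled to this fraction of
  the local background variance (preictal variance reduction);
* ``kurtosis_boost`` — sparse heavy-tailed spikes raise the standardized
  4th moment by roughly this amount while adding little variance;
* ``band_shift`` — named EEG bands get their power multiplied (e.g.
  ``{"alpha": 3.0}``), shifting the spectral distribution.

The signature is parametric, not biophysical: it gives the pipeline a
ground-truth effect of known size.  With the identity signature
(ratio 1, boost 0, no shift) preictal and interictal data are statistically
identical, which is the negative control for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features_freq import EEG_BANDS
from .io import write_annotation_json, write_edf
from .types import Recording, SeizureAnnotation

#: background RMS amplitude, microvolts (typical scalp EEG)
BACKGROUND_RMS_UV = 50.0
#: spike rate per sample used for the kurtosis boost
SPIKE_RATE = 0.01


@dataclass
class PreictalSignature:
    variance_ratio: float = 1.0
    kurtosis_boost: float = 0.0
    band_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.variance_ratio <= 1:
            raise ValueError("variance_ratio must be in (0, 1]")
        if self.kurtosis_boost < 0:
            raise ValueError("kurtosis_boost must be >= 0")
        for band in self.band_shift:
            if band not in EEG_BANDS:
                raise ValueError(f"unknown EEG band {band!r}")

    @property
    def is_identity(self) -> bool:
        return (self.variance_ratio == 1.0 and self.kurtosis_boost == 0.0
                and not self.band_shift)


@dataclass
class SyntheticConfig:
    n_channels: int = 3
    fs: float = 256.0
    duration_s: float = 3600.0
    seizure_times: list[tuple[float, float]] = field(default_factory=list)
    preictal_len_s: float = 900.0
    signature: PreictalSignature = field(default_factory=PreictalSignature)
    inter_channel_coupling: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if not 0 <= self.inter_channel_coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        prev_end = -np.inf
        for s, e in sorted(self.seizure_times):
            if not (0 <= s < e <= self.duration_s):
                raise ValueError(f"seizure ({s}, {e}) outside recording")
            if s < prev_end:
                raise ValueError("seizure intervals overlap")
            prev_end = e


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-weighted Gaussian noise, flat below 1 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weights = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    weights[0] = 0.0  # no DC
    spec = weights * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    x = np.fft.irfft(spec, n=n)
    return x / np.std(x)


def _band_component(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """FFT-mask band-pass of x over [lo, hi] Hz."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    return np.fft.irfft(spec * mask, n=x.size)


def preictal_windows(cfg: SyntheticConfig) -> list[tuple[float, float]]:
    """[onset - preictal_len, onset) per seizure, clipped at the recording
    start and at the previous seizure's end."""
    out = []
    prev_end = 0.0
    for s, e in sorted(cfg.seizure_times):
        w0 = max(0.0, s - cfg.preictal_len_s, prev_end)
        if w0 < s:
            out.append((w0, s))
        prev_end = e
    return out


def generate_recording(
    cfg: SyntheticConfig, record_id: str = "synthetic"
) -> tuple[Recording, SeizureAnnotation]:
    """Multichannel recording plus its ground-truth seizure annotation.

    Fully reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    shared = _pink_noise(rng, n, fs)
    c = cfg.inter_channel_coupling
    signal = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        own = _pink_noise(rng, n, fs)
        signal[ch] = BACKGROUND_RMS_UV * (
            np.sqrt(1.0 - c**2) * own + c * shared
        )

    sig = cfg.signature
    for w0, w1 in preictal_windows(cfg):
        i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
        for ch in range(cfg.n_channels):
            x = signal[ch, i0:i1].copy()
            base_var = np.var(x)
            for band, mult in sig.band_shift.items():
                lo, hi = EEG_BANDS[band]
                comp = _band_component(x, fs, lo, hi)
                x = x + (np.sqrt(mult) - 1.0) * comp
            # rescale so preictal variance = variance_ratio * background variance
            cur = np.var(x)
            if cur > 0:
                x *= np.sqrt(sig.variance_ratio * base_var / cur)
            if sig.kurtosis_boost > 0:
                sigma = np.sqrt(np.var(x))
                amp = sigma * (sig.kurtosis_boost / SPIKE_RATE) ** 0.25
                spikes = (
                    (rng.random(x.size) < SPIKE_RATE)
                    * rng.choice([-1.0, 1.0], size=x.size)
                    * amp
                )
                x = x + spikes
            signal[ch, i0:i1] = x

    for s, e in cfg.seizure_times:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        t = np.arange(i1 - i0) / fs
        for ch in range(cfg.n_channels):
            phase = rng.uniform(0, 2 * np.pi)
            signal[ch, i0:i1] += (
                3.0 * BACKGROUND_RMS_UV * np.sin(2 * np.pi * 4.0 * t + phase)
            )

    rec = Recording(
        record_id=record_id,
        channel_labels=[f"CH{k + 1}" for k in range(cfg.n_channels)],
        fs=fs,
        signal=signal,
    )
    ann = SeizureAnnotation(
        record_id=record_id,
        intervals=[(float(s), float(e)) for s, e in sorted(cfg.seizure_times)],
    )
    return rec, ann


def write_fixture_edf(
    rec: Recording,
    path: str | Path,
    annotation: SeizureAnnotation | None = None,
) -> None:
    """Write an EDF fixture (and a JSON annotation sidecar if given)."""
    path = Path(path)
    write_edf(rec, path)
    if annotation is not None:
        write_annotation_json(annotation, path.with_suffix(".json"))
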