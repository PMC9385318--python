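"""Frequency-domain features: periodogram band powers and DWT sub-band energies.

Two complementary views of each window's energy distribution:

* a raw (untapered, unaveraged) one-sided periodogram, aggregated over the
  six canonical EEG bands — delta 1-3, theta 4-7, alpha 8-13, beta 14-30,
  gamma1 31-55 and gamma2 65-110 Hz — plus the total power above 0 Hz.
  The 0-1 Hz and 55-65 Hz (power-line) regions belong to no band, so the
  band powers need not sum to the total.
* a 7-level discrete wavelet pyramid (Daubechies db4, periodized
  boundaries): detail energies cover the dyadic bands 64-128 down to
  1-2 Hz at fs = 256 Hz; the <1 Hz approximation band is computed for the
  energy-conservation check but excluded from the feature set, since that
  region is dominated by slow non-cerebral potentials.

Periodogram ordinates are |rfft|^2 / N with interior bins doubled (one-sided
power-spectrum scaling); only power *ratios* matter downstream, so any
consistent normalization is equivalent.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pywt

#: canonical EEG bands, Hz, inclusive edges
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma1": (31.0, 55.0),
    "gamma2": (65.0, 110.0),
}

DWT_LEVELS = 7
DWT_WAVELET = "db4"

#: nominal detail-band edges at fs = 256 Hz, level 1..7
DWT_BAND_EDGES_256 = (
    (64.0, 128.0), (32.0, 64.0), (16.0, 32.0), (8.0, 16.0),
    (4.0, 8.0), (2.0, 4.0), (1.0, 2.0),
)


class BandPowers(NamedTuple):
    p_delta: float
    p_theta: float
    p_alpha: float
    p_beta: float
    p_gamma1: float
    p_gamma2: float
    p_total: float


class DwtEnergies(NamedTuple):
    """Detail energies, level 1 (highest band) .. 7, plus the approximation."""

    e_detail: tuple[float, ...]
    e_approx: float


def periodogram_onesided(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum: frequencies and ordinates |X|^2-scaled."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    # double interior bins so the one-sided spectrum preserves total power
    if n % 2 == 0:
        spec[1:-1] *= 2.0
    else:
        spec[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def band_powers(x: np.ndarray, fs: float) -> BandPowers:
    """Aggregate the periodogram over the six canonical bands + total power.

    Band edges are inclusive; the gamma2 band is truncated at Nyquist (with
    a warning) when fs < 220 Hz.  Total power excludes the DC ordinate.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    freqs, spec = periodogram_onesided(x, fs)
    nyq = fs / 2.0
    if EEG_BANDS["gamma2"][1] > nyq:
        warnings.warn(
            f"gamma2 band truncated at Nyquist ({nyq:g} Hz)", stacklevel=2
        )
    powers = []
    for lo, hi in EEG_BANDS.values():
        mask = (freqs >= lo) & (freqs <= min(hi, nyq))
        powers.append(float(spec[mask].sum()))
    p_total = float(spec[freqs > 0].sum())
    return BandPowers(*powers, p_total)


def dwt_band_energies(
    x: np.ndarray, fs: float = 256.0, wavelet: str = DWT_WAVELET
) -> DwtEnergies:
    """Energies of the 7-level wavelet detail bands.

    Uses periodized signal extension so the decomposition is orthogonal and
    total energy is conserved exactly:  sum of the 7 detail energies plus
    the approximation energy equals ``sum(x**2)`` to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2**DWT_LEVELS:
        raise ValueError(
            f"signal of {x.size} samples too short for a "
            f"{DWT_LEVELS}-level decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=DWT_LEVELS)
    # wavedec returns [cA_7, cD_7, ..., cD_1]; reorder details level 1..7
    e_approx = float(np.sum(coeffs[0] ** 2))
    details = coeffs[1:]                # cD_7 .. cD_1
    e_detail = tuple(float(np.sum(c**2)) for c in reversed(details))
    return DwtEnergies(e_detail=e_detail, e_approx=e_approx)
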