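"""Per-channel time-domain features of a 5-s EEG window.

Nine descriptors computed directly on the sampled amplitudes: mean,
variance, standard deviation, skewness, kurtosis, zero-crossing count,
signal range (max - min), peak absolute amplitude, and the area under the
rectified signal by the trapezoid rule.  Reduced variance and elevated
kurtosis in the window preceding a seizure are among the best-documented
scalp-EEG precursors, which is what these features target.

Conventions
-----------
* skewness / kurtosis are the standardized 3rd / 4th central moments with
  population normalization; kurtosis is NON-excess (a Gaussian scores 3).
  A zero-variance window returns 0 for both by convention.
* a zero crossing is a strict sign change between consecutive samples;
  exact-zero samples neither count nor break a crossing pair.
* the area integrates |x| with dt = 1/fs, so it is sign-invariant but
  sensitive to baseline shifts.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

TIME_FEATURE_NAMES = (
    "mean", "variance", "std", "skewness", "kurtosis",
    "zero_crossings", "signal_range", "peak_amplitude", "area",
)


class TimeFeatures(NamedTuple):
    mean: float
    variance: float
    std: float
    skewness: float
    kurtosis: float
    zero_crossings: int
    signal_range: float
    peak_amplitude: float
    area: float


def zero_crossing_count(x: np.ndarray) -> int:
    """Strict sign-change count; exact zeros are transparent."""
    signs = np.sign(x)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def time_domain_features(x: np.ndarray, fs: float) -> TimeFeatures:
    """All nine time-domain descriptors of one single-channel window."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("x must be a 1-D vector of length >= 2")
    if not fs > 0:
        raise ValueError("fs must be positive")
    mean = float(np.mean(x))
    var = float(np.var(x))
    std = float(np.sqrt(var))
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew = kurt = 0.0
    return TimeFeatures(
        mean=mean,
        variance=var,
        std=std,
        skewness=skew,
        kurtosis=kurt,
        zero_crossings=zero_crossing_count(x),
        signal_range=float(np.max(x) - np.min(x)),
        peak_amplitude=float(np.max(np.abs(x))),
        area=float(np.trapezoid(np.abs(x), dx=1.0 / fs)),
    )
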