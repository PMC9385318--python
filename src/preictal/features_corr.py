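"""Between-channel cross-correlation and per-channel decorrelation time.

Synchronization *and* de-synchronization between cortical regions both
carry predictive information, so the scalar kept per channel pair is the
signed normalized cross-correlation at the lag of maximum absolute value:
+1 for identical channels, -1 for anti-phase ones.

The correlation function is Pearson-style: means removed, normalized by the
two standard deviations and by the per-lag overlap length (unbiased), over
lags ``-max_lag .. +max_lag``.

The decorrelation time of a channel is the lag at which its normalized
autocorrelation first becomes non-positive, in seconds; white noise
decorrelates after one sample, rhythmic activity after a quarter period.
If the autocorrelation never crosses zero within the window the value is
censored at the window duration.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from scipy import signal as _signal


class CrossCorrelation(NamedTuple):
    rho_max: float
    lag_at_max: int


class DecorrelationTime(NamedTuple):
    seconds: float
    censored: bool


def cross_correlation(
    ci: np.ndarray, cj: np.ndarray, max_lag: int | None = None
) -> CrossCorrelation:
    """Signed peak of the normalized cross-correlation of two channels.

    Ties on |rho| resolve to the smallest |lag|, then to the negative lag.
    A zero-variance channel yields (0.0, 0) with a warning, since the
    sigma normalization is undefined.
    """
    ci = np.asarray(ci, dtype=float)
    cj = np.asarray(cj, dtype=float)
    if ci.shape != cj.shape or ci.ndim != 1:
        raise ValueError("channels must be equal-length 1-D vectors")
    n = ci.size
    if max_lag is None:
        max_lag = n // 10
    if not 0 <= max_lag < n:
        raise ValueError("max_lag must satisfy 0 <= max_lag < len(x)")
    si, sj = np.std(ci), np.std(cj)
    if si == 0.0 or sj == 0.0:
        warnings.warn("zero-variance channel: correlation undefined, using 0",
                      stacklevel=2)
        return CrossCorrelation(0.0, 0)
    a = ci - ci.mean()
    b = cj - cj.mean()
    full = _signal.correlate(a, b, mode="full", method="auto")
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= max_lag
    lags = lags[keep]
    overlap = n - np.abs(lags)
    rho = full[keep] / (overlap * si * sj)
    # max |rho|; ties -> smallest |lag|, then negative lag first.
    # |rho| is rounded so exact ties (periodic signals at whole-period
    # lags) are not broken arbitrarily by floating-point noise.
    order = np.lexsort((lags > 0, np.abs(lags), -np.round(np.abs(rho), 12)))
    best = order[0]
    # the unbiased estimator can marginally exceed |1| at short overlaps;
    # the reported coefficient is clipped to the normalized interval
    return CrossCorrelation(float(np.clip(rho[best], -1.0, 1.0)),
                            int(lags[best]))


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased normalized autocorrelation r[k]/r[0] for lags 0..n-1."""
    x = np.asarray(x, dtype=float)
    a = x - x.mean()
    full = _signal.correlate(a, a, mode="full", method="auto")
    r = full[x.size - 1 :]
    if r[0] == 0.0:
        raise ValueError("constant signal: autocorrelation undefined")
    return r / r[0]


def decorrelation_time(x: np.ndarray, fs: float) -> DecorrelationTime:
    """Lag of the first non-positive autocorrelation value, in seconds."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if not fs > 0:
        raise ValueError("fs must be positive")
    duration = x.size / fs
    if np.var(x) == 0.0:
        return DecorrelationTime(duration, censored=True)
    r = autocorrelation(x)
    nonpos = np.nonzero(r[1:] <= 0.0)[0]
    if nonpos.size == 0:
        return DecorrelationTime(duration, censored=True)
    return DecorrelationTime((int(nonpos[0]) + 1) / fs, censored=False)
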