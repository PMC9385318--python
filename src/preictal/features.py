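"""Assemble the per-segment feature table for one or more recordings.

Columns follow ``<channel>__<feature>`` for per-channel features,
``<chA>-<chB>__rho`` for channel-pair correlations, and the metadata
columns ``record_id``, ``segment_index``, ``start_s``, ``label``.

:class:`SegmentFeatureExtractor` is a stateless transformer (``fit`` only
validates parameters) so it composes with sklearn-style pipelines; the
module function :func:`extract_features` is the plain-call convenience.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .features_corr import cross_correlation, decorrelation_time
from .features_freq import DWT_LEVELS, band_powers, dwt_band_energies
from .features_time import TIME_FEATURE_NAMES, time_domain_features
from .types import LabeledSegment, Recording

METADATA_COLUMNS = ("record_id", "segment_index", "start_s", "label")


class SegmentFeatureExtractor:
    """Compute time / frequency / wavelet / correlation features per segment.

    Parameters
    ----------
    include : tuple of str
        Feature families to compute, any of
        ``{"time", "band", "dwt", "corr", "decorr"}``.
    max_lag : int or None
        Cross-correlation lag range in samples; default fs/2 (0.5 s).
    wavelet : str
        Mother wavelet for the detail-energy pyramid.
    """

    FAMILIES = ("time", "band", "dwt", "corr", "decorr")

    def __init__(
        self,
        include: tuple[str, ...] = FAMILIES,
        max_lag: int | None = None,
        wavelet: str = "db4",
    ):
        self.include = include
        self.max_lag = max_lag
        self.wavelet = wavelet

    def get_params(self, deep: bool = True) -> dict:
        return {"include": self.include, "max_lag": self.max_lag,
                "wavelet": self.wavelet}

    def set_params(self, **params) -> "SegmentFeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "SegmentFeatureExtractor":
        unknown = set(self.include) - set(self.FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families {sorted(unknown)}")
        return self

    # -- per-segment work ---------------------------------------------------

    def _segment_row(self, rec: Recording, seg: LabeledSegment) -> dict:
        sl = slice(seg.start_sample, seg.start_sample + seg.n_samples)
        window = rec.signal[:, sl]
        fs = rec.fs
        max_lag = self.max_lag if self.max_lag is not None else int(fs // 2)
        row: dict[str, float] = {}
        for ch, x in zip(rec.channel_labels, window):
            if "time" in self.include:
                tf = time_domain_features(x, fs)
                for name, val in zip(TIME_FEATURE_NAMES, tf):
                    row[f"{ch}__{name}"] = val
            if "band" in self.include:
                bp = band_powers(x, fs)
                for name, val in zip(bp._fields, bp):
                    row[f"{ch}__{name}"] = val
            if "dwt" in self.include:
                de = dwt_band_energies(x, fs, wavelet=self.wavelet)
                for lvl in range(1, DWT_LEVELS + 1):
                    row[f"{ch}__dwt_e{lvl}"] = de.e_detail[lvl - 1]
            if "decorr" in self.include:
                row[f"{ch}__decorr_time"] = decorrelation_time(x, fs).seconds
        if "corr" in self.include:
            for (la, xa), (lb, xb) in combinations(
                zip(rec.channel_labels, window), 2
            ):
                cc = cross_correlation(xa, xb, max_lag=max_lag)
                row[f"{la}-{lb}__rho"] = cc.rho_max
        return row

    def transform(
        self,
        recordings: Recording | list[Recording],
        segments: list[LabeledSegment],
    ) -> pd.DataFrame:
        """Feature table with one row per segment, metadata columns first.

        ``discarded`` (ictal) segments are passed through with their label so
        callers can drop them; their features are still computed.
        """
        self.fit()
        if isinstance(recordings, Recording):
            recordings = [recordings]
        by_id = {rec.record_id: rec for rec in recordings}
        rows = []
        for seg in segments:
            rec = by_id[seg.record_id]
            row = {
                "record_id": seg.record_id,
                "segment_index": seg.index,
                "start_s": seg.start_s,
                "label": seg.label,
            }
            row.update(self._segment_row(rec, seg))
            rows.append(row)
        return pd.DataFrame(rows)


def extract_features(
    recordings: Recording | list[Recording],
    segments: list[LabeledSegment],
    **params,
) -> pd.DataFrame:
    return SegmentFeatureExtractor(**params).transform(recordings, segments)


def raw_segment_table(
    recordings: Recording | list[Recording], segments: list[LabeledSegment]
) -> pd.DataFrame:
    """No-feature mode: each segment's row is its flattened raw samples.

    Column ``raw_<i>`` is channel-major sample i; this feeds the classifier
    directly with the windowed time series instead of derived features.
    """
    if isinstance(recordings, Recording):
        recordings = [recordings]
    by_id = {rec.record_id: rec for rec in recordings}
    rows = []
    for seg in segments:
        rec = by_id[seg.record_id]
        sl = slice(seg.start_sample, seg.start_sample + seg.n_samples)
        flat = rec.signal[:, sl].ravel()
        row = {
            "record_id": seg.record_id,
            "segment_index": seg.index,
            "start_s": seg.start_s,
            "label": seg.label,
        }
        row.update({f"raw_{i}": v for i, v in enumerate(flat)})
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Split a feature table into (values, feature-column names)."""
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[cols].to_numpy(dtype=float), cols
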