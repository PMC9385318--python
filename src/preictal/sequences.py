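"""Build ordered length-L sequences of per-segment feature vectors.

The classifier consumes blocks of L consecutive 5-s segments.  Blocks are
taken with stride 1 inside every maximal run of same-label, temporally
consecutive segments of one recording; blocks never cross a label change
or a recording boundary, so each sequence has a well-defined binary label.
Each block is attributed to its *last* segment (causal attribution), which
is what event scoring uses to place predictions on the timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import METADATA_COLUMNS


@dataclass
class SequenceDataset:
    """Sequences (n, L, d), their labels, and per-sequence metadata.

    ``meta`` has one row per sequence: record_id, the last segment's index
    and start_s, and the block label.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    meta: pd.DataFrame

    def __len__(self) -> int:
        return self.X.shape[0]


def build_sequences(
    table: pd.DataFrame,
    L: int,
    feature_columns: list[str] | None = None,
) -> SequenceDataset:
    """Stride-1 length-L blocks of consecutive same-label segments.

    ``table`` is a feature table from
    :class:`~preictal.features.SegmentFeatureExtractor` (metadata columns +
    feature columns); ``discarded`` segments are ignored and break runs.
    """
    if not 1 <= L <= 50:
        raise ValueError("sequence length L must be in [1, 50]")
    if feature_columns is None:
        feature_columns = [c for c in table.columns
                           if c not in METADATA_COLUMNS]
    usable = table[table["label"].isin(["preictal", "interictal"])]
    X_blocks, y_blocks, meta_rows = [], [], []
    for rid, group in usable.groupby("record_id", sort=False):
        group = group.sort_values("segment_index")
        idx = group["segment_index"].to_numpy()
        labels = group["label"].to_numpy()
        feats = group[feature_columns].to_numpy(dtype=float)
        starts = group["start_s"].to_numpy()
        # split into maximal runs of consecutive indices with constant label
        run_start = 0
        boundaries = list(
            np.nonzero(
                (np.diff(idx) != 1) | (labels[1:] != labels[:-1])
            )[0] + 1
        ) + [len(group)]
        for run_end in boundaries:
            run_len = run_end - run_start
            for k in range(run_len - L + 1):
                lo = run_start + k
                X_blocks.append(feats[lo : lo + L])
                y_blocks.append(labels[lo])
                meta_rows.append(
                    {"record_id": rid,
                     "segment_index": int(idx[lo + L - 1]),
                     "start_s": float(starts[lo + L - 1]),
                     "label": labels[lo]}
                )
            run_start = run_end
    if not X_blocks:
        warnings.warn(
            f"no homogeneous run of length {L}; dataset is empty",
            stacklevel=2,
        )
        d = len(feature_columns)
        return SequenceDataset(
            X=np.empty((0, L, d)),
            y=np.empty(0, dtype=object),
            feature_names=feature_columns,
            meta=pd.DataFrame(
                columns=["record_id", "segment_index", "start_s", "label"]
            ),
        )
    return SequenceDataset(
        X=np.stack(X_blocks),
        y=np.asarray(y_blocks),
        feature_names=feature_columns,
        meta=pd.DataFrame(meta_rows),
    )
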