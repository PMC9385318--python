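"""Segment- and event-based scoring of preictal predictions.

Segment metrics are the usual confusion-matrix quantities with *preictal*
as the positive class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
Ratios with a zero denominator are returned as None and flagged rather
than silently zeroed.

Event metrics treat each seizure as an independent event: a seizure counts
as *predicted* when at least one segment inside its qualifying window is
classified preictal.  False alarms are maximal runs of consecutive
truly-interictal segments classified preictal; runs separated by less than
a refractory gap (default 300 s) merge into one alarm, reflecting that a
clinical warning stays raised for some minutes.  The false prediction rate
(FPR) normalizes alarm count by the monitored interictal hours.

Class imbalance is handled by partitioning the interictal pool into
disjoint subgroups the size of the preictal pool; models are trained and
scored per subgroup and the reported metrics are subgroup averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import QualifyingWindow
from .types import SeizureAnnotation

POSITIVE_LABEL = "preictal"
NEGATIVE_LABEL = "interictal"


@dataclass
class SegmentMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


@dataclass
class EventReport:
    n_seizures: int
    n_predicted: int
    event_sensitivity: float
    false_alarms: int
    raw_false_positive_segments: int
    monitored_interictal_hours: float
    fpr_per_hour: float | None
    per_seizure_predicted: list[bool] = field(default_factory=list)


def segment_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> SegmentMetrics:
    """Confusion-matrix scores with preictal as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    pos_t = y_true == POSITIVE_LABEL
    pos_p = y_pred == POSITIVE_LABEL
    tp = int(np.sum(pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return SegmentMetrics(tp, tn, fp, fn, sens, spec)


def event_metrics(
    predictions: pd.DataFrame,
    annotations: list[SeizureAnnotation],
    qw: QualifyingWindow,
    refractory_s: float = 300.0,
    segment_s: float = 5.0,
) -> EventReport:
    """Event-based seizure-prediction scoring.

    ``predictions`` needs columns record_id, start_s, label (true label)
    and pred (predicted label) for every scored segment.
    """
    required = {"record_id", "start_s", "label", "pred"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions table needs columns {sorted(required)}")

    per_seizure: list[bool] = []
    for ann in annotations:
        sub = predictions[predictions["record_id"] == ann.record_id]
        s0 = sub["start_s"].to_numpy(dtype=float)
        flagged = (sub["pred"] == POSITIVE_LABEL).to_numpy()
        for onset, _end in ann.intervals:
            w0 = max(0.0, onset - qw.length_s)
            in_window = (s0 >= w0) & (s0 + segment_s <= onset)
            per_seizure.append(bool(np.any(flagged & in_window)))

    n_seiz = len(per_seizure)
    n_pred = int(sum(per_seizure))

    # false alarms: runs of flagged truly-interictal segments, refractory-merged
    false_alarms = 0
    raw_fp = 0
    inter_hours = 0.0
    for rid, sub in predictions.groupby("record_id", sort=False):
        inter = sub[sub["label"] == NEGATIVE_LABEL].sort_values("start_s")
        inter_hours += len(inter) * segment_s / 3600.0
        flagged = inter[inter["pred"] == POSITIVE_LABEL]
        raw_fp += len(flagged)
        starts = flagged["start_s"].to_numpy(dtype=float)
        if starts.size == 0:
            continue
        # cluster flagged segments: contiguous segments (gap == segment_s)
        # are always one run; runs with gaps within the refractory merge
        gaps = np.diff(starts)
        false_alarms += 1 + int(np.sum(gaps > max(refractory_s, segment_s)))
    fpr = false_alarms / inter_hours if inter_hours > 0 else None
    if fpr is None:
        warnings.warn("zero interictal hours: FPR undefined", stacklevel=2)
    return EventReport(
        n_seizures=n_seiz,
        n_predicted=n_pred,
        event_sensitivity=n_pred / n_seiz if n_seiz else float("nan"),
        false_alarms=false_alarms,
        raw_false_positive_segments=raw_fp,
        monitored_interictal_hours=inter_hours,
        fpr_per_hour=fpr,
        per_seizure_predicted=per_seizure,
    )


def balance_interictal(
    labels: np.ndarray, seed: int
) -> list[np.ndarray]:
    """Disjoint interictal index subgroups, each the size of the preictal pool.

    Returns ``floor(Ni/Np)`` randomly drawn disjoint index arrays into
    ``labels``; leftover interictal items are unused.  If the interictal
    pool is *smaller* than the preictal one, the single (unbalanced) full
    interictal index set is returned with a warning.
    """
    labels = np.asarray(labels)
    pre_idx = np.nonzero(labels == POSITIVE_LABEL)[0]
    int_idx = np.nonzero(labels == NEGATIVE_LABEL)[0]
    n_pre = pre_idx.size
    if n_pre == 0:
        raise ValueError("no preictal items: cannot balance")
    if int_idx.size < n_pre:
        warnings.warn(
            f"interictal pool ({int_idx.size}) smaller than preictal "
            f"({n_pre}); returning one unbalanced group",
            stacklevel=2,
        )
        return [int_idx]
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(int_idx)
    n_groups = int_idx.size // n_pre
    return [shuffled[g * n_pre : (g + 1) * n_pre] for g in range(n_groups)]


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test index split over binary labels.

    Note: with overlapping stride-1 sequences a fully random split leaks
    shared segments between train and test; prefer
    :func:`blocked_stratified_split` for honest generalization estimates.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        n_test = int(round(len(idx) * test_fraction))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def blocked_stratified_split(
    meta: pd.DataFrame,
    test_fraction: float,
    seed: int,
    purge: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-blocked stratified split with a purge gap.

    Stride-1 sequences overlap in their underlying segments, so a random
    split leaks: a test sequence can share all but one segment with a
    training sequence.  Here each class's sequences are sorted in time and
    the test set is one contiguous chunk at a seeded random position;
    training sequences within ``purge`` segment indices of any test
    sequence of the same recording (i.e. sharing segments with it) are
    discarded.

    Parameters
    ----------
    meta : DataFrame
        One row per sequence with columns record_id, segment_index (the
        sequence's last segment) and label.
    purge : int
        Segment-index distance below which a train sequence is dropped;
        use ``L - 1`` for sequences of length L.

    Returns positional (train, test) index arrays into ``meta``.
    """
    rng = np.random.default_rng(seed)
    labels = meta["label"].to_numpy()
    test_mask = np.zeros(len(meta), dtype=bool)
    for cls in np.unique(labels):
        pos = np.nonzero(labels == cls)[0]
        sub = meta.iloc[pos].sort_values(["record_id", "segment_index"])
        order = sub.index.to_numpy()  # meta row labels in time order
        n = len(order)
        n_test = int(round(n * test_fraction))
        if n_test == 0:
            continue
        s = int(rng.integers(0, n - n_test + 1))
        test_rows = order[s : s + n_test]
        test_mask[meta.index.get_indexer(test_rows)] = True

    # purge train sequences that share segments with any test sequence
    keep_train = ~test_mask
    if purge > 0:
        for rid, sub in meta.groupby("record_id", sort=False):
            rid_pos = meta.index.get_indexer(sub.index)
            rid_test = test_mask[rid_pos]
            if not rid_test.any():
                continue
            test_idx_sorted = np.sort(
                sub["segment_index"].to_numpy()[rid_test]
            )
            seg_idx = sub["segment_index"].to_numpy()
            ins = np.searchsorted(test_idx_sorted, seg_idx)
            left = np.abs(
                seg_idx - test_idx_sorted[np.clip(ins - 1, 0, None)]
            )
            right = np.abs(
                seg_idx
                - test_idx_sorted[np.clip(ins, None, len(test_idx_sorted) - 1)]
            )
            near = np.minimum(left, right) <= purge
            keep_train[rid_pos[near & ~rid_test]] = False
    train = np.nonzero(keep_train & ~test_mask)[0]
    test = np.nonzero(test_mask)[0]
    return train, test
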