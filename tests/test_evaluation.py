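"""Segment metrics, event-based alarm scoring, interictal balancing."""

import numpy as np
import pandas as pd
import pytest

from preictal.evaluation import (
    balance_interictal,
    event_metrics,
    segment_metrics,
    stratified_split,
)
from preictal.segmentation import QualifyingWindow
from preictal.types import SeizureAnnotation


class TestSegmentMetrics:
    def test_sensitivity_99(self):
        y_true = np.array(["preictal"] * 100)
        y_pred = np.array(["preictal"] * 99 + ["interictal"])
        m = segment_metrics(y_true, y_pred)
        assert (m.tp, m.fn) == (99, 1)
        assert m.sensitivity == pytest.approx(0.99)
        assert m.specificity is None  # no negatives scored

    def test_perfect_classification(self):
        y = np.array(["preictal"] * 10 + ["interictal"] * 20)
        m = segment_metrics(y, y)
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.tp + m.tn + m.fp + m.fn == 30

    def test_all_interictal_flags_undefined_sensitivity(self):
        y_true = np.array(["interictal"] * 10)
        y_pred = np.array(["interictal"] * 8 + ["preictal"] * 2)
        m = segment_metrics(y_true, y_pred)
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_metrics(np.array(["preictal"]), np.array([]))


def _pred_table(rows):
    return pd.DataFrame(rows, columns=["record_id", "start_s", "label",
                                       "pred"])


class TestEventMetrics:
    def test_one_flag_suffices_per_seizure(self):
        """A seizure counts as predicted from a single flagged qualifying
        segment out of 180."""
        rows = []
        for i in range(180):
            start = 2700.0 + 5 * i
            pred = "preictal" if i == 77 else "interictal"
            rows.append(("r", start, "preictal", pred))
        ann = SeizureAnnotation("r", [(3600.0, 3640.0)])
        rep = event_metrics(_pred_table(rows), [ann], QualifyingWindow(15.0))
        assert rep.n_seizures == 1 and rep.n_predicted == 1
        assert rep.event_sensitivity == 1.0

    def test_more_flags_do_not_change_event_sensitivity(self):
        rows_all = [("r", 2700.0 + 5 * i, "preictal", "preictal")
                    for i in range(180)]
        ann = SeizureAnnotation("r", [(3600.0, 3640.0)])
        rep = event_metrics(_pred_table(rows_all), [ann],
                            QualifyingWindow(15.0))
        assert rep.event_sensitivity == 1.0

    def test_unflagged_seizure_missed(self):
        rows = [("r", 2700.0 + 5 * i, "preictal", "interictal")
                for i in range(180)]
        ann = SeizureAnnotation("r", [(3600.0, 3640.0)])
        rep = event_metrics(_pred_table(rows), [ann], QualifyingWindow(15.0))
        assert rep.n_predicted == 0 and rep.event_sensitivity == 0.0

    def test_three_disjoint_runs_in_ten_hours(self):
        """3 alarm runs over 10 interictal hours -> FPR 0.3/h."""
        rows = []
        n = int(10 * 3600 / 5)
        alarm_starts = {1000.0, 15000.0, 30000.0}
        for i in range(n):
            start = 5.0 * i
            pred = "preictal" if start in alarm_starts else "interictal"
            rows.append(("r", start, "interictal", pred))
        rep = event_metrics(_pred_table(rows), [], QualifyingWindow(15.0),
                            refractory_s=300.0)
        assert rep.monitored_interictal_hours == pytest.approx(10.0)
        assert rep.false_alarms == 3
        assert rep.fpr_per_hour == pytest.approx(0.3)

    def test_consecutive_flags_merge_into_one_alarm(self):
        """6 consecutive flagged segments (30 s) with refractory 60 s
        are one alarm, not six; brute-force interval clustering agrees."""
        rows = []
        for i in range(720):
            start = 5.0 * i
            pred = "preictal" if 600.0 <= start < 630.0 else "interictal"
            rows.append(("r", start, "interictal", pred))
        rep = event_metrics(_pred_table(rows), [], QualifyingWindow(15.0),
                            refractory_s=60.0)
        # oracle: cluster flagged starts with gap > 60 s
        starts = sorted(s for (_, s, _, p) in rows if p == "preictal")
        oracle = 1 + sum(b - a > 60.0 for a, b in zip(starts, starts[1:]))
        assert rep.false_alarms == oracle == 1
        assert rep.raw_false_positive_segments == 6

    def test_zero_interictal_hours_fpr_undefined(self):
        rows = [("r", 0.0, "preictal", "preictal")]
        with pytest.warns(UserWarning, match="FPR undefined"):
            rep = event_metrics(_pred_table(rows), [], QualifyingWindow(15.0))
        assert rep.fpr_per_hour is None


class TestBalanceInterictal:
    def test_900_by_180_gives_five_disjoint_groups(self):
        labels = np.array(["interictal"] * 900 + ["preictal"] * 180)
        groups = balance_interictal(labels, seed=0)
        assert len(groups) == 5
        assert all(len(g) == 180 for g in groups)
        flat = np.concatenate(groups)
        assert len(set(flat.tolist())) == 900  # disjoint, covering all
        assert all(labels[i] == "interictal" for i in flat)

    def test_equal_counts_single_full_group(self):
        labels = np.array(["interictal"] * 180 + ["preictal"] * 180)
        groups = balance_interictal(labels, seed=1)
        assert len(groups) == 1 and len(groups[0]) == 180

    def test_fewer_interictal_warns_unbalanced(self):
        labels = np.array(["interictal"] * 100 + ["preictal"] * 180)
        with pytest.warns(UserWarning, match="unbalanced"):
            groups = balance_interictal(labels, seed=2)
        assert len(groups) == 1 and len(groups[0]) == 100

    def test_zero_preictal_rejected(self):
        with pytest.raises(ValueError):
            balance_interictal(np.array(["interictal"] * 10), seed=0)

    def test_remainder_unused(self):
        labels = np.array(["interictal"] * 1000 + ["preictal"] * 180)
        groups = balance_interictal(labels, seed=3)
        assert len(groups) == 5
        assert sum(len(g) for g in groups) == 900  # 100 unused

    def test_seeded_partition_reproducible(self):
        labels = np.array(["interictal"] * 360 + ["preictal"] * 120)
        g1 = balance_interictal(labels, seed=9)
        g2 = balance_interictal(labels, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(g1, g2))


class TestStratifiedSplit:
    def test_split_preserves_class_fractions(self):
        labels = np.array(["preictal"] * 50 + ["interictal"] * 50)
        train, test = stratified_split(labels, 0.2, seed=0)
        assert len(test) == 20 and len(train) == 80
        assert (labels[test] == "preictal").sum() == 10
        assert set(train) | set(test) == set(range(100))
        assert not set(train) & set(test)


def test_averaged_equals_pooled_specificity_for_equal_groups():
    """With equal per-subgroup test sizes the subgroup-averaged specificity
    equals the pooled value."""
    rng = np.random.default_rng(0)
    specs, tns, fps = [], [], []
    for _ in range(5):
        y_true = np.array(["interictal"] * 40 + ["preictal"] * 40)
        y_pred = np.where(rng.random(80) < 0.1,
                          "preictal", y_true)
        m = segment_metrics(y_true, y_pred)
        specs.append(m.specificity)
        tns.append(m.tn)
        fps.append(m.fp)
    pooled = sum(tns) / (sum(tns) + sum(fps))
    assert np.mean(specs) == pytest.approx(pooled, abs=1e-12)
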