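"""Evaluation: confusion metrics, error taxonomy, bout matching, agreement."""

import numpy as np
import pytest
from scipy import stats

import scratchdetect as sd
from scratchdetect.evaluation import (ConfusionMatrix, classify_errors,
                                      confusion, match_bouts, metrics,
                                      round_pct)
from scratchdetect.inference import Bout, BoutTable, PredictionTrack


def _tracks(pred, labels):
    pred = np.asarray(pred, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    return (PredictionTrack(np.where(pred, 0.9, 0.1), pred),
            sd.LabelTrack(labels))


class TestConfusion:
    def test_perfect_prediction(self, rng):
        lab = (rng.random(100) > 0.7).astype(np.uint8)
        pred, labels = _tracks(lab, lab)
        cm = confusion(pred, labels)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == lab.sum() and cm.tn == 100 - lab.sum()

    def test_all_zero_everything(self):
        pred, labels = _tracks([0] * 50, [0] * 50)
        cm = confusion(pred, labels)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 0, 50)

    def test_counts_partition_track(self, rng):
        p = (rng.random(300) > 0.8).astype(np.uint8)
        l = (rng.random(300) > 0.8).astype(np.uint8)
        cm = confusion(*_tracks(p, l))
        assert cm.total == 300

    def test_unscored_frames_excluded(self):
        scores = np.array([np.nan, 0.9, 0.1, np.nan])
        calls = np.array([0, 1, 0, 0], dtype=np.uint8)
        track = PredictionTrack(scores, calls)
        cm = confusion(track, sd.LabelTrack(np.array([1, 1, 0, 0])))
        assert cm.total == 2
        assert cm.tp == 1 and cm.tn == 1

    def test_length_mismatch_rejected(self):
        pred, _ = _tracks([0, 1], [0, 1])
        with pytest.raises(ValueError, match="mismatch"):
            confusion(pred, sd.LabelTrack(np.array([0, 1, 0])))


class TestMetrics:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)

    def test_perfect_matrix(self):
        m = metrics(ConfusionMatrix(tp=50, fp=0, fn=0, tn=950))
        r = m.rounded()
        assert r["sensitivity"] == 100.0 and r["specificity"] == 100.0
        assert r["ppv"] == 100.0 and r["npv"] == 100.0
        assert r["error_rate"] == 0.0

    def test_undefined_metric_is_none_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None   # no positive labels
        assert m.ppv is None           # no positive calls
        assert m.specificity == 100.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    @pytest.mark.parametrize("x,expected", [
        (0.25, 0.3), (15.75, 15.8), (93.54, 93.5), (99.94999, 99.9),
        (84.0, 84.0),
    ])
    def test_percentages_round_half_up(self, x, expected):
        assert round_pct(x) == expected


class TestClassifyErrors:
    def test_pure_shift_is_boundary_only(self):
        """A 20-frame bout predicted 3 frames late: 3 missed at the start
        plus 3 spurious at the end, all boundary."""
        labels = np.zeros(60, dtype=np.uint8)
        labels[10:30] = 1
        pred = np.zeros(60, dtype=np.uint8)
        pred[13:33] = 1
        eb = classify_errors(*_tracks(pred, labels))
        assert (eb.boundary, eb.false_detection, eb.oversight) == (6, 0, 0)

    def test_isolated_prediction_is_false_detection(self):
        labels = np.zeros(60, dtype=np.uint8)
        pred = np.zeros(60, dtype=np.uint8)
        pred[20:32] = 1
        eb = classify_errors(*_tracks(pred, labels))
        assert (eb.boundary, eb.false_detection, eb.oversight) == (0, 12, 0)

    def test_missed_bout_is_oversight(self):
        labels = np.zeros(60, dtype=np.uint8)
        labels[20:35] = 1
        pred = np.zeros(60, dtype=np.uint8)
        eb = classify_errors(*_tracks(pred, labels))
        assert (eb.boundary, eb.false_detection, eb.oversight) == (0, 0, 15)

    def test_split_bout_interior_gap_is_boundary(self):
        labels = np.zeros(60, dtype=np.uint8)
        labels[10:40] = 1
        pred = labels.copy()
        pred[20:25] = 0  # detector briefly drops out mid-bout
        eb = classify_errors(*_tracks(pred, labels))
        assert (eb.boundary, eb.false_detection, eb.oversight) == (5, 0, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_identity_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        pred = (rng.random(n) > 0.7).astype(np.uint8)
        labels = (rng.random(n) > 0.7).astype(np.uint8)
        cm = confusion(*_tracks(pred, labels))
        eb = classify_errors(*_tracks(pred, labels))
        assert eb.total == cm.fp + cm.fn


class TestMatchBouts:
    def test_split_bout_durations_sum(self):
        """One human bout predicted as two: predicted duration adds up."""
        human = BoutTable([Bout(100, 160, 1.0)], fps=60)
        pred = BoutTable([Bout(100, 120, 20 / 60), Bout(130, 160, 30 / 60)],
                         fps=60)
        per_human, unassigned = match_bouts(pred, human)
        assert per_human[0] == pytest.approx(50 / 60)
        assert unassigned == []

    def test_non_overlapping_prediction_unassigned(self):
        human = BoutTable([Bout(0, 30, 0.5)], fps=60)
        pred = BoutTable([Bout(100, 120, 20 / 60)], fps=60)
        per_human, unassigned = match_bouts(pred, human)
        assert per_human[0] == 0
        assert len(unassigned) == 1

    def test_identical_tables_match_exactly(self):
        bouts = [Bout(0, 30, 0.5), Bout(50, 80, 0.5)]
        table = BoutTable(bouts, fps=60)
        per_human, unassigned = match_bouts(table, table)
        assert np.allclose(per_human, [0.5, 0.5])
        assert unassigned == []


class TestAgreement:
    def _table(self, counts_durations, fps=60):
        bouts, pos = [], 0
        for dur_frames in counts_durations:
            bouts.append(Bout(pos, pos + dur_frames, dur_frames / fps))
            pos += dur_frames + 20
        return BoutTable(bouts, fps)

    def test_identical_vectors_give_r_one(self):
        pairs = [(self._table([30] * k), self._table([30] * k))
                 for k in (1, 2, 3)]
        rep = sd.agreement(pairs)
        assert rep.r_bouts == pytest.approx(1.0)
        assert rep.r_durations == pytest.approx(1.0)

    def test_anti_ordered_vectors_give_r_minus_one(self):
        human = [self._table([30] * k) for k in (1, 2, 3)]
        pred = [self._table([30] * k) for k in (3, 2, 1)]
        rep = sd.agreement(list(zip(human, pred)))
        assert rep.r_bouts == pytest.approx(-1.0)

    def test_pearson_matches_closed_form(self):
        """r for x=(1,2,3,4), y=(2,4,5,9), computed from the definition:
        r = sum(dx*dy) / sqrt(sum(dx^2) * sum(dy^2)) = 11/sqrt(5*26)."""
        human = [self._table([30] * k) for k in (1, 2, 3, 4)]
        pred = [self._table([30] * k) for k in (2, 4, 5, 9)]
        rep = sd.agreement(list(zip(human, pred)))
        expected = 11 / np.sqrt(5 * 26)
        assert rep.r_bouts == pytest.approx(expected, abs=1e-9)
        assert rep.r_bouts == pytest.approx(
            stats.pearsonr([1, 2, 3, 4], [2, 4, 5, 9]).statistic)

    def test_degenerate_variance_reported_undefined(self):
        pairs = [(self._table([30]), self._table([30, 30])),
                 (self._table([30]), self._table([30, 30, 30]))]
        rep = sd.agreement(pairs)
        assert rep.r_bouts is None  # human counts constant


class TestFilterInteraction:
    @pytest.mark.parametrize("seed", range(10))
    def test_posterior_filter_never_adds_false_detections(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        labels = np.zeros(n, dtype=np.uint8)
        for s in rng.integers(0, n - 30, size=3):
            labels[s:s + 20] = 1
        pred = labels.copy()
        flip = rng.random(n) < 0.05
        pred[flip] ^= 1
        track, lab = _tracks(pred, labels)
        before = classify_errors(track, lab).false_detection
        filtered = sd.posterior_filter(track, 10)
        after = classify_errors(filtered, lab).false_detection
        assert after <= before
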