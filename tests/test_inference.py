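"""Prediction tracks, run-length encoding, the posterior filter, bouts.

The filter and RLE invariants are verified exhaustively against brute
force over every binary track of length <= 12.
"""

import itertools

import numpy as np
import pytest

import scratchdetect as sd
from scratchdetect.inference import (Bout, BoutTable, PredictionTrack,
                                     bouts_from_track, posterior_filter,
                                     run_length_encode)


def brute_force_filter(calls, min_run):
    """Reference posterior filter: literal scan over maximal 1-runs."""
    calls = list(calls)
    out = calls[:]
    i = 0
    while i < len(calls):
        if calls[i] == 1:
            j = i
            while j < len(calls) and calls[j] == 1:
                j += 1
            if j - i < min_run:
                for t in range(i, j):
                    out[t] = 0
            i = j
        else:
            i += 1
    return out


def all_binary_tracks(max_len):
    for n in range(max_len + 1):
        for bits in itertools.product((0, 1), repeat=n):
            yield np.array(bits, dtype=np.uint8)


def _track(calls):
    calls = np.asarray(calls, dtype=np.uint8)
    return PredictionTrack(np.where(calls, 0.9, 0.1), calls)


class TestRunLengthEncode:
    @pytest.mark.parametrize("calls,expected", [
        ([0, 0, 0], [(0, 0, 3)]),
        ([0, 1, 1, 0], [(0, 0, 1), (1, 1, 2), (0, 3, 1)]),
        ([1], [(1, 0, 1)]),
        ([], []),
    ])
    def test_examples(self, calls, expected):
        assert run_length_encode(calls) == expected

    def test_reconstruction_identity_exhaustive(self):
        for track in all_binary_tracks(12):
            rle = run_length_encode(track)
            rebuilt = np.concatenate(
                [np.full(ln, v, dtype=np.uint8) for v, s, ln in rle]
            ) if rle else np.array([], dtype=np.uint8)
            assert np.array_equal(rebuilt, track)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            run_length_encode([0, 2, 1])


class TestPosteriorFilter:
    def test_nine_frame_run_removed(self):
        calls = [0] + [1] * 9 + [0]
        out = posterior_filter(_track(calls), min_run=10)
        assert out.calls.sum() == 0
        assert out.filtered

    def test_ten_frame_run_survives(self):
        calls = [0] + [1] * 10 + [0]
        out = posterior_filter(_track(calls), min_run=10)
        assert out.calls.sum() == 10

    def test_scores_kept_for_audit(self):
        track = _track([0, 1, 1, 0])
        out = posterior_filter(track, min_run=10)
        assert np.array_equal(out.scores, track.scores)
        assert out.calls.sum() == 0

    def test_invalid_min_run_rejected(self):
        with pytest.raises(ValueError):
            posterior_filter(_track([0, 1]), min_run=0)

    def test_filter_properties_exhaustive(self):
        """Idempotence, 1-count monotonicity, no short survivor, and bout
        count never increases -- against brute force, all tracks len<=12."""
        for calls in all_binary_tracks(12):
            track = _track(calls)
            once = posterior_filter(track, min_run=10)
            assert once.calls.tolist() == brute_force_filter(calls, 10)
            twice = posterior_filter(once, min_run=10)
            assert np.array_equal(twice.calls, once.calls)
            assert once.calls.sum() <= calls.sum()
            surviving = [ln for v, _, ln in run_length_encode(once.calls)
                         if v == 1]
            assert all(ln >= 10 for ln in surviving)
            n_before = sum(1 for v, _, _ in run_length_encode(calls) if v == 1)
            assert len(surviving) <= n_before
            # zeros are never touched
            assert not np.any((once.calls == 1) & (calls == 0))


class TestBouts:
    def test_all_zero_track_gives_empty_table(self):
        table = bouts_from_track(_track([0] * 20), fps=60)
        assert len(table) == 0
        assert table.total_duration_s == 0

    def test_durations_from_run_lengths(self):
        calls = [0] + [1] * 12 + [0] + [1] * 30 + [0]
        table = bouts_from_track(_track(calls), fps=60)
        assert len(table) == 2
        assert table.bouts[0].duration_s == pytest.approx(0.2)
        assert table.bouts[1].duration_s == pytest.approx(0.5)
        assert table.bouts[0].n_frames == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_total_duration_conserves_one_count(self, seed):
        rng = np.random.default_rng(seed)
        calls = (rng.random(200) > 0.6).astype(np.uint8)
        table = bouts_from_track(_track(calls), fps=60)
        assert table.total_duration_s == pytest.approx(calls.sum() / 60)
        n_runs = sum(1 for v, _, _ in run_length_encode(calls) if v == 1)
        assert len(table) == n_runs

    def test_bad_fps_rejected(self):
        with pytest.raises(ValueError):
            bouts_from_track(_track([0, 1]), fps=0)

    def test_bout_table_ordering_enforced(self):
        with pytest.raises(ValueError):
            BoutTable([Bout(10, 20, 1.0), Bout(5, 8, 0.5)], fps=60)


class TestPredictTrack:
    class _StubModel:
        """Duck-typed model with a fixed score sequence."""

        def __init__(self, spec, scores):
            self.spec = spec
            self._scores = scores

        def score(self, stacks, batch_size=64):
            return np.asarray(self._scores[:len(stacks)], dtype=np.float64)

    @pytest.fixture
    def frames22(self, rendered_video):
        seq, _ = rendered_video
        return sd.FrameSequence(seq.frames[:22], fps=60)

    def test_minimal_video_scores_exactly_center_frame(self, frames22,
                                                       small_pre_config):
        spec = sd.CRNNSpec.small()
        model = self._StubModel(spec, [0.8])
        track = sd.predict_track(model, frames22, small_pre_config)
        assert track.scored_mask.sum() == 1
        assert track.scored_mask[10]
        assert track.calls[10] == 1 and track.calls.sum() == 1

    def test_threshold_is_strict(self, frames22, small_pre_config):
        spec = sd.CRNNSpec.small()
        model = self._StubModel(spec, [0.5])
        track = sd.predict_track(model, frames22, small_pre_config)
        assert track.calls.sum() == 0  # score == 0.5 is not scratching

    def test_edge_frames_unscored_and_zero(self, frames22, small_pre_config):
        spec = sd.CRNNSpec.small()
        model = self._StubModel(spec, [0.9])
        track = sd.predict_track(model, frames22, small_pre_config)
        assert np.isnan(track.scores[:10]).all()
        assert np.isnan(track.scores[11:]).all()
        assert track.calls[:10].sum() == 0 and track.calls[11:].sum() == 0

    def test_mismatched_config_rejected(self, frames22):
        spec = sd.CRNNSpec.small()
        model = self._StubModel(spec, [0.9])
        with pytest.raises(ValueError, match="match"):
            sd.predict_track(model, frames22,
                             sd.PreprocessConfig(out_size=32))
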