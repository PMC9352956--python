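"""Per-frame prediction, the run-length posterior filter, and bout tables.

A trained model scores every frame that has full segment context; a frame
is called scratching when its score is strictly above the threshold
(default 0.5).  Edge frames without the full window are left unscored and
called 0.  The posterior filter deletes predicted runs of fewer than
``min_run`` consecutive frames (default 10, i.e. runs of nine or fewer
frames are removed) — scratching this brief is biologically implausible at
60 Hz and such runs are dominated by walk/groom false detections.  A bout
is a maximal surviving run; its duration is run length over fps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import CRNNModel
from .preprocess import PreprocessConfig, build_segments
from .video_io import FrameSequence

__all__ = ["PredictionTrack", "Bout", "BoutTable", "predict_track",
           "run_length_encode", "posterior_filter", "bouts_from_track"]


@dataclass
class PredictionTrack:
    """Per-frame scores (NaN where unscored) and binary calls."""

    scores: np.ndarray
    calls: np.ndarray
    threshold: float = 0.5
    filtered: bool = False
    source_id: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.scores.shape != self.calls.shape or self.scores.ndim != 1:
            raise ValueError("scores and calls must be equal-length 1-D")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be 0 or 1")

    def __len__(self):
        return len(self.calls)

    @property
    def scored_mask(self) -> np.ndarray:
        return ~np.isnan(self.scores)


@dataclass(frozen=True)
class Bout:
    start: int            # inclusive frame
    end: int              # exclusive frame
    duration_s: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("bout end must exceed start")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class BoutTable:
    bouts: list[Bout]
    fps: float
    source_id: str = ""

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        prev_end = -1
        for b in self.bouts:
            if b.start <= prev_end:
                raise ValueError("bouts must be sorted with >= 1 frame gaps")
            prev_end = b.end

    def __len__(self):
        return len(self.bouts)

    @property
    def total_duration_s(self) -> float:
        return sum(b.duration_s for b in self.bouts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start": b.start, "end": b.end, "n_frames": b.n_frames,
              "duration_s": b.duration_s} for b in self.bouts],
            columns=["start", "end", "n_frames", "duration_s"])


def predict_track(model: CRNNModel, frames: FrameSequence,
                  pre_cfg: PreprocessConfig | None = None,
                  threshold: float = 0.5,
                  batch_size: int = 64) -> PredictionTrack:
    """Score every segment-coverable frame of a video.

    Calls use strict ``score > threshold``; frames within ``half_window`` of
    either end (no full 21-frame context) stay NaN-scored with call 0.
    """
    if pre_cfg is None:
        pre_cfg = PreprocessConfig(out_size=model.spec.input_size)
    if pre_cfg.seq_len != model.spec.seq_len or \
            pre_cfg.out_size != model.spec.input_size:
        raise ValueError(
            f"preprocess config (seq_len={pre_cfg.seq_len}, "
            f"out_size={pre_cfg.out_size}) does not match model spec "
            f"(seq_len={model.spec.seq_len}, input={model.spec.input_size})")
    dataset = build_segments(frames, None, pre_cfg)
    scores = np.full(len(frames), np.nan)
    scores[dataset.centers] = model.score(dataset.stacks,
                                          batch_size=batch_size)
    calls = np.zeros(len(frames), dtype=np.uint8)
    calls[dataset.centers] = scores[dataset.centers] > threshold
    return PredictionTrack(scores, calls, threshold=threshold,
                           source_id=frames.source_id)


def run_length_encode(calls) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a binary track as (value, start, length)."""
    calls = np.asarray(calls).astype(np.int64)
    if calls.ndim != 1:
        raise ValueError("calls must be 1-D")
    if len(calls) == 0:
        return []
    if not np.isin(calls, (0, 1)).all():
        raise ValueError("calls must be 0 or 1")
    breaks = np.flatnonzero(np.diff(calls)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(calls)]])
    return [(int(calls[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def posterior_filter(track: PredictionTrack,
                     min_run: int = 10) -> PredictionTrack:
    """Remove predicted runs shorter than ``min_run`` frames.

    At the default, runs of nine or fewer consecutive 1-calls are set to 0;
    runs of ten or more pass unchanged and 0-calls are never touched, so
    the operation is idempotent.  Scores are kept unmodified for audit.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    calls = track.calls.copy()
    for value, start, length in run_length_encode(calls):
        if value == 1 and length < min_run:
            calls[start:start + length] = 0
    return replace(track, scores=track.scores.copy(), calls=calls,
                   filtered=True)


def bouts_from_track(track, fps: float | None = None,
                     source_id: str | None = None) -> BoutTable:
    """One bout per maximal run of 1s; duration is run length / fps.

    Accepts a PredictionTrack, a LabelTrack, or a raw binary array.
    """
    if hasattr(track, "calls"):
        calls, sid = track.calls, track.source_id
    elif hasattr(track, "labels"):
        calls, sid = track.labels, track.source_id
    else:
        calls, sid = np.asarray(track), ""
    if fps is None or fps <= 0:
        raise ValueError("a positive fps is required")
    bouts = [Bout(start, start + length, length / fps)
             for value, start, length in run_length_encode(calls)
             if value == 1]
    return BoutTable(bouts, fps, source_id=source_id or sid)
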