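"""Prediction-vs-label evaluation: frame confusion metrics, the three-way
error taxonomy, bout matching, and per-video agreement.

Mispredicted frames fall into three categories.  A maximal run of
false-positive frames is a *false detection* when its enclosing predicted
run overlaps no human-labeled bout, else a *boundary error* (a shifted
start/end of an otherwise detected bout).  A maximal run of false-negative
frames is an *oversight* when its enclosing labeled bout overlaps no
predicted run, else a boundary error.  The three counts partition fp + fn
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .inference import BoutTable, PredictionTrack, run_length_encode
from .video_io import LabelTrack

log = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "MetricSet", "ErrorBreakdown",
           "AgreementReport", "confusion", "metrics", "classify_errors",
           "match_bouts", "agreement", "round_pct"]


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round-half-up to one decimal, the convention used for reporting
    percentages (e.g. 0.25 -> 0.3, 15.75 -> 15.8)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Percentages on [0, 100]; None where the denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    error_rate: float

    def rounded(self) -> dict[str, float | None]:
        return {k: (None if v is None else round_pct(v))
                for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class ErrorBreakdown:
    boundary: int
    false_detection: int
    oversight: int

    @property
    def total(self) -> int:
        return self.boundary + self.false_detection + self.oversight


@dataclass(frozen=True)
class AgreementReport:
    human_bout_counts: tuple[int, ...]
    pred_bout_counts: tuple[int, ...]
    human_durations_s: tuple[float, ...]
    pred_durations_s: tuple[float, ...]
    r_bouts: float | None
    r_durations: float | None


def _calls_and_mask(pred) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, PredictionTrack):
        return pred.calls, pred.scored_mask
    calls = np.asarray(pred.labels if hasattr(pred, "labels") else pred)
    return calls, np.ones(len(calls), dtype=bool)


def confusion(pred, labels) -> ConfusionMatrix:
    """Frame-level confusion counts; unscored frames are excluded."""
    calls, mask = _calls_and_mask(pred)
    lab = labels.labels if isinstance(labels, LabelTrack) else np.asarray(labels)
    if len(calls) != len(lab):
        raise ValueError(f"length mismatch: {len(calls)} calls vs "
                         f"{len(lab)} labels")
    n_excluded = int((~mask).sum())
    if n_excluded:
        log.info("excluding %d unscored edge frames from confusion counts",
                 n_excluded)
    c = calls[mask].astype(bool)
    l = lab[mask].astype(bool)
    return ConfusionMatrix(tp=int((c & l).sum()), fp=int((c & ~l).sum()),
                           fn=int((~c & l).sum()), tn=int((~c & ~l).sum()))


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Standard screening metrics as percentages.

    sensitivity = 100*tp/(tp+fn), specificity = 100*tn/(tn+fp),
    ppv = 100*tp/(tp+fp), npv = 100*tn/(tn+fn),
    error_rate = 100*(fp+fn)/total.  A metric with a zero denominator is
    None (undefined), never 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return None if den == 0 else 100.0 * num / den

    return MetricSet(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        error_rate=100.0 * (cm.fp + cm.fn) / cm.total,
    )


def _one_runs(x: np.ndarray) -> list[tuple[int, int]]:
    return [(s, s + ln) for v, s, ln in run_length_encode(x) if v == 1]


def _overlaps(a: tuple[int, int], runs: list[tuple[int, int]]) -> bool:
    return any(min(a[1], e) > max(a[0], s) for s, e in runs)


def _enclosing(frame: int, runs: list[tuple[int, int]]) -> tuple[int, int]:
    for s, e in runs:
        if s <= frame < e:
            return (s, e)
    raise AssertionError("run bookkeeping violated")


def classify_errors(pred, labels) -> ErrorBreakdown:
    """Partition mispredicted frames into boundary / false detection /
    oversight (see module docstring for the overlap rules)."""
    calls, _ = _calls_and_mask(pred)
    lab = labels.labels if isinstance(labels, LabelTrack) else np.asarray(labels)
    if len(calls) != len(lab):
        raise ValueError("length mismatch between predictions and labels")
    calls = calls.astype(bool)
    lab = lab.astype(bool)
    pred_runs = _one_runs(calls.astype(np.uint8))
    label_runs = _one_runs(lab.astype(np.uint8))

    boundary = false_detection = oversight = 0
    for s, e in _one_runs((calls & ~lab).astype(np.uint8)):  # FP runs
        enclosing = _enclosing(s, pred_runs)
        if _overlaps(enclosing, label_runs):
            boundary += e - s
        else:
            false_detection += e - s
    for s, e in _one_runs((~calls & lab).astype(np.uint8)):  # FN runs
        enclosing = _enclosing(s, label_runs)
        if _overlaps(enclosing, pred_runs):
            boundary += e - s
        else:
            oversight += e - s
    return ErrorBreakdown(boundary, false_detection, oversight)


def match_bouts(pred_bouts: BoutTable, human_bouts: BoutTable):
    """Assign each predicted bout to the human bout with maximal frame
    overlap; a human bout split into several predictions gets the summed
    predicted duration.

    Returns (per_human_duration_s, unassigned) where ``per_human_duration_s``
    has one entry per human bout and ``unassigned`` lists predicted bouts
    overlapping no human bout.
    """
    per_human = np.zeros(len(human_bouts), dtype=np.float64)
    unassigned = []
    for pb in pred_bouts.bouts:
        overlaps = [max(0, min(pb.end, hb.end) - max(pb.start, hb.start))
                    for hb in human_bouts.bouts]
        if overlaps and max(overlaps) > 0:
            per_human[int(np.argmax(overlaps))] += pb.duration_s
        else:
            unassigned.append(pb)
    return per_human, unassigned


def agreement(per_video_pairs) -> AgreementReport:
    """Pearson correlation of bout counts and of total durations across
    videos.

    ``per_video_pairs`` is an iterable of (human_bouts, pred_bouts)
    BoutTable pairs.  With fewer than 2 videos or zero variance in either
    vector the corresponding r is None (undefined).
    """
    pairs = list(per_video_pairs)
    hc = [len(h) for h, _ in pairs]
    pc = [len(p) for _, p in pairs]
    hd = [h.total_duration_s for h, _ in pairs]
    pd_ = [p.total_duration_s for _, p in pairs]

    def pearson(x, y):
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            log.warning("degenerate agreement vectors; r undefined")
            return None
        return float(stats.pearsonr(x, y).statistic)

    return AgreementReport(tuple(hc), tuple(pc), tuple(hd), tuple(pd_),
                           r_bouts=pearson(hc, pc),
                           r_durations=pearson(hd, pd_))
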