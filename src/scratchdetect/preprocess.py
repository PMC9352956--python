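"""Frame sequences -> 21-frame binarized motion segments.

Pipeline per difference index k (frames k and k+1): absolute successive
difference, square crop around the body centroid of frame k, binarize with
a strict ``> threshold`` test (default 15), nearest-neighbor resize to
``out_size`` (default 200) so the output stays binary.  The segment centered
at frame t stacks the processed differences d_{t-10}..d_{t+10} and inherits
the label of frame t.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .video_io import FrameSequence, LabelTrack

log = logging.getLogger(__name__)

__all__ = ["PreprocessConfig", "Segment", "SegmentDataset", "body_centroid",
           "diff_binarize", "crop_resize", "build_segments"]


@dataclass(frozen=True)
class PreprocessConfig:
    binarize_threshold: int = 15      # gray levels, strict >
    out_size: int = 200               # segment image side, px
    crop_side: int | None = None      # pre-resize crop side, px
    expected_body_diameter: float | None = None  # used when crop_side is None
    fg_threshold: int = 100           # body pixels are darker than this
    half_window: int = 10             # segment spans t-h..t+h

    def __post_init__(self):
        if not 0 < self.binarize_threshold < 255:
            raise ValueError("binarize_threshold must be in (0, 255)")
        if self.out_size <= 0:
            raise ValueError("out_size must be positive")
        if self.crop_side is not None and self.crop_side <= 0:
            raise ValueError("crop_side must be positive")
        if self.half_window < 0:
            raise ValueError("half_window must be >= 0")

    @property
    def seq_len(self) -> int:
        return 2 * self.half_window + 1

    def resolve_crop_side(self, first_frame: np.ndarray) -> int:
        """Crop side: explicit, else 1.5x the expected body diameter,
        else 1.5x a diameter estimated from the dark-pixel area of the
        first frame (equivalent-circle diameter)."""
        if self.crop_side is not None:
            return self.crop_side
        if self.expected_body_diameter is not None:
            return max(1, int(round(1.5 * self.expected_body_diameter)))
        area = int((first_frame < self.fg_threshold).sum())
        if area == 0:
            side = min(first_frame.shape)
            log.warning("no dark body pixels in first frame; "
                        "falling back to crop_side=%d", side)
            return side
        diameter = 2.0 * np.sqrt(area / np.pi)
        return max(1, int(round(1.5 * diameter)))


@dataclass
class Segment:
    stack: np.ndarray          # (2h+1, S, S) values in {0, 1}
    center_frame: int
    label: int | None = None   # 1 scratch, 0 other, None unknown
    source_id: str = ""


class SegmentDataset:
    """Array-backed collection of segments with shared provenance.

    ``stacks`` is (n, 2h+1, S, S) uint8 in {0, 1}; ``labels`` uses -1 for
    unknown.  Supports concatenation across videos and a compressed
    npz + JSON-manifest archive format.
    """

    def __init__(self, stacks: np.ndarray, centers: np.ndarray,
                 labels: np.ndarray | None, source_ids, provenance: dict):
        self.stacks = np.asarray(stacks, dtype=np.uint8)
        self.centers = np.asarray(centers, dtype=np.int64)
        n = len(self.stacks)
        if labels is None:
            labels = np.full(n, -1)
        self.labels = np.asarray(labels, dtype=np.int8)
        if isinstance(source_ids, str):
            source_ids = [source_ids] * n
        self.source_ids = np.asarray(source_ids, dtype=object)
        self.provenance = dict(provenance)
        if not (len(self.centers) == len(self.labels)
                == len(self.source_ids) == n):
            raise ValueError("inconsistent dataset field lengths")
        if self.stacks.ndim != 4:
            raise ValueError("stacks must be (n, seq_len, S, S)")

    def __len__(self):
        return len(self.stacks)

    def __getitem__(self, i: int) -> Segment:
        lab = int(self.labels[i])
        return Segment(self.stacks[i], int(self.centers[i]),
                       None if lab < 0 else lab, str(self.source_ids[i]))

    @property
    def scratch_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @classmethod
    def concatenate(cls, datasets: list["SegmentDataset"]) -> "SegmentDataset":
        if not datasets:
            raise ValueError("nothing to concatenate")
        prov = {}
        for d in datasets:
            prov.update(d.provenance)
        return cls(np.concatenate([d.stacks for d in datasets]),
                   np.concatenate([d.centers for d in datasets]),
                   np.concatenate([d.labels for d in datasets]),
                   np.concatenate([d.source_ids for d in datasets]),
                   prov)

    def save(self, path) -> Path:
        path = Path(path)
        manifest = {"provenance": self.provenance,
                    "source_ids": [str(s) for s in self.source_ids]}
        np.savez_compressed(
            path, stacks=np.packbits(self.stacks, axis=-1),
            stack_shape=np.array(self.stacks.shape),
            centers=self.centers, labels=self.labels,
            manifest=np.frombuffer(json.dumps(manifest).encode(), np.uint8))
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz")

    @classmethod
    def load(cls, path) -> "SegmentDataset":
        with np.load(path, allow_pickle=False) as z:
            shape = tuple(z["stack_shape"])
            stacks = np.unpackbits(
                z["stacks"], axis=-1, count=shape[-1]).reshape(shape)
            manifest = json.loads(bytes(z["manifest"]).decode())
            return cls(stacks, z["centers"], z["labels"],
                       manifest["source_ids"], manifest["provenance"])


def body_centroid(frame: np.ndarray, fg_threshold: int = 100) -> tuple[float, float]:
    """Centroid (row, col) of dark body pixels (< fg_threshold).

    Falls back to the image center, with a warning, when no pixel qualifies.
    """
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D grayscale")
    rows, cols = np.nonzero(frame < fg_threshold)
    if len(rows) == 0:
        log.warning("no foreground pixels below %d; using image center",
                    fg_threshold)
        return ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)
    return (float(rows.mean()), float(cols.mean()))


def diff_binarize(frame_t: np.ndarray, frame_t1: np.ndarray,
                  threshold: int = 15) -> np.ndarray:
    """Binary motion image: 1 where |frame_t1 - frame_t| > threshold."""
    if frame_t.shape != frame_t1.shape:
        raise ValueError(f"shape mismatch {frame_t.shape} vs {frame_t1.shape}")
    diff = np.abs(frame_t1.astype(np.int16) - frame_t.astype(np.int16))
    return (diff > threshold).astype(np.uint8)


def crop_resize(img: np.ndarray, center: tuple[float, float],
                crop_side: int, out_size: int) -> np.ndarray:
    """Square crop centered on ``center`` (zero-padded at image borders),
    nearest-neighbor resized to ``out_size`` so binary inputs stay binary."""
    if crop_side <= 0 or out_size <= 0:
        raise ValueError("crop_side and out_size must be positive")
    r0 = int(round(center[0])) - crop_side // 2
    c0 = int(round(center[1])) - crop_side // 2
    # nearest-neighbor source index for each output pixel
    src = (np.arange(out_size) * crop_side) // out_size
    rows = r0 + src
    cols = c0 + src
    valid_r = (rows >= 0) & (rows < img.shape[0])
    valid_c = (cols >= 0) & (cols < img.shape[1])
    out = np.zeros((out_size, out_size), dtype=img.dtype)
    rr = rows[valid_r][:, None]
    cc = cols[valid_c][None, :]
    out[np.ix_(valid_r, valid_c)] = img[rr, cc]
    return out


def build_segments(frames: FrameSequence, labels: LabelTrack | None,
                   config: PreprocessConfig) -> SegmentDataset:
    """Preprocess a frame sequence into labeled motion segments.

    Difference d_k pairs frames k and k+1 and is cropped at the body
    centroid of frame k; the segment centered at t stacks d_{t-h}..d_{t+h},
    so centers range over [h, N-2-h].
    """
    n = len(frames)
    h = config.half_window
    min_frames = 2 * h + 2
    if n < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames for half_window={h}, got {n}")
    if labels is not None and len(labels) != n:
        raise ValueError("label track length does not match frame count")
    crop_side = config.resolve_crop_side(frames.frames[0])

    proc = np.empty((n - 1, config.out_size, config.out_size), dtype=np.uint8)
    for k in range(n - 1):
        center = body_centroid(frames.frames[k], config.fg_threshold)
        diff = np.abs(frames.frames[k + 1].astype(np.int16)
                      - frames.frames[k].astype(np.int16))
        win = crop_resize(diff, center, crop_side, config.out_size)
        proc[k] = win > config.binarize_threshold

    centers = np.arange(h, n - 1 - h)
    stacks = np.lib.stride_tricks.sliding_window_view(
        proc, 2 * h + 1, axis=0)  # (n-1-2h, S, S, 2h+1)
    stacks = np.ascontiguousarray(stacks.transpose(0, 3, 1, 2))
    seg_labels = labels.labels[centers].astype(np.int8) if labels is not None \
        else None
    provenance = {frames.source_id: {**asdict(config),
                                     "crop_side_resolved": crop_side}}
    return SegmentDataset(stacks, centers, seg_labels, frames.source_id,
                          provenance)
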