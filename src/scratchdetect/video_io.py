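"""Frame-sequence and per-frame track I/O.

Frames live in memory as a single ``(N, H, W)`` uint8 array.  On disk the
lossless interchange format is a directory of zero-padded numbered PNGs;
video containers are attempted through imageio when a decoding plugin is
available.  Label and prediction tracks are plain CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_IMAGE_EXTS = (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")

# Rec.601 luminance weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a frame rate."""

    frames: np.ndarray  # (N, H, W) uint8
    fps: float
    source_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) array")
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least 2 frames "
                             "(successive-frame differencing)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self):
        return len(self.frames)


@dataclass
class LabelTrack:
    """Per-frame binary scratching labels (1 = scratching)."""

    labels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self):
        return len(self.labels)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.uint8)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return (img[..., :3].astype(np.float64) @ _LUMA).round().astype(np.uint8)
    raise ValueError(f"unsupported frame shape {img.shape}")


def read_frames(path, fps: float = 60.0, as_gray: bool = True,
                source_id: str | None = None) -> FrameSequence:
    """Read a video file or an image directory into a FrameSequence.

    Directory entries are taken in lexicographic order, which matches the
    zero-padded naming this package writes.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise ValueError(f"no image frames found in {path}")
        imgs = [iio.imread(f) for f in files]
    else:
        try:
            imgs = [frame for frame in iio.imiter(path)]
        except Exception as exc:  # no plugin / corrupt container
            raise ValueError(f"cannot decode video container {path}: {exc}")
        if not imgs:
            raise ValueError(f"zero frames decoded from {path}")
    if as_gray:
        imgs = [_to_gray(np.asarray(f)) for f in imgs]
    shapes = {f.shape for f in imgs}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
    return FrameSequence(np.stack(imgs), fps=fps,
                         source_id=source_id or path.name)


def write_frames(seq: FrameSequence, out_dir) -> Path:
    """Write frames as zero-padded PNGs; returns the directory."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(seq) - 1)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame)
    return out_dir


def read_label_track(path, n_frames: int, source_id: str | None = None) -> LabelTrack:
    """Read a frame,label CSV; rows missing from [0, n_frames) default to 0.

    Accepts ``label`` or ``call`` as the value column so prediction CSVs
    round-trip as label tracks.
    """
    df = pd.read_csv(path)
    labels = np.zeros(n_frames, dtype=np.uint8)
    if len(df) == 0:
        log.warning("%s: empty label CSV, returning all-zero track", path)
        return LabelTrack(labels, source_id=source_id or str(path))
    col = "label" if "label" in df.columns else "call"
    if "frame" not in df.columns or col not in df.columns:
        raise ValueError(f"{path}: expected columns frame,label (or frame,call)")
    frames = df["frame"].to_numpy()
    vals = df[col].to_numpy()
    if len(np.unique(frames)) != len(frames):
        raise ValueError(f"{path}: duplicate frame indices")
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: labels must be 0 or 1")
    in_range = (frames >= 0) & (frames < n_frames)
    if not in_range.all():
        raise ValueError(f"{path}: frame indices outside [0, {n_frames})")
    if len(frames) < n_frames:
        log.warning("%s: %d of %d frames listed; missing rows default to 0",
                    path, len(frames), n_frames)
    labels[frames] = vals
    return LabelTrack(labels, source_id=source_id or str(path))


def write_track(track, path) -> Path:
    """Write a label or prediction track as CSV.

    Label tracks get columns ``frame,label``; prediction tracks get
    ``frame,score,call`` with scores at 6 decimals (missing scores blank).
    """
    path = Path(path)
    if hasattr(track, "calls"):  # PredictionTrack
        calls = np.asarray(track.calls)
        if len(calls) == 0:
            raise ValueError("refusing to write a zero-length track")
        scores = np.asarray(track.scores, dtype=np.float64)
        df = pd.DataFrame({"frame": np.arange(len(calls)),
                           "score": scores, "call": calls})
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        labels = np.asarray(track.labels)
        if len(labels) == 0:
            raise ValueError("refusing to write a zero-length track")
        pd.DataFrame({"frame": np.arange(len(labels)),
                      "label": labels}).to_csv(path, index=False)
    return path
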