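"""Training loop: per-epoch sampling, augmentation, Adam/BCE optimization,
periodic checkpoints, and validation-based checkpoint selection.

Each epoch draws a fresh sample: ``n_scratch_per_epoch`` segments uniformly
from the scratch-labeled pool plus ``n_random_per_epoch`` uniformly from all
segments regardless of label (the two draws are independent, so overlap is
allowed).  Every sampled stack gets one random horizontal-flip decision and
one rotation by a random multiple of ``rotation_step_deg``, applied
identically to all images of the stack with nearest-neighbor resampling so
binarity is preserved.  The selected model is the checkpoint with the lowest
validation frame error rate at the decision threshold; ties go to the
earliest epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .model import CRNNSpec, CRNNModel, build
from .preprocess import SegmentDataset

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "sample_epoch", "augment", "augment_stack",
           "train", "select_model", "error_rate"]


@dataclass(frozen=True)
class TrainConfig:
    n_scratch_per_epoch: int = 100
    n_random_per_epoch: int = 1500
    learning_rate: float = 3e-5
    max_epochs: int = 800
    checkpoint_every: int = 200
    rotation_step_deg: int = 20
    flip: bool = True
    decision_threshold: float = 0.5
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.rotation_step_deg <= 0 or 360 % self.rotation_step_deg:
            raise ValueError("360 must be divisible by rotation_step_deg")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.n_scratch_per_epoch < 0 or self.n_random_per_epoch < 0:
            raise ValueError("per-epoch sample counts must be >= 0")
        if self.max_epochs < 0 or self.checkpoint_every < 1:
            raise ValueError("invalid epoch configuration")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimization configuration")


def _draw(rng: np.random.Generator, pool: np.ndarray, k: int,
          what: str) -> np.ndarray:
    if k <= len(pool):
        return rng.choice(pool, size=k, replace=False)
    log.info("sampling %d %s segments from a pool of %d: with replacement",
             k, what, len(pool))
    return rng.choice(pool, size=k, replace=True)


def sample_epoch(dataset: SegmentDataset, cfg: TrainConfig,
                 epoch: int) -> np.ndarray:
    """Indices for one epoch: scratch quota + label-blind draw, shuffled.

    The stream is seeded by (cfg.seed, epoch), so a (seed, epoch) pair
    always yields the same sample.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    scratch = dataset.scratch_indices
    if len(scratch) == 0:
        raise ValueError("dataset contains no scratch-labeled segments")
    rng = np.random.default_rng([cfg.seed, epoch])
    idx = np.concatenate([
        _draw(rng, scratch, cfg.n_scratch_per_epoch, "scratch"),
        _draw(rng, np.arange(len(dataset)), cfg.n_random_per_epoch, "random"),
    ])
    rng.shuffle(idx)
    return idx


def augment_stack(stack: np.ndarray, rng: np.random.Generator,
                  rotation_step_deg: int = 20, flip: bool = True) -> np.ndarray:
    """One flip decision (p=0.5) and one rotation by a random multiple of
    ``rotation_step_deg``, applied identically to every image of the stack.

    Multiples of 90 degrees rotate exactly; other angles use
    nearest-neighbor resampling with zero fill, so values stay in {0, 1}.
    """
    out = stack
    if flip and rng.random() < 0.5:
        out = out[..., ::-1]
    n_angles = 360 // rotation_step_deg
    angle = int(rng.integers(n_angles)) * rotation_step_deg
    if angle == 0:
        return np.ascontiguousarray(out)
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(out, k=angle // 90,
                                             axes=(-2, -1)))
    return ndimage.rotate(out, angle, axes=(-2, -1), reshape=False,
                          order=0, mode="constant", cval=0, prefilter=False)


def augment(segment, rng: np.random.Generator,
            rotation_step_deg: int = 20, flip: bool = True):
    """Segment-level wrapper around :func:`augment_stack`."""
    from .preprocess import Segment
    return Segment(augment_stack(segment.stack, rng, rotation_step_deg, flip),
                   segment.center_frame, segment.label, segment.source_id)


def error_rate(model: CRNNModel, dataset: SegmentDataset,
               threshold: float = 0.5, batch_size: int = 64) -> float:
    """Fraction of mispredicted segments at the decision threshold,
    scored without augmentation."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    scores = model.score(dataset.stacks, batch_size=batch_size)
    calls = scores > threshold
    return float(np.mean(calls != (dataset.labels == 1)))


def train(train_set: SegmentDataset, cfg: TrainConfig, spec: CRNNSpec,
          out_dir=None):
    """Run the optimization; returns (checkpoints, loss_log).

    ``checkpoints`` is a list of (epoch, CRNNModel) snapshots taken at epoch
    0, at every multiple of ``checkpoint_every``, and at the final epoch.
    ``loss_log`` is a list of (epoch, mean per-segment loss).  Non-finite
    loss aborts with a diagnostic.  When ``out_dir`` is given the loss log
    is written to ``loss_log.csv`` there.
    """
    model = build(spec, cfg.seed)
    if train_set.stacks.shape[1] != spec.seq_len or \
            train_set.stacks.shape[2] != spec.input_size:
        raise ValueError(
            f"dataset stacks {train_set.stacks.shape[1:]} do not match spec "
            f"(seq_len={spec.seq_len}, input_size={spec.input_size})")
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    checkpoints = [(0, _snapshot(model, 0))]
    loss_log: list[tuple[int, float]] = []

    for epoch in range(1, cfg.max_epochs + 1):
        idx = sample_epoch(train_set, cfg, epoch)
        aug_rng = np.random.default_rng([cfg.seed, epoch, 1])
        total, count = 0.0, 0
        for lo in range(0, len(idx), cfg.batch_size):
            batch_idx = idx[lo:lo + cfg.batch_size]
            x = np.stack([
                augment_stack(train_set.stacks[i], aug_rng,
                              cfg.rotation_step_deg, cfg.flip)
                for i in batch_idx]).astype(np.float32)
            y = (train_set.labels[batch_idx] == 1).astype(np.float32)
            loss, grads = model.loss_and_grads(x, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {lo} (lr={cfg.learning_rate})")
            opt.step(grads)
            total += loss * len(batch_idx)
            count += len(batch_idx)
        mean_loss = total / count
        loss_log.append((epoch, mean_loss))
        log.info("epoch %d: mean loss %.5f", epoch, mean_loss)
        if epoch % cfg.checkpoint_every == 0 or epoch == cfg.max_epochs:
            checkpoints.append((epoch, _snapshot(model, epoch)))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "loss_log.csv", "w") as fh:
            fh.write("epoch,mean_loss\n")
            for epoch, loss in loss_log:
                fh.write(f"{epoch},{loss:.8f}\n")
    return checkpoints, loss_log


def _snapshot(model: CRNNModel, epoch: int) -> CRNNModel:
    snap = CRNNModel(model.spec, model.rng_seed, dtype=model.dtype,
                     epoch=epoch)
    snap.set_params(model.params)
    return snap


def select_model(checkpoints, validation_set: SegmentDataset,
                 cfg: TrainConfig) -> CRNNModel:
    """Checkpoint with the lowest validation frame error rate (ties ->
    earliest epoch); segments are scored without augmentation."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    if len(validation_set) == 0:
        raise ValueError("empty validation set")
    best_model, best_err, best_epoch = None, np.inf, None
    for epoch, snap in checkpoints:
        err = error_rate(snap, validation_set, cfg.decision_threshold)
        log.info("checkpoint epoch %d: validation error rate %.4f", epoch, err)
        if err < best_err:
            best_model, best_err, best_epoch = snap, err, epoch
    log.info("selected checkpoint at epoch %d (error rate %.4f)",
             best_epoch, best_err)
    return best_model
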