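"""Synthetic arena videos with ground-truth scratching labels.

The generator emulates the recording setup the detector targets: a dark
mouse-sized blob on a light arena floor, filmed from above at 60 Hz.  Four
behaviors are rendered:

``scratch``
    a small appendage blob adjacent to the body toggles between two
    positions with a short period (default 5 frames, ~12 Hz at 60 fps) —
    the rapid repetitive hind-limb motion that defines scratching;
``groom``
    the same positional motif at a 4x longer period, the classic slow
    oscillation distractor;
``walk``
    smooth whole-body translation;
``still``
    no motion.

Every frame carries a ground-truth binary label (1 exactly on scratch
episodes), so each downstream stage is testable without real recordings.
Rendering is bit-exact under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .video_io import FrameSequence, LabelTrack, write_frames, write_track

__all__ = ["EthogramSchedule", "SimulationConfig", "make_schedule",
           "render_video", "schedule_labels", "simulate_session"]

BEHAVIORS = ("scratch", "groom", "walk", "still")

# frames a bout must reach so a correct detection survives the default
# run-length posterior filter
MIN_BOUT_FRAMES = 10


@dataclass(frozen=True)
class EthogramSchedule:
    """Non-overlapping behavior episodes covering [0, total_frames).

    Episodes are ``(behavior, start, end)`` with half-open frame ranges.
    """

    episodes: tuple[tuple[str, int, int], ...]
    total_frames: int
    fps: float = 60.0

    def __post_init__(self):
        if self.total_frames <= 0:
            raise ValueError("total_frames must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        prev_end = 0
        for name, start, end in self.episodes:
            if name not in BEHAVIORS:
                raise ValueError(f"unknown behavior {name!r}")
            if not (0 <= start < end <= self.total_frames):
                raise ValueError(f"episode ({name}, {start}, {end}) out of range")
            if start != prev_end:
                raise ValueError("episodes must tile [0, total_frames) "
                                 f"without gaps; gap before frame {start}")
            prev_end = end
        if prev_end != self.total_frames:
            raise ValueError("episodes do not cover the full schedule")

    @property
    def n_scratch_bouts(self) -> int:
        return sum(1 for b, _, _ in self.episodes if b == "scratch")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"total_frames": self.total_frames, "fps": self.fps,
             "episodes": [list(e) for e in self.episodes]}, indent=1))

    @classmethod
    def from_json(cls, path) -> "EthogramSchedule":
        d = json.loads(Path(path).read_text())
        return cls(tuple(tuple(e) for e in d["episodes"]),
                   d["total_frames"], d["fps"])


@dataclass(frozen=True)
class SimulationConfig:
    """Arena geometry, photometry and motion parameters.

    Intensities are 8-bit gray levels; the body must be darker than the
    arena floor (dark mouse, light arena).
    """

    arena_size_px: tuple[int, int] = (180, 240)  # (H, W)
    body_radius_px: float = 14.0
    scratch_oscillation_period_frames: int = 5
    groom_oscillation_period_frames: int = 20
    walk_speed_px_per_frame: float = 2.0
    background_intensity: int = 200
    body_intensity: int = 30
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.body_intensity < self.background_intensity <= 255):
            raise ValueError("need body_intensity < background_intensity in [0,255]")
        if self.scratch_oscillation_period_frames < 2 or \
                self.groom_oscillation_period_frames < 2:
            raise ValueError("oscillation periods must be >= 2 frames")
        if min(self.arena_size_px) <= 0 or self.body_radius_px <= 0:
            raise ValueError("arena and body sizes must be positive")
        if self.walk_speed_px_per_frame < 0 or self.noise_sd < 0:
            raise ValueError("speed and noise_sd must be non-negative")


def make_schedule(total_frames: int, n_scratch_bouts: int,
                  bout_len_range: tuple[int, int], rng_seed: int,
                  fps: float = 60.0, min_gap: int = 12,
                  edge_margin: int = 15) -> EthogramSchedule:
    """Randomly place scratch bouts, filling gaps with walk/groom/still.

    Bout lengths are drawn uniformly from ``bout_len_range`` (inclusive) and
    must be >= 10 frames so that a correctly detected bout survives the
    default posterior filter.  Raises ValueError when the requested bouts
    cannot be packed into ``total_frames`` with the separation margins.
    """
    lo, hi = bout_len_range
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    if n_scratch_bouts < 0 or lo > hi:
        raise ValueError("invalid bout specification")
    if n_scratch_bouts and lo < MIN_BOUT_FRAMES:
        raise ValueError(f"bout lengths must be >= {MIN_BOUT_FRAMES} frames")
    rng = np.random.default_rng(rng_seed)
    lengths = rng.integers(lo, hi + 1, size=n_scratch_bouts)
    n_gaps = n_scratch_bouts + 1
    min_gaps = np.full(n_gaps, min_gap)
    if n_gaps >= 1:
        min_gaps[0] = edge_margin
        min_gaps[-1] = edge_margin
    need = int(lengths.sum() + min_gaps.sum())
    if need > total_frames:
        raise ValueError(
            f"{n_scratch_bouts} bouts of {lo}-{hi} frames do not fit in "
            f"{total_frames} frames (need >= {need})")
    # spread the slack over the gaps
    slack = total_frames - need
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps))
    gaps = min_gaps + extra

    episodes: list[tuple[str, int, int]] = []
    pos = 0

    def fill_gap(n: int) -> None:
        nonlocal pos
        while n > 0:
            chunk = int(min(n, rng.integers(10, 41)))
            if n - chunk < 10:  # avoid a trailing sliver
                chunk = n
            behavior = str(rng.choice(("walk", "groom", "still")))
            episodes.append((behavior, pos, pos + chunk))
            pos += chunk
            n -= chunk

    for j in range(n_scratch_bouts):
        fill_gap(int(gaps[j]))
        episodes.append(("scratch", pos, pos + int(lengths[j])))
        pos += int(lengths[j])
    fill_gap(int(gaps[-1]))
    return EthogramSchedule(tuple(episodes), total_frames, fps)


def schedule_labels(schedule: EthogramSchedule) -> np.ndarray:
    labels = np.zeros(schedule.total_frames, dtype=np.uint8)
    for behavior, start, end in schedule.episodes:
        if behavior == "scratch":
            labels[start:end] = 1
    return labels


def _draw_disc(frame: np.ndarray, center: tuple[float, float],
               a: float, b: float, theta: float, intensity: int) -> None:
    """Fill an ellipse (semi-axes a, b rotated by theta) into frame."""
    h, w = frame.shape
    cy, cx = center
    r = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    frame[y0:y1, x0:x1][mask] = intensity


def render_video(schedule: EthogramSchedule,
                 config: SimulationConfig) -> tuple[FrameSequence, LabelTrack]:
    """Render the schedule into frames plus the matching label track.

    The body is an ellipse; during scratch/groom episodes an appendage disc
    adjacent to the body toggles between two radial positions with the
    configured period.  The body is clamped inside the arena, never an
    error.  Identical (schedule, config) pairs give bit-identical output.
    """
    h, w = config.arena_size_px
    rng = np.random.default_rng(config.seed)
    r = config.body_radius_px
    margin = 1.8 * r
    pos = np.array([h / 2.0, w / 2.0])
    heading = float(rng.uniform(0, 2 * np.pi))

    frames = np.empty((schedule.total_frames, h, w), dtype=np.uint8)
    # geometry chosen so the appendage stays inside the default crop window
    # (1.5x the body diameter around the centroid) at both poses
    app_r = max(2.0, 0.3 * r)      # appendage disc radius
    osc_amp = max(3.0, 0.35 * r)   # appendage displacement between poses

    for behavior, start, end in schedule.episodes:
        if behavior in ("scratch", "groom"):
            app_angle = float(rng.uniform(0, 2 * np.pi))
            period = (config.scratch_oscillation_period_frames
                      if behavior == "scratch"
                      else config.groom_oscillation_period_frames)
        for t in range(start, end):
            if behavior == "walk":
                heading += float(rng.normal(0, 0.15))
                step = config.walk_speed_px_per_frame * np.array(
                    [np.sin(heading), np.cos(heading)])
                pos = pos + step
                if not (margin <= pos[0] <= h - margin):
                    heading = -heading
                if not (margin <= pos[1] <= w - margin):
                    heading = np.pi - heading
                pos[0] = np.clip(pos[0], margin, h - margin)
                pos[1] = np.clip(pos[1], margin, w - margin)
            frame = np.full((h, w), config.background_intensity, dtype=np.uint8)
            _draw_disc(frame, (pos[0], pos[1]), r, 0.8 * r, heading,
                       config.body_intensity)
            if behavior in ("scratch", "groom"):
                phase = (t - start) % period
                dist = 0.75 * r + (osc_amp if phase < period / 2 else 0.0)
                app = pos + dist * np.array([np.sin(app_angle),
                                             np.cos(app_angle)])
                _draw_disc(frame, (app[0], app[1]), app_r, app_r, 0.0,
                           config.body_intensity)
            frames[t] = frame

    if config.noise_sd > 0:
        noise = rng.normal(0, config.noise_sd, frames.shape)
        frames = np.clip(frames.astype(np.float64) + noise, 0, 255) \
            .round().astype(np.uint8)

    seq = FrameSequence(frames, fps=schedule.fps, source_id=f"sim-{config.seed}")
    track = LabelTrack(schedule_labels(schedule), source_id=seq.source_id)
    return seq, track


def simulate_session(schedule: EthogramSchedule, config: SimulationConfig,
                     out_dir=None):
    """Render a session; optionally write frames/, labels.csv, schedule.json."""
    seq, track = render_video(schedule, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_frames(seq, out_dir / "frames")
        write_track(track, out_dir / "labels.csv")
        schedule.to_json(out_dir / "schedule.json")
        (out_dir / "sim_config.json").write_text(json.dumps(asdict(config)))
    return seq, track
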