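"""End-to-end run: simulate -> preprocess -> train -> predict -> evaluate.

A single YAML/dict config drives every stage; all randomness fans out from
one global seed, so re-running a config reproduces every CSV/JSON output
bit for bit.  Sections map onto the stage configs (SimulationConfig,
PreprocessConfig, CRNNSpec, TrainConfig); unknown keys and invalid values
raise at load time, naming the field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, inference, synthetic, training
from .model import CRNNSpec, save_checkpoint
from .preprocess import PreprocessConfig, SegmentDataset, build_segments
from .video_io import write_track

log = logging.getLogger(__name__)

__all__ = ["load_config", "validate_config", "run_pipeline", "DEMO_CONFIG"]

# Desk-scale demo: small preset, short synthetic videos, a short training
# run with frequent checkpoints.  Completes on one CPU in a few minutes.
DEMO_CONFIG: dict = {
    "seed": 0,
    "fps": 60,
    "simulation": {"noise_sd": 2.0},
    "schedule": {"total_frames": 600, "n_scratch_bouts": 10,
                 "bout_len_range": [12, 30]},
    "data": {"n_train_videos": 2, "n_val_videos": 1, "n_test_videos": 1},
    "preprocess": {"out_size": 64},
    "model": {"preset": "small"},
    "training": {"n_scratch_per_epoch": 100, "n_random_per_epoch": 200,
                 "learning_rate": 1e-3, "max_epochs": 10,
                 "checkpoint_every": 2, "batch_size": 32},
    "inference": {"threshold": 0.5, "min_run": 10},
}

_SECTIONS = ("seed", "fps", "simulation", "schedule", "data", "preprocess",
             "model", "training", "inference")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def _build_section(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {name} config fields: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {name} config: {exc}") from exc


def _model_spec(section: dict, seq_len: int, out_size: int) -> CRNNSpec:
    section = dict(section)
    preset = section.pop("preset", None)
    if preset == "small":
        spec = CRNNSpec.small(seq_len=seq_len)
        base = dataclasses.asdict(spec)
    elif preset in (None, "default"):
        base = dataclasses.asdict(CRNNSpec())
    else:
        raise ValueError(f"unknown model preset {preset!r}")
    base.update(section)
    base["seq_len"] = seq_len
    base["input_size"] = out_size
    for k in ("conv_channels", "lstm_units", "fc_units"):
        base[k] = tuple(base[k])
    return _build_section(CRNNSpec, base, "model")


def validate_config(cfg: dict) -> dict:
    """Validate a pipeline config dict, raising on any bad field."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for req in ("seed", "fps"):
        if req not in cfg:
            raise ValueError(f"config is missing required field: {req}")
    if cfg["fps"] <= 0:
        raise ValueError("fps must be positive")
    # construct every stage config so invariants run now, not mid-pipeline
    staged = resolve_stages(cfg)
    for sched_key in ("total_frames", "n_scratch_bouts", "bout_len_range"):
        if sched_key not in cfg.get("schedule", {}):
            raise ValueError(f"schedule config is missing: {sched_key}")
    del staged
    return cfg


def resolve_stages(cfg: dict):
    """Instantiate the per-stage config objects from a validated dict."""
    sim_section = dict(cfg.get("simulation", {}))
    sim_section.setdefault("seed", cfg["seed"])
    sim = _build_section(synthetic.SimulationConfig, sim_section, "simulation")
    pre = _build_section(PreprocessConfig, cfg.get("preprocess", {}),
                         "preprocess")
    train_section = dict(cfg.get("training", {}))
    train_section.setdefault("seed", cfg["seed"])
    tr = _build_section(training.TrainConfig, train_section, "training")
    spec = _model_spec(cfg.get("model", {}), seq_len=pre.seq_len,
                       out_size=pre.out_size)
    inf = dict(cfg.get("inference", {}))
    inf.setdefault("threshold", 0.5)
    inf.setdefault("min_run", 10)
    return sim, pre, spec, tr, inf


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def simulate_videos(cfg: dict, n: int, seed_offset: int):
    """Render ``n`` synthetic labeled videos from the config's schedule
    and simulation sections, seeds fanned out from the global seed."""
    sim, _, _, _, _ = resolve_stages(cfg)
    sched_cfg = cfg["schedule"]
    seeds = _child_seeds(cfg["seed"] + seed_offset, 2 * n)
    out = []
    for j in range(n):
        schedule = synthetic.make_schedule(
            sched_cfg["total_frames"], sched_cfg["n_scratch_bouts"],
            tuple(sched_cfg["bout_len_range"]), rng_seed=seeds[2 * j],
            fps=cfg["fps"])
        video_sim = dataclasses.replace(sim, seed=seeds[2 * j + 1])
        seq, track = synthetic.render_video(schedule, video_sim)
        seq.source_id = f"sim{seed_offset}-{j}"
        track.source_id = seq.source_id
        out.append((schedule, seq, track))
    return out


def run_pipeline(cfg: dict, out_dir) -> Path:
    """Execute the full chain on synthetic data; returns the run directory.

    Writes labels/predictions/bout CSVs per test video, the selected model
    checkpoint, the training loss log, report.json and a manifest.
    """
    cfg = validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim, pre, spec, tr, inf = resolve_stages(cfg)
    n_train = cfg.get("data", {}).get("n_train_videos", 2)
    n_val = cfg.get("data", {}).get("n_val_videos", 1)
    n_test = cfg.get("data", {}).get("n_test_videos", 1)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    log.info("simulating %d train / %d val / %d test videos",
             n_train, n_val, n_test)
    train_videos = stage("simulate", simulate_videos, cfg, n_train, 1)
    val_videos = stage("simulate", simulate_videos, cfg, n_val, 2)
    test_videos = stage("simulate", simulate_videos, cfg, n_test, 3)

    def to_dataset(videos):
        return SegmentDataset.concatenate(
            [build_segments(seq, track, pre) for _, seq, track in videos])

    train_set = stage("preprocess", to_dataset, train_videos)
    val_set = stage("preprocess", to_dataset, val_videos)

    checkpoints, loss_log = stage("train", training.train,
                                  train_set, tr, spec, out_dir)
    selected = stage("select", training.select_model,
                     checkpoints, val_set, tr)
    save_checkpoint(selected, out_dir / "model.ckpt.npz")
    val_err = training.error_rate(selected, val_set, tr.decision_threshold)

    pairs, report_videos, cms = [], [], []
    for schedule, seq, track in test_videos:
        raw = stage("predict", inference.predict_track, selected, seq, pre,
                    inf["threshold"])
        filt = inference.posterior_filter(raw, inf["min_run"])
        write_track(track, out_dir / f"{seq.source_id}_labels.csv")
        write_track(filt, out_dir / f"{seq.source_id}_pred.csv")
        human_bouts = inference.bouts_from_track(track, cfg["fps"])
        pred_bouts = inference.bouts_from_track(filt, cfg["fps"])
        pred_bouts.to_dataframe().to_csv(
            out_dir / f"{seq.source_id}_bouts.csv", index=False)
        cm = evaluation.confusion(filt, track)
        ms = evaluation.metrics(cm)
        eb = evaluation.classify_errors(filt, track)
        pairs.append((human_bouts, pred_bouts))
        cms.append(cm)
        report_videos.append({
            "source_id": seq.source_id,
            "confusion": dataclasses.asdict(cm),
            "metrics": ms.rounded(),
            "error_breakdown": dataclasses.asdict(eb),
            "human_bouts": len(human_bouts),
            "predicted_bouts": len(pred_bouts),
            "human_duration_s": round(human_bouts.total_duration_s, 6),
            "predicted_duration_s": round(pred_bouts.total_duration_s, 6),
        })

    report = {
        "config_hash": config_hash(cfg),
        "selected_epoch": selected.epoch,
        "validation_error_rate_pct": evaluation.round_pct(100 * val_err, 4),
        "final_train_loss": round(loss_log[-1][1], 6) if loss_log else None,
        "videos": report_videos,
    }
    pooled = evaluation.ConfusionMatrix(
        tp=sum(c.tp for c in cms), fp=sum(c.fp for c in cms),
        fn=sum(c.fn for c in cms), tn=sum(c.tn for c in cms))
    report["pooled_confusion"] = dataclasses.asdict(pooled)
    report["pooled_metrics"] = evaluation.metrics(pooled).rounded()
    if len(pairs) >= 2:
        ag = evaluation.agreement(pairs)
        report["agreement"] = {"r_bouts": ag.r_bouts,
                               "r_durations": ag.r_durations}
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    manifest = {"config": cfg, "config_hash": config_hash(cfg),
                "outputs": sorted(p.name for p in out_dir.iterdir())}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
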