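"""Run configuration: schema, validation, hashing and stage orchestration.

A `RunConfig` describes a full pipeline run (simulate -> preprocess ->
train -> evaluate).  Configs are strict: unknown keys are rejected rather
than silently ignored, bounds are enforced at validation time, and every
executed stage writes its resolved config and a content hash next to its
outputs so an unchanged stage can be skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import architecture, evaluation, phantom, preprocessing, training

logger = logging.getLogger(__name__)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    counts: dict[str, int] = Field(default_factory=lambda: dict(phantom.DEFAULT_COUNTS))
    preset: str = "test"

    @field_validator("preset")
    @classmethod
    def _preset_known(cls, v):
        if v not in phantom.PRESETS:
            raise ValueError(f"preset must be one of {sorted(phantom.PRESETS)}")
        return v

    @field_validator("counts")
    @classmethod
    def _counts_valid(cls, v):
        for label, c in v.items():
            if label not in phantom.CLASSES:
                raise ValueError(f"unknown class {label!r}")
            if c < 0:
                raise ValueError(f"count for {label} must be >= 0")
        return v


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    frac_threshold: float = 0.5
    bet_path: str | None = None
    normalize: bool = True

    @field_validator("frac_threshold")
    @classmethod
    def _frac_bounds(cls, v):
        if not 0 < v < 1:
            raise ValueError("frac_threshold must lie in (0, 1)")
        return v


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arch: str = "3d"
    base_channels: int = 4
    fc_units: tuple[int, int] = (64, 32)
    n_classes: int = 4
    slice_step: int = 1  # 2D baseline: keep every slice_step-th brain slice

    @field_validator("arch")
    @classmethod
    def _arch_known(cls, v):
        if v not in ("3d", "2d"):
            raise ValueError("arch must be '3d' or '2d'")
        return v


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lr_init: float = 1e-2
    lr_decay: float = 0.9
    decay_step: int = 300
    epochs: int = 20
    batch_size: int = 4
    momentum: float = 0.9
    loss: str = "summed_bce"
    train_fraction: float = 0.75

    @field_validator("lr_decay")
    @classmethod
    def _decay_bounds(cls, v):
        if not 0 < v < 1:
            raise ValueError("lr_decay must lie in the open interval (0, 1)")
        return v

    @field_validator("train_fraction")
    @classmethod
    def _fraction_bounds(cls, v):
        if not 0 < v < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        return v

    def to_training_config(self, seed: int) -> training.TrainingConfig:
        return training.TrainingConfig(
            lr_init=self.lr_init,
            lr_decay=self.lr_decay,
            decay_step=self.decay_step,
            epochs=self.epochs,
            batch_size=self.batch_size,
            momentum=self.momentum,
            loss=self.loss,
            seed=seed,
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved_dict(), fh, sort_keys=True)


def validate_config(path) -> RunConfig:
    """Load and schema-check a YAML/JSON config file; errors carry key paths."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.model_validate(raw)


def config_hash(fragment: dict) -> str:
    return hashlib.sha256(json.dumps(fragment, sort_keys=True).encode()).hexdigest()[:16]


def _stage_fresh(stage_dir: Path, digest: str) -> bool:
    marker = stage_dir / ".config_hash"
    return marker.exists() and marker.read_text().strip() == digest


def _mark_stage(stage_dir: Path, digest: str) -> None:
    (stage_dir / ".config_hash").write_text(digest + "\n")


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = ("simulate", "preprocess", "train", "evaluate")) -> dict:
    """Execute the pipeline (or a prefix); unchanged stages are skipped.

    Each stage directory under ``out_dir`` is stamped with a hash of the
    config fragment (plus upstream hashes) that produced it; rerunning with
    an identical config is a no-op for every stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.save(out / "config.yaml")
    artifacts: dict = {"out_dir": out}

    valid_order = ("simulate", "preprocess", "train", "evaluate")
    stages = tuple(stages)
    unknown = set(stages) - set(valid_order)
    if unknown or list(stages) != [s for s in valid_order if s in stages]:
        raise ValueError(f"stages must be an ordered subset of {valid_order}, got {stages}")

    sim_dir = out / "cohort"
    sim_digest = config_hash({"seed": cfg.seed, **cfg.cohort.model_dump()})
    if "simulate" in stages:
        if _stage_fresh(sim_dir, sim_digest):
            logger.info("simulate: unchanged config, skipping")
        else:
            if sim_dir.exists():
                for p in sorted(sim_dir.rglob("*"), reverse=True):
                    p.unlink() if p.is_file() else p.rmdir()
            phantom.generate_cohort(
                sim_dir,
                per_class_counts=cfg.cohort.counts,
                master_seed=cfg.seed,
                preset=cfg.cohort.preset,
                overwrite=True,
            )
            _mark_stage(sim_dir, sim_digest)
        artifacts["manifest"] = sim_dir / "manifest.csv"

    pre_dir = out / "preprocessed"
    pre_digest = config_hash({"upstream": sim_digest, **cfg.preprocess.model_dump()})
    if "preprocess" in stages:
        if not (sim_dir / "manifest.csv").exists():
            raise FileNotFoundError("missing cohort manifest: run the simulate stage first")
        if _stage_fresh(pre_dir, pre_digest):
            logger.info("preprocess: unchanged config, skipping")
        else:
            pre_dir.mkdir(parents=True, exist_ok=True)
            manifest = phantom.CohortManifest.load(sim_dir / "manifest.csv")
            vols = [preprocessing.load_volume(p) for p in manifest.table["path"]]
            cropped, box = preprocessing.preprocess_dataset(
                vols,
                frac_threshold=cfg.preprocess.frac_threshold,
                bet_path=cfg.preprocess.bet_path,
                normalize=cfg.preprocess.normalize,
            )
            arr = np.stack([v.data for v in cropped]).astype(np.float32)
            np.savez_compressed(pre_dir / "volumes.npz", volumes=arr)
            manifest.table.to_csv(pre_dir / "manifest.csv", index=False)
            preprocessing.write_sidecar(
                pre_dir / "preprocess.json", box, cfg.preprocess.model_dump()
            )
            _mark_stage(pre_dir, pre_digest)
        artifacts["preprocessed"] = pre_dir

    train_dir = out / "model"
    train_digest = config_hash(
        {"upstream": pre_digest, "seed": cfg.seed, **cfg.model.model_dump(), **cfg.train.model_dump()}
    )
    if "train" in stages:
        if not (pre_dir / "volumes.npz").exists():
            raise FileNotFoundError("missing preprocessed volumes: run the preprocess stage first")
        if _stage_fresh(train_dir, train_digest):
            logger.info("train: unchanged config, skipping")
        else:
            _run_training_stage(cfg, pre_dir, train_dir)
            _mark_stage(train_dir, train_digest)
        artifacts["model"] = train_dir

    eval_dir = out / "eval"
    eval_digest = config_hash({"upstream": train_digest})
    if "evaluate" in stages:
        if not (train_dir / "history.csv").exists():
            raise FileNotFoundError("missing trained model: run the train stage first")
        if _stage_fresh(eval_dir, eval_digest):
            logger.info("evaluate: unchanged config, skipping")
        else:
            _run_evaluation_stage(cfg, pre_dir, train_dir, eval_dir)
            _mark_stage(eval_dir, eval_digest)
        artifacts["eval"] = eval_dir
    return artifacts


def _load_preprocessed(pre_dir: Path):
    with np.load(pre_dir / "volumes.npz") as data:
        arr = data["volumes"]
    manifest = phantom.CohortManifest.load(pre_dir / "manifest.csv")
    labels = np.array([phantom.CLASSES.index(l) for l in manifest.table["label"]])
    return arr, labels, manifest


def _build_spec(cfg: RunConfig, extents):
    if cfg.model.arch == "3d":
        return architecture.build_3d_cnn(
            extents, n_classes=cfg.model.n_classes, base_channels=cfg.model.base_channels, fc_units=tuple(cfg.model.fc_units)
        )
    return architecture.build_2d_baseline(
        extents[:2], n_classes=cfg.model.n_classes, base_channels=cfg.model.base_channels, fc_units=tuple(cfg.model.fc_units)
    )


def _run_training_stage(cfg: RunConfig, pre_dir: Path, train_dir: Path):
    arr, labels, manifest = _load_preprocessed(pre_dir)
    plan = training.split_train_test(
        manifest.table, fraction=cfg.train.train_fraction, seed=cfg.seed
    )
    sid = manifest.table["subject_id"].tolist()
    train_idx = np.array([sid.index(s) for s in plan.train_ids])
    test_idx = np.array([sid.index(s) for s in plan.test_ids])
    tconf = cfg.train.to_training_config(cfg.seed)
    x = arr[:, None]  # add channel axis
    if cfg.model.arch == "3d":
        spec = _build_spec(cfg, arr.shape[1:])
        hist, net = training.train(
            spec, x[train_idx], labels[train_idx], x[test_idx], labels[test_idx], tconf
        )
    else:
        spec = _build_spec(cfg, arr.shape[1:])
        xs_tr, ys_tr, _ = training.volumes_to_slice_dataset(
            x[train_idx], labels[train_idx], step=cfg.model.slice_step
        )
        xs_te, ys_te, grp_te = training.volumes_to_slice_dataset(
            x[test_idx], labels[test_idx], step=cfg.model.slice_step
        )
        hist, net = training.train(spec, xs_tr, ys_tr, xs_te, ys_te, tconf, test_groups=grp_te)
    training.save_run(train_dir, hist, net, tconf, {"seed": cfg.seed, "arch": cfg.model.arch})
    with open(train_dir / "arch.json", "w") as fh:
        fh.write(spec.to_json())
    with open(train_dir / "split.json", "w") as fh:
        json.dump({"train_ids": list(plan.train_ids), "test_ids": list(plan.test_ids)}, fh, indent=2)


def _run_evaluation_stage(cfg: RunConfig, pre_dir: Path, train_dir: Path, eval_dir: Path):
    from .nn import build_network

    arr, labels, manifest = _load_preprocessed(pre_dir)
    with open(train_dir / "arch.json") as fh:
        spec = architecture.ArchitectureSpec.from_json(fh.read())
    net = build_network(spec, seed=0)
    net.load(train_dir / "weights.npz")
    with open(train_dir / "split.json") as fh:
        split = json.load(fh)
    sid = manifest.table["subject_id"].tolist()
    test_idx = np.array([sid.index(s) for s in split["test_ids"]])
    x = arr[:, None][test_idx]
    y = labels[test_idx]
    if cfg.model.arch == "3d":
        probs = net.predict_proba(x, batch_size=cfg.train.batch_size)
    else:
        xs, _, grp = training.volumes_to_slice_dataset(x, y, step=cfg.model.slice_step)
        slice_probs = net.predict_proba(xs, batch_size=cfg.train.batch_size)
        probs = np.stack([slice_probs[grp == g].mean(axis=0) for g in np.unique(grp)])
    pred = evaluation.predict_classes(probs)
    cm = evaluation.confusion(y, pred)
    metrics = evaluation.metrics_report(cm, classifier=cfg.model.arch.upper())
    hist = training.TrainingHistory()
    hist_df = pd.read_csv(train_dir / "history.csv")
    hist.epochs = hist_df.to_dict("records")
    evaluation.report(eval_dir, metrics, histories={cfg.model.arch.upper(): hist}, confusions={cfg.model.arch.upper(): cm})
    with open(eval_dir / "summary.json", "w") as fh:
        json.dump({"accuracy": evaluation.accuracy(cm)}, fh, indent=2)

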