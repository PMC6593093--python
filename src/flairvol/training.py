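"""Loss, learning-rate schedule, data splitting and the seeded training loop.

The protocol follows the study design: a stratified 75/25 train/test split,
optional 10-fold cross-validation inside the training set, SGD with momentum,
an exponentially decayed learning rate initialized at 1e-2 with decay step
300 (continuous, non-staircase exponent), and per-epoch train/test loss and
accuracy traces.

The default loss is a binary cross-entropy summed over the N class outputs,

    loss = -sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ],

applied to the softmax output vector with one-hot targets and averaged over
the batch.  This differs from plain categorical cross-entropy by the
(1-y) log(1-p) terms; categorical CE is available as a config alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .architecture import ArchitectureSpec
from .nn import SGD, Network, build_network

EPS = 1e-7


@dataclass(frozen=True)
class TrainingConfig:
    lr_init: float = 1e-2
    lr_decay: float = 0.9
    decay_step: int = 300
    epochs: int = 50
    batch_size: int = 4
    momentum: float = 0.9
    loss: str = "summed_bce"  # or "categorical"
    seed: int = 0

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.decay_step < 1:
            raise ValueError("decay_step must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.loss not in ("summed_bce", "categorical"):
            raise ValueError(f"unknown loss {self.loss!r}")


def lr_at(global_step: int, config: TrainingConfig) -> float:
    """Decayed learning rate: lr_init * lr_decay ** (step / decay_step)."""
    return config.lr_init * config.lr_decay ** (global_step / config.decay_step)


def cross_entropy(y: np.ndarray, y_hat: np.ndarray, kind: str = "summed_bce", eps: float = EPS) -> float:
    """Loss for one sample (1D) or mean loss for a batch (2D).

    ``y`` is one-hot, ``y_hat`` a probability vector; probabilities are
    clipped to [eps, 1-eps] before the logarithms.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {y_hat.shape}")
    p = np.clip(y_hat, eps, 1 - eps)
    if kind == "summed_bce":
        per = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=-1)
    elif kind == "categorical":
        per = -(y * np.log(p)).sum(axis=-1)
    else:
        raise ValueError(f"unknown loss {kind!r}")
    return float(per if per.ndim == 0 else per.mean())


def _loss_grad(y: np.ndarray, p_raw: np.ndarray, kind: str, eps: float = EPS) -> np.ndarray:
    """d(mean batch loss)/d(probabilities), zero where clipping saturates."""
    p = np.clip(p_raw, eps, 1 - eps)
    n = p_raw.shape[0]
    if kind == "summed_bce":
        g = -(y / p - (1 - y) / (1 - p)) / n
    else:
        g = -(y / p) / n
    g[(p_raw < eps) | (p_raw > 1 - eps)] = 0.0
    return g.astype(p_raw.dtype)


@dataclass(frozen=True)
class SplitPlan:
    """Stratified subject-level train/test split with optional CV folds."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: dict | None = None  # subject id -> fold index

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def split_train_test(manifest: pd.DataFrame, fraction: float = 0.75, seed: int = 0) -> SplitPlan:
    """Stratified split by largest-remainder apportionment.

    The global train count is round(fraction * N); per-class counts start at
    floor(fraction * n_class) and the remainder goes to the classes with the
    largest fractional parts, so every class stays within one subject of its
    proportional share while the overall split is exactly the requested
    fraction (75/25 by default).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    groups = {label: g["subject_id"].tolist() for label, g in manifest.groupby("label", sort=True)}
    for label, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 subjects; cannot split")
    n_total = sum(len(v) for v in groups.values())
    n_train_total = int(round(fraction * n_total))
    floors = {l: int(np.floor(fraction * len(ids))) for l, ids in groups.items()}
    fracs = {l: fraction * len(ids) - floors[l] for l, ids in groups.items()}
    remainder = n_train_total - sum(floors.values())
    for l in sorted(groups, key=lambda l: (-fracs[l], l))[:remainder]:
        floors[l] += 1
    train, test = [], []
    for label in sorted(groups):
        ids = groups[label]
        n_train = min(max(floors[label], 1), len(ids) - 1)  # keep both sides non-empty
        order = rng.permutation(len(ids))
        train += [ids[i] for i in order[:n_train]]
        test += [ids[i] for i in order[n_train:]]
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)))


def kfold(train_ids, labels, k: int = 10, seed: int = 0) -> dict:
    """Stratified k-fold assignment over training subjects (sizes differ <= 1).

    Returns a mapping subject id -> fold index in [0, k).  Fold i serves as
    the validation share of session i while the other k-1 folds train.
    """
    train_ids = list(train_ids)
    labels = list(labels)
    if len(train_ids) != len(labels):
        raise ValueError("ids and labels differ in length")
    if k > len(train_ids):
        raise ValueError(f"k={k} exceeds number of training subjects ({len(train_ids)})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(train_ids)), labels)):
        for i in val_idx:
            assignment[train_ids[i]] = fold
    return assignment


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy traces plus the per-step learning rate."""

    epochs: list = field(default_factory=list)
    lr_per_step: list = field(default_factory=list)

    def record(self, epoch: int, train_loss: float, train_acc: float, test_loss: float, test_acc: float):
        self.epochs.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "test_loss": test_loss,
                "test_acc": test_acc,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs, columns=["epoch", "train_loss", "train_acc", "test_loss", "test_acc"])

    def save(self, csv_path) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)


def _forward_metrics(net: Network, x, y_onehot, kind: str, batch_size: int, groups=None):
    """Evaluation-mode loss and accuracy; optionally subject-aggregated.

    With ``groups`` given (one group id per row, e.g. subject of each 2D
    slice), softmax outputs are averaged within each group before the
    argmax, giving one prediction per subject.
    """
    probs = net.predict_proba(x, batch_size=batch_size)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        agg_p = np.stack([probs[groups == g].mean(axis=0) for g in uniq])
        agg_y = np.stack([y_onehot[groups == g][0] for g in uniq])
        probs, y_onehot = agg_p, agg_y
    loss = cross_entropy(y_onehot, probs, kind)
    acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
    return loss, acc


def train(
    spec: ArchitectureSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray | None,
    y_test: np.ndarray | None,
    config: TrainingConfig,
    test_groups=None,
    verbose: bool = False,
) -> tuple[TrainingHistory, Network]:
    """Seeded end-to-end training run.

    ``x_train``/``x_test`` are (N, C, *spatial) arrays whose spatial extents
    must all match ``spec.input_extents``; ``y_train``/``y_test`` are integer
    class indices.  Records per-epoch train loss/accuracy (running over the
    epoch's batches, batch-norm in training mode) and evaluation-mode test
    metrics.  Deterministic: the same seed and config reproduce the run
    bit-for-bit on CPU.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    if x_train.shape[2:] != tuple(spec.input_extents):
        raise ValueError(
            f"input extents {x_train.shape[2:]} do not match architecture {tuple(spec.input_extents)}"
        )
    if x_test is not None:
        x_test = np.asarray(x_test, dtype=np.float32)
        if x_test.shape[2:] != tuple(spec.input_extents):
            raise ValueError("test volumes have inconsistent extents")
    n_classes = spec.n_classes
    eye = np.eye(n_classes, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    y1h_train = eye[y_train]
    y1h_test = eye[np.asarray(y_test, dtype=np.int64)] if y_test is not None else None

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, seed=rng)
    opt = SGD(net, momentum=config.momentum)
    history = TrainingHistory()
    step = 0
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y1h_train[idx]
            probs = net.forward(xb, train=True)
            losses.append(cross_entropy(yb, probs, config.loss))
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            seen += len(idx)
            net.backward(_loss_grad(yb, probs, config.loss))
            lr = lr_at(step, config)
            history.lr_per_step.append(lr)
            opt.step(lr)
            step += 1
        train_loss = float(np.mean(losses))
        train_acc = correct / seen
        if x_test is not None and len(x_test):
            test_loss, test_acc = _forward_metrics(
                net, x_test, y1h_test, config.loss, config.batch_size, groups=test_groups
            )
        else:
            test_loss, test_acc = float("nan"), float("nan")
        history.record(epoch + 1, train_loss, train_acc, test_loss, test_acc)
        if verbose:
            print(
                f"epoch {epoch + 1:3d}: train loss {train_loss:.4f} acc {train_acc:.3f}"
                f" | test loss {test_loss:.4f} acc {test_acc:.3f}"
            )
    return history, net


def cross_validate(
    spec: ArchitectureSpec,
    x: np.ndarray,
    y: np.ndarray,
    subject_ids,
    config: TrainingConfig,
    k: int = 10,
) -> dict:
    """k training sessions, rotating one fold out as validation each time.

    Returns per-session validation accuracies and their mean (the figure the
    protocol reports as training-set accuracy).
    """
    labels = [str(v) for v in y]
    assignment = kfold(list(subject_ids), labels, k=k, seed=config.seed)
    fold_of = np.array([assignment[s] for s in subject_ids])
    accs = []
    for fold in range(k):
        val = fold_of == fold
        hist, net = train(spec, x[~val], y[~val], x[val], y[val], config)
        accs.append(hist.epochs[-1]["test_acc"])
    return {"fold_accuracies": accs, "mean_accuracy": float(np.mean(accs))}


def volumes_to_slice_dataset(
    x: np.ndarray, y: np.ndarray, min_nonzero_frac: float = 0.05, step: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unstack volumes into 2D slice samples for the 2D baseline.

    Keeps every ``step``-th slice whose non-zero (brain) fraction reaches
    ``min_nonzero_frac``.  Returns (slices (M,C,H,W), labels, subject index)
    where the subject index maps each slice back to its source volume for
    subject-level aggregation of slice predictions.
    """
    x = np.asarray(x)
    slices, labels, groups = [], [], []
    for i in range(x.shape[0]):
        for z in range(0, x.shape[-1], step):
            sl = x[i, :, :, :, z]
            if np.count_nonzero(sl) / sl.size >= min_nonzero_frac:
                slices.append(sl)
                labels.append(y[i])
                groups.append(i)
    if not slices:
        raise ValueError("no slices pass the brain-fraction filter")
    return np.stack(slices), np.asarray(labels), np.asarray(groups)


def save_run(out_dir, history: TrainingHistory, net: Network, config: TrainingConfig, seed_note: dict | None = None):
    """Serialize history (CSV + JSON), weights and the run's provenance."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    history.save(out_dir / "history.csv")
    with open(out_dir / "history.json", "w") as fh:
        json.dump({"epochs": history.epochs}, fh, indent=2)
    net.save(out_dir / "weights.npz")
    with open(out_dir / "run.json", "w") as fh:
        json.dump(
            {
                "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
                **(seed_note or {}),
            },
            fh,
            indent=2,
        )
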