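"""Supervised training of the bifocal classifier and its evaluation.

Training minimizes inverse-frequency-weighted cross-entropy with Adam.
Validation is case-level: when the dataset spans several slides, whole
slides are held out, mirroring the case-level train/test discipline of the
dataset split — no slide contributes tiles to both sides.  Training-time
augmentation draws one independent perturbation per pair member; the
evaluation and prediction paths never augment.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from . import augment as _augment
from . import model as _model
from . import nn
from .metrics import EvalReport, confusion_matrix_normalized, precision_sensitivity, roc_auc_ovr
from .model import BifocalNet, SubnetNet
from .tiling import BifocalPair

__all__ = [
    "TrainConfig",
    "PairDataset",
    "train",
    "predict_batch",
    "evaluate",
    "cross_validate",
    "normalize_batch",
    "downscale_tiles",
]


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    class_weighting: bool = True
    augment: bool = True
    folds: int = 1
    val_fraction: float = 0.15
    early_stop_patience: int = 5
    rng_seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.folds > 1 and self.folds < 2:
            raise ValueError("folds must be >= 2 when cross-validation is requested")


@dataclass
class PairDataset:
    """In-memory tile-pair dataset.  Tiles are uint8 HWC; labels are class
    indices aligned with ``class_names``."""

    wide: np.ndarray
    narrow: np.ndarray
    labels: np.ndarray
    slide_ids: np.ndarray
    class_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_pairs(
        cls, pairs: list[BifocalPair], class_names: tuple[str, ...], downscale: int = 1
    ) -> "PairDataset":
        if not pairs:
            raise ValueError("empty dataset")
        name_to_idx = {n: i for i, n in enumerate(class_names)}
        labels = np.array([name_to_idx[p.label] for p in pairs], dtype=np.int64)
        wide = np.stack([downscale_tiles(p.wide, downscale) for p in pairs])
        narrow = np.stack([downscale_tiles(p.narrow, downscale) for p in pairs])
        sids = np.array([p.slide_id or "" for p in pairs])
        return cls(wide=wide, narrow=narrow, labels=labels, slide_ids=sids, class_names=tuple(class_names))

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(self.wide[idx], self.narrow[idx], self.labels[idx], self.slide_ids[idx], self.class_names)


def downscale_tiles(tiles: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling of uint8 HWC tiles (or batches of them)."""
    if factor == 1:
        return tiles
    *lead, h, w, c = tiles.shape
    if h % factor or w % factor:
        raise ValueError(f"tile size {h}x{w} not divisible by downscale {factor}")
    t = tiles.reshape(*lead, h // factor, factor, w // factor, factor, c)
    return t.mean(axis=(-2, -4)).astype(np.uint8)


def normalize_batch(tiles: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 NCHW, roughly zero-mean unit-scale."""
    x = tiles.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _augment_batch(wide: np.ndarray, narrow: np.ndarray, rng: np.random.Generator):
    aw = np.empty_like(wide)
    an = np.empty_like(narrow)
    for i in range(len(wide)):
        aw[i] = _augment.apply_augmentation(wide[i], _augment._draw_spec(rng))
        an[i] = _augment.apply_augmentation(narrow[i], _augment._draw_spec(rng))
    return aw, an


def _case_level_val_split(dataset: PairDataset, cfg: TrainConfig, rng: np.random.Generator):
    uniq = np.unique(dataset.slide_ids)
    n = len(dataset)
    if len(uniq) >= 2:
        n_val_slides = max(1, int(round(cfg.val_fraction * len(uniq))))
        if n_val_slides >= len(uniq):
            n_val_slides = len(uniq) - 1
        val_slides = set(rng.permutation(uniq)[:n_val_slides])
        val_mask = np.isin(dataset.slide_ids, list(val_slides))
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[perm[:n_val]] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def _forward_loss(model, wide_u8, narrow_u8, labels, class_weights, training):
    model.set_training(training)
    logits = model.forward(normalize_batch(wide_u8), normalize_batch(narrow_u8))
    return nn.softmax_cross_entropy(logits, labels, class_weights)


def train(
    model: BifocalNet | SubnetNet,
    dataset: PairDataset,
    config: TrainConfig | None = None,
    val_dataset: PairDataset | None = None,
) -> tuple[BifocalNet | SubnetNet, dict]:
    """Train in place; returns (model, history).

    ``history`` holds per-epoch mean training loss and validation loss.
    Early stopping restores the weights of the best validation epoch.
    """
    config = config if config is not None else TrainConfig()
    config.validate()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    present = np.unique(dataset.labels)
    if len(present) < 2:
        raise ValueError("dataset must contain at least 2 classes")

    rng = np.random.default_rng(config.rng_seed)
    if val_dataset is None:
        tr_idx, va_idx = _case_level_val_split(dataset, config, rng)
        val_dataset = dataset.subset(va_idx)
        dataset = dataset.subset(tr_idx)

    n_classes = model.config.num_classes
    if config.class_weighting:
        counts = np.bincount(dataset.labels, minlength=n_classes).astype(np.float64)
        weights = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        weights *= (counts > 0).sum() / weights.sum()
    else:
        weights = None

    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (math.inf, None)
    bad_epochs = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            bw, bn_ = dataset.wide[idx], dataset.narrow[idx]
            if config.augment:
                bw, bn_ = _augment_batch(bw, bn_, rng)
            loss, dlogits = _forward_loss(model, bw, bn_, dataset.labels[idx], weights, True)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss = _validation_loss(model, val_dataset, config.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best[0] - 1e-6:
            best = (val_loss, _snapshot_state(model))
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break
    if best[1] is not None:
        _restore_state(model, best[1])
    model.set_training(False)
    return model, history


def _snapshot_state(model) -> tuple:
    """Copy trainable parameters and batch-norm running statistics, so the
    restored best-validation model is self-consistent."""
    params = [p.value.copy() for p in model.parameters()]
    stats = [
        (m.running_mean.copy(), m.running_var.copy())
        for m in _model._iter_modules(model)
        if isinstance(m, nn.BatchNorm2d)
    ]
    return params, stats


def _restore_state(model, state: tuple) -> None:
    params, stats = state
    for p, v in zip(model.parameters(), params):
        p.value[...] = v
    bns = [m for m in _model._iter_modules(model) if isinstance(m, nn.BatchNorm2d)]
    for b, (rm, rv) in zip(bns, stats):
        b.running_mean[...] = rm
        b.running_var[...] = rv


def _validation_loss(model, dataset: PairDataset, batch_size: int) -> float:
    if len(dataset) == 0:
        return float("nan")
    total, n = 0.0, 0
    model.set_training(False)
    for lo in range(0, len(dataset), batch_size):
        sl = slice(lo, lo + batch_size)
        loss, _ = _forward_loss(
            model, dataset.wide[sl], dataset.narrow[sl], dataset.labels[sl], None, False
        )
        total += loss * len(dataset.labels[sl])
        n += len(dataset.labels[sl])
    return total / n


def predict_batch(model, wide: np.ndarray, narrow: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Probability vectors for uint8 tile batches; no augmentation is applied."""
    if wide.ndim != 4 or narrow.ndim != 4 or len(wide) != len(narrow):
        raise ValueError("expected aligned (N, H, W, 3) uint8 tile batches")
    out = []
    for lo in range(0, len(wide), batch_size):
        sl = slice(lo, lo + batch_size)
        out.append(
            model.predict_proba(normalize_batch(wide[sl]), normalize_batch(narrow[sl]))
        )
    return np.concatenate(out, axis=0)


def evaluate(model, dataset: PairDataset, history: dict | None = None) -> EvalReport:
    probs = predict_batch(model, dataset.wide, dataset.narrow)
    preds = probs.argmax(axis=1)
    aucs, macro = roc_auc_ovr(dataset.labels, probs, list(dataset.class_names))
    cm = confusion_matrix_normalized(dataset.labels, preds, n_classes=probs.shape[1])
    prec, sens = precision_sensitivity(dataset.labels, preds, n_classes=probs.shape[1])
    return EvalReport(
        per_class_auc=aucs,
        macro_auc=macro,
        confusion=cm,
        precision=prec,
        sensitivity=sens,
        history=history,
    )


def cross_validate(
    build_model, dataset: PairDataset, config: TrainConfig
) -> tuple[list[EvalReport], EvalReport]:
    """Case-level k-fold cross-validation: folds are groups of slides, so no
    slide appears in both the train and validation side of any fold.
    Returns the per-fold reports and a summary carrying the mean +/- sd of
    the macro AUC across folds."""
    if config.folds < 2:
        raise ValueError("cross-validation requires folds >= 2")
    uniq = np.unique(dataset.slide_ids)
    if len(uniq) < config.folds:
        raise ValueError(f"need >= {config.folds} slides for {config.folds}-fold case-level CV")
    rng = np.random.default_rng(config.rng_seed)
    perm = rng.permutation(uniq)
    groups = np.array_split(perm, config.folds)
    reports = []
    for k, val_slides in enumerate(groups):
        val_mask = np.isin(dataset.slide_ids, val_slides)
        tr, va = dataset.subset(np.flatnonzero(~val_mask)), dataset.subset(np.flatnonzero(val_mask))
        fold_cfg = dataclasses.replace(config, rng_seed=config.rng_seed + k)
        model = build_model()
        model, hist = train(model, tr, fold_cfg, val_dataset=va)
        reports.append(evaluate(model, va, history=hist))
    macros = [r.macro_auc for r in reports]
    summary = EvalReport(
        per_class_auc={},
        macro_auc=float(np.mean(macros)),
        confusion=np.mean([r.confusion for r in reports], axis=0),
        precision=float(np.mean([r.precision for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        auc_mean=float(np.mean(macros)),
        auc_sd=float(np.std(macros, ddof=1)) if len(macros) > 1 else 0.0,
    )
    return reports, summary
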