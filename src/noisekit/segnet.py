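"""3D U-Net segmentation: label preprocessing, training, inference, postprocessing.

The training schedule: cross-entropy loss (with an ignore label) and the
Nadam optimizer; learning rate 1e-4, halved when the validation loss has not
decreased for 5 epochs; training stops when it has not decreased for 10
epochs; an epoch is a fixed number of patch iterations; periodically the
model is run over the entire training set and patch sampling is re-weighted
toward high-loss regions (hard-example mining); the checkpoint with the best
validation aorta Dice is returned.  Dropout 0.5 sits before the last and
second-to-last convolutions and conv kernels carry L2 weight decay 1e-3.

Label preprocessing ignores artery voxels far from the aorta and the
one-voxel boundary shell of every structure, since neither is a precise
annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import TrainingDiverged
from .nn import UNet3D, Nadam
from .nn.losses import IGNORE_LABEL, softmax_cross_entropy, voxel_cross_entropy
from .volio import LabelMask, Volume

# fixed affine HU normalisation (HU is a calibrated scale, so no per-volume
# statistics are needed and inference stays deterministic)
HU_SHIFT, HU_SCALE = 250.0, 250.0

_FOREGROUND = ("aorta", "lm", "rca")


# ---------------------------------------------------------------------------
# Label preprocessing
# ---------------------------------------------------------------------------

def preprocess_labels(mask: LabelMask, aorta_distance_cutoff: float = 20.0) -> LabelMask:
    """Mark imprecise voxels with the ignore label before training.

    LM/RCA voxels farther than ``aorta_distance_cutoff`` mm (Euclidean, in
    physical units) from the aorta mask are ignored, as is the one-voxel
    inner and outer boundary shell of every structure.  The aorta interior is
    untouched.
    """
    aorta = mask.class_mask("aorta")
    if not aorta.any():
        raise ValueError("mask contains no aorta voxels")
    labels = mask.labels.copy()

    if np.isfinite(aorta_distance_cutoff):
        dist = ndimage.distance_transform_edt(~aorta, sampling=mask.spacing)
        far = dist > aorta_distance_cutoff
        artery = mask.class_mask("lm") | mask.class_mask("rca")
        labels[far & artery] = IGNORE_LABEL

    for name in _FOREGROUND:
        m = mask.class_mask(name)
        if not m.any():
            continue
        inner = m & ~ndimage.binary_erosion(m)
        outer = ndimage.binary_dilation(m) & ~m
        labels[inner | outer] = IGNORE_LABEL
    return LabelMask(labels=labels, spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# Configuration and schedule
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters of the training schedule.

    Full-scale defaults follow the published schedule (20,000 iterations per
    epoch, hard mining every 500 epochs); :meth:`toy` returns the desk-scale
    configuration used for CPU training on phantoms.
    """

    initial_lr: float = 1e-4
    lr_factor: float = 0.5
    lr_patience_epochs: int = 5
    stop_patience_epochs: int = 10
    iterations_per_epoch: int = 20_000
    hardmine_every_epochs: int = 500
    l2_weight: float = 1e-3
    dropout_rate: float = 0.5
    patch_size: tuple[int, int, int] = (64, 96, 96)
    batch_size: int = 2
    levels: int = 4
    base_width: int = 32
    max_epochs: int | None = None
    infer_overlap: float = 0.5
    aorta_distance_cutoff: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.lr_patience_epochs < 1 or self.stop_patience_epochs < 1:
            raise ValueError("patience values must be >= 1")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def toy(cls, seed: int = 0, **overrides) -> "TrainingConfig":
        """Desk-scale config: small net and patches, short epochs."""
        kw = dict(iterations_per_epoch=200, hardmine_every_epochs=5,
                  patch_size=(16, 32, 32), batch_size=1, levels=2,
                  base_width=8, max_epochs=10, infer_overlap=0.25, seed=seed)
        kw.update(overrides)
        return cls(**kw)


class PlateauScheduler:
    """LR halving on validation-loss plateau, with early stopping.

    "Not decreased" means not strictly below the running best.  The
    non-improvement streak drives both actions: the LR is multiplied by
    ``factor`` whenever the streak reaches a multiple of ``lr_patience``, and
    ``update`` returns ``stop=True`` once it reaches ``stop_patience``.
    """

    def __init__(self, initial_lr: float, factor: float = 0.5,
                 lr_patience: int = 5, stop_patience: int = 10):
        self.lr = float(initial_lr)
        self.factor = factor
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self.streak = 0

    def update(self, val_loss: float) -> tuple[float, bool]:
        if val_loss < self.best:
            self.best = val_loss
            self.streak = 0
        else:
            self.streak += 1
            if self.streak % self.lr_patience == 0:
                self.lr *= self.factor
        return self.lr, self.streak >= self.stop_patience


@dataclass
class TrainedModel:
    """A trained network with its config, selection metric and training log."""

    net: UNet3D
    config: TrainingConfig
    best_val_dice: dict = field(default_factory=dict)
    training_log: list = field(default_factory=list)

    def save(self, path) -> None:
        """Checkpoint: weights as .npz plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        sidecar = {"net": self.net.config, "training": asdict(self.config),
                   "best_val_dice": self.best_val_dice,
                   "training_log": self.training_log}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = UNet3D(**sidecar["net"])
        with np.load(path.with_suffix(".npz")) as state:
            net.load_state_dict(dict(state))
        tc = sidecar["training"]
        tc["patch_size"] = tuple(tc["patch_size"])
        return cls(net=net, config=TrainingConfig(**tc),
                   best_val_dice=sidecar["best_val_dice"],
                   training_log=sidecar["training_log"])


# ---------------------------------------------------------------------------
# Patch plumbing
# ---------------------------------------------------------------------------

def _normalize(values: np.ndarray) -> np.ndarray:
    return ((values - HU_SHIFT) / HU_SCALE).astype(np.float32)


def _extract_patch(arr: np.ndarray, center, patch) -> np.ndarray:
    """Patch of size ``patch`` around ``center``, clipped inside ``arr``."""
    starts = [int(np.clip(c - p // 2, 0, max(0, s - p)))
              for c, p, s in zip(center, patch, arr.shape)]
    sl = tuple(slice(s, s + p) for s, p in zip(starts, patch))
    return arr[sl]


def _window_starts(size: int, patch: int, overlap: float) -> list[int]:
    if size <= patch:
        return [0]
    step = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def _infer_logits(net: UNet3D, values: np.ndarray,
                  patch, overlap: float) -> np.ndarray:
    """Average sliding-window logits over a (possibly padded) volume."""
    shape = values.shape
    pad = [(0, max(0, p - s)) for p, s in zip(patch, shape)]
    padded = np.pad(values, pad, mode="reflect") if any(b for _, b in pad) else values
    x = _normalize(padded)
    logits = np.zeros((net.n_classes,) + padded.shape, dtype=np.float32)
    counts = np.zeros(padded.shape, dtype=np.float32)
    for z0 in _window_starts(padded.shape[0], patch[0], overlap):
        for y0 in _window_starts(padded.shape[1], patch[1], overlap):
            for x0 in _window_starts(padded.shape[2], patch[2], overlap):
                sl = (slice(z0, z0 + patch[0]), slice(y0, y0 + patch[1]),
                      slice(x0, x0 + patch[2]))
                out = net.forward(x[sl][None, None], train=False)[0]
                logits[(slice(None),) + sl] += out
                counts[sl] += 1.0
    logits /= counts
    return logits[(slice(None),) + tuple(slice(0, s) for s in shape)]


def sliding_window_infer(model: TrainedModel, volume: Volume,
                         overlap: float | None = None) -> LabelMask:
    """Segment a whole volume by tiling patches and averaging their logits.

    Volumes smaller than the patch are reflect-padded then cropped back, so
    the output always has exactly the input shape.  Argmax ties resolve to
    the lowest class code.
    """
    cfg = model.config
    logits = _infer_logits(model.net, np.asarray(volume.values, dtype=np.float32),
                           cfg.patch_size,
                           cfg.infer_overlap if overlap is None else overlap)
    labels = np.argmax(logits, axis=0).astype(np.int64)
    return LabelMask(labels=labels, spacing=volume.spacing, origin=volume.origin)


# ---------------------------------------------------------------------------
# Metrics and postprocessing
# ---------------------------------------------------------------------------

def dice(pred: LabelMask, truth: LabelMask, class_name: str = "aorta") -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as 1.0."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    a = pred.class_mask(class_name)
    b = truth.class_mask(class_name)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


_CONN26 = np.ones((3, 3, 3), dtype=bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


def _largest_component(m: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(m, structure=_CONN26)
    if n <= 1:
        return m
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if candidates.size > 1:
        # tie-break: component whose minimum (z, y, x) index comes first
        # (first occurrence in C order is the lexicographic minimum)
        flat = lab.ravel()
        firsts = {c: np.argmax(flat == c) for c in candidates}
        keep = min(candidates, key=lambda c: firsts[c])
    else:
        keep = candidates[0]
    return lab == keep


def postprocess(mask: LabelMask) -> LabelMask:
    """Keep the largest 26-connected component per class and fill cavities.

    Classes are processed independently in the fixed order aorta, LM, RCA
    (first writer wins where filled regions would overlap); cavity filling
    uses a 6-connected background complement.  Idempotent.
    """
    out = np.zeros_like(mask.labels)
    for name in _FOREGROUND:
        m = mask.class_mask(name)
        if not m.any():
            continue
        m = _largest_component(m)
        m = ndimage.binary_fill_holes(m, structure=_CONN6)
        out[m & (out == 0)] = mask.class_codes[name]
    return LabelMask(labels=out, spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _PatchSampler:
    """Case- and voxel-weighted patch-center sampling with a uniform fallback."""

    def __init__(self, shapes, rng):
        self.rng = rng
        self.shapes = shapes
        self.case_p = np.full(len(shapes), 1.0 / len(shapes))
        self.voxel_cdfs = [None] * len(shapes)

    def reweight(self, loss_maps: list[np.ndarray]) -> None:
        means = np.array([float(m.mean()) for m in loss_maps])
        total = means.sum()
        self.case_p = (means / total) if total > 0 else \
            np.full(len(loss_maps), 1.0 / len(loss_maps))
        self.voxel_cdfs = []
        for m in loss_maps:
            w = m.ravel().astype(np.float64)
            w += 1e-6 * (w.max() if w.max() > 0 else 1.0)  # keep support full
            self.voxel_cdfs.append(np.cumsum(w / w.sum()))

    def draw(self) -> tuple[int, tuple[int, int, int]]:
        i = int(self.rng.choice(len(self.shapes), p=self.case_p))
        shape = self.shapes[i]
        cdf = self.voxel_cdfs[i]
        if cdf is None:
            center = tuple(int(self.rng.integers(0, s)) for s in shape)
        else:
            flat = int(np.searchsorted(cdf, self.rng.random()))
            center = tuple(int(c) for c in np.unravel_index(flat, shape))
        return i, center


def _full_volume_loss(net, values, targets, patch, overlap) -> tuple[float, np.ndarray]:
    logits = _infer_logits(net, values, patch, overlap)
    loss, _ = softmax_cross_entropy(logits[None], targets[None])
    voxel = voxel_cross_entropy(logits[None], targets[None])[0]
    return loss, voxel


def train(phantoms_train, phantoms_val, config: TrainingConfig,
          resume_from: TrainedModel | None = None) -> TrainedModel:
    """Train the U-Net on phantoms and return the best-validation-Dice model.

    ``phantoms_*`` are :class:`~noisekit.phantom.Phantom` objects (or any
    objects with ``volume``/``labels``).  Per epoch, ``iterations_per_epoch``
    batches are drawn; the validation loss drives LR halving and early
    stopping; every ``hardmine_every_epochs`` epochs per-voxel loss maps over
    the full training set re-weight patch sampling.  Deterministic given
    ``config.seed``.
    """
    if not phantoms_train or not phantoms_val:
        raise ValueError("train and validation sets must be non-empty")
    ids = {id(p) for p in phantoms_train}
    if any(id(p) in ids for p in phantoms_val):
        raise ValueError("train and validation sets must be disjoint")

    cfg = config
    train_vols = [np.asarray(p.volume.values, dtype=np.float32) for p in phantoms_train]
    train_targets = [preprocess_labels(p.labels, cfg.aorta_distance_cutoff).labels
                     for p in phantoms_train]
    val_vols = [np.asarray(p.volume.values, dtype=np.float32) for p in phantoms_val]
    val_targets = [preprocess_labels(p.labels, cfg.aorta_distance_cutoff).labels
                   for p in phantoms_val]

    net = UNet3D(in_channels=1, n_classes=4, levels=cfg.levels,
                 base_width=cfg.base_width, dropout_rate=cfg.dropout_rate,
                 seed=cfg.seed)
    epoch_offset = 0
    if resume_from is not None:
        net.load_state_dict(resume_from.net.state_dict())
        epoch_offset = len(resume_from.training_log)
    opt = Nadam(net.optimizer_params(), lr=cfg.initial_lr, l2=cfg.l2_weight)
    sched = PlateauScheduler(cfg.initial_lr, cfg.lr_factor,
                             cfg.lr_patience_epochs, cfg.stop_patience_epochs)
    rng = np.random.default_rng(cfg.seed + 10_000)
    sampler = _PatchSampler([v.shape for v in train_vols], rng)

    log: list[dict] = list(resume_from.training_log) if resume_from else []
    best = {"dice": -1.0, "state": None, "per_class": {}}
    epoch = 0
    while cfg.max_epochs is None or epoch < cfg.max_epochs:
        epoch += 1
        losses = []
        for _ in range(cfg.iterations_per_epoch):
            xs, ys = [], []
            for _ in range(cfg.batch_size):
                i, center = sampler.draw()
                xs.append(_extract_patch(train_vols[i], center, cfg.patch_size))
                ys.append(_extract_patch(train_targets[i], center, cfg.patch_size))
            x = _normalize(np.stack(xs))[:, None]
            y = np.stack(ys)
            logits = net.forward(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            losses.append(loss + opt.l2_penalty())

        val_losses, dices = [], {"aorta": [], "lm": [], "rca": []}
        for p, vol, tgt in zip(phantoms_val, val_vols, val_targets):
            vloss, _ = _full_volume_loss(net, vol, tgt, cfg.patch_size,
                                         cfg.infer_overlap)
            val_losses.append(vloss)
            pred_labels = np.argmax(
                _infer_logits(net, vol, cfg.patch_size, cfg.infer_overlap),
                axis=0).astype(np.int64)
            pred = LabelMask(labels=pred_labels, spacing=p.labels.spacing)
            for name in dices:
                dices[name].append(dice(pred, p.labels, name))
        val_loss = float(np.mean(val_losses))
        per_class = {k: float(np.mean(v)) for k, v in dices.items()}
        per_class["mean"] = float(np.mean([per_class[k] for k in _FOREGROUND]))

        lr_next, stop = sched.update(val_loss)
        log.append({"epoch": epoch + epoch_offset,
                    "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss, "val_dice_aorta": per_class["aorta"],
                    "val_dice_mean": per_class["mean"], "lr": opt.lr})
        # model selection: highest validation aorta Dice
        if per_class["aorta"] > best["dice"]:
            best = {"dice": per_class["aorta"], "state": net.state_dict(),
                    "per_class": per_class}
        opt.lr = lr_next

        if stop:
            break
        if cfg.hardmine_every_epochs and epoch % cfg.hardmine_every_epochs == 0:
            loss_maps = [_full_volume_loss(net, v, t, cfg.patch_size,
                                           cfg.infer_overlap)[1]
                         for v, t in zip(train_vols, train_targets)]
            sampler.reweight(loss_maps)

    if best["state"] is not None:
        net.load_state_dict(best["state"])
    return TrainedModel(net=net, config=cfg, best_val_dice=best["per_class"],
                        training_log=log)


def training_log_frame(model: TrainedModel):
    """Training log as a DataFrame (epoch, train_loss, val_loss, dice, lr)."""
    import pandas as pd
    return pd.DataFrame(model.training_log)
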