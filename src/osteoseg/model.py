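"""Slice-wise (2.5D) U-Net segmentation: training, prediction, thresholding.

A 2D U-Net is trained on individual slices and applied slice-by-slice
through a volume, trading full 3D context for a much smaller memory and
compute footprint — the standard 2.5D scheme for anisotropic MRI stacks
where in-plane resolution is much finer than the slice distance.  One binary
network is trained per bone.  The final-layer probability threshold is kept
explicit (default 0.5) because it is the calibration target of
:mod:`osteoseg.calibrate`.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, SGDMomentum, UNet2D, bce_loss, soft_dice_loss
from .io import ImageVolume, LabelVolume, ProbabilityVolume
from .preprocess import SliceDataset

__all__ = [
    "NetConfig",
    "TrainingRecord",
    "build_model",
    "dice_score",
    "train",
    "predict_volume",
    "apply_threshold",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

_LOSSES = {"soft_dice": soft_dice_loss, "bce": bce_loss}


@dataclass
class NetConfig:
    """Hyper-parameters of the slice-wise U-Net.

    Defaults follow the classic U-Net layout (4 encoder levels, 32 base
    filters doubling per level, 3x3 convolutions, 2x2 pooling) trained with
    momentum SGD; the loss defaults to soft Dice so the optimised quantity
    matches the monitored metric.  ``threshold`` is the final-layer
    probability cut-off; ``fusion_mode`` selects single-axis slice-wise
    inference or averaging of predictions run along all three grid axes.
    """

    depth: int = 4
    base_filters: int = 32
    loss: str = "soft_dice"  # soft_dice | bce | bce+dice
    optimizer: str = "sgd"  # sgd (momentum) | adam
    learning_rate: float = 1e-2
    momentum: float = 0.9
    batch_size: int = 8
    epochs: int = 70
    threshold: float = 0.5
    seed: int = 0
    fusion_mode: str = "single_axis"  # single_axis | tri_axis_majority
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.loss not in ("soft_dice", "bce", "bce+dice"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.fusion_mode not in ("single_axis", "tri_axis_majority"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")


@dataclass
class TrainingRecord:
    epoch: int
    loss: float
    train_dice: float  # percent
    val_dice: float  # percent


def build_model(config: NetConfig) -> UNet2D:
    """Fresh U-Net under the config's seed: biases exactly 0, He weights."""
    return UNet2D(
        depth=config.depth, base_filters=config.base_filters, in_channels=1, seed=config.seed
    )


def dice_score(S: np.ndarray, R: np.ndarray) -> float:
    """Dice overlap 2|S∩R| / (|S|+|R|) as a percentage.

    100 means perfect agreement.  Two empty masks agree perfectly and score
    100 — empty slices are common in bone segmentation and must not drag the
    average down.
    """
    S = np.asarray(S).astype(bool)
    R = np.asarray(R).astype(bool)
    if S.shape != R.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {R.shape}")
    denom = int(S.sum()) + int(R.sum())
    if denom == 0:
        return 100.0
    return 200.0 * int((S & R).sum()) / denom


def _mean_slice_dice(model: UNet2D, images: np.ndarray, masks: np.ndarray, batch: int = 16) -> float:
    scores = []
    for start in range(0, len(images), batch):
        x = images[start : start + batch, None, :, :] / 255.0
        p = model.forward(x)
        pred = p[:, 0] >= 0.5
        for k in range(len(x)):
            scores.append(dice_score(pred[k], masks[start + k]))
    return float(np.mean(scores)) if scores else 100.0


def _loss_fn(name: str):
    if name == "bce+dice":
        def combined(p, t):
            l1, g1 = soft_dice_loss(p, t)
            l2, g2 = bce_loss(p, t)
            return l1 + l2, g1 + g2

        return combined
    return _LOSSES[name]


def train(
    model: UNet2D,
    dataset: SliceDataset,
    val_dataset: SliceDataset | None,
    config: NetConfig,
) -> list[TrainingRecord]:
    """Train the slice-wise network, recording per-epoch train/val Dice.

    Slices are shuffled each epoch under the config seed.  Training aborts
    with a diagnostic if the loss goes non-finite; an optional early stop
    triggers when validation Dice has not improved for
    ``early_stop_patience`` epochs.
    """
    if dataset.n_slices == 0:
        raise ValueError("training dataset is empty")
    model.check_input(dataset.m, dataset.m)
    rng = np.random.default_rng(config.seed + 1)
    loss_fn = _loss_fn(config.loss)
    if config.optimizer == "sgd":
        opt = SGDMomentum(model.params(), lr=config.learning_rate, momentum=config.momentum)
    else:
        opt = Adam(model.params(), lr=config.learning_rate)

    records: list[TrainingRecord] = []
    best_val, since_best = -np.inf, 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(dataset.n_slices)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = dataset.images[idx][:, None, :, :] / 255.0
            t = dataset.masks[idx][:, None, :, :]
            p = model.forward(x, remember=True)
            loss, dp = loss_fn(p, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "reduce the learning rate"
                )
            model.backward(dp)
            opt.step(model.grads())
            epoch_loss += loss
            n_batches += 1
        train_dice = _mean_slice_dice(model, dataset.images, dataset.masks)
        val_dice = (
            _mean_slice_dice(model, val_dataset.images, val_dataset.masks)
            if val_dataset is not None and val_dataset.n_slices
            else float("nan")
        )
        records.append(
            TrainingRecord(
                epoch=epoch, loss=epoch_loss / max(n_batches, 1), train_dice=train_dice, val_dice=val_dice
            )
        )
        logger.info(
            "epoch %d: loss %.4f train Dice %.2f%% val Dice %.2f%%",
            epoch, records[-1].loss, train_dice, val_dice,
        )
        if config.early_stop_patience is not None and np.isfinite(val_dice):
            if val_dice > best_val + 1e-6:
                best_val, since_best = val_dice, 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    logger.info("early stop: val Dice plateau at epoch %d", epoch)
                    break
    return records


def _pad_to_multiple(sl: np.ndarray, mult: int):
    h, w = sl.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph == 0 and pw == 0:
        return sl, (0, 0)
    return np.pad(sl, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge"), (ph, pw)


def _predict_along_axis(model: UNet2D, voxels: np.ndarray, axis: int, batch: int) -> np.ndarray:
    vol = np.moveaxis(voxels, axis, 0)
    mult = model.required_multiple()
    out = np.empty(vol.shape, dtype=np.float32)
    for start in range(0, vol.shape[0], batch):
        x = vol[start : start + batch][:, None, :, :].astype(np.float32) / 255.0
        x, (ph, pw) = _pad_to_multiple(x, mult)
        p = model.forward(x)[:, 0]
        if ph or pw:
            p = p[:, : p.shape[1] - ph if ph else None, : p.shape[2] - pw if pw else None]
        out[start : start + batch] = p
    return np.moveaxis(out, 0, axis)


def predict_volume(model: UNet2D, volume: ImageVolume, config: NetConfig) -> ProbabilityVolume:
    """Predict a per-voxel foreground probability volume slice by slice.

    Input intensities are expected on the normalised [0, 255] scale produced
    by the preprocessing pipeline.  With ``fusion_mode='tri_axis_majority'``
    the network is run along each of the three grid axes (padding non-square
    slices as needed) and the three probability volumes are averaged.
    """
    voxels = np.asarray(volume.voxels, dtype=np.float32)
    if config.fusion_mode == "tri_axis_majority":
        acc = np.zeros(voxels.shape, dtype=np.float64)
        for axis in range(3):
            acc += _predict_along_axis(model, voxels, axis, config.batch_size)
        probs = acc / 3.0
    else:
        probs = _predict_along_axis(model, voxels, 0, config.batch_size)
    return ProbabilityVolume(
        probs=np.clip(probs, 0.0, 1.0),
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
    )


def apply_threshold(prob: ProbabilityVolume, tau: float) -> LabelVolume:
    """Binarise at the final-layer threshold: 1 where ``p >= tau``.

    Monotone by construction: raising tau can only shrink the mask.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie strictly in (0, 1)")
    mask = (prob.probs >= tau).astype(np.uint8)
    return LabelVolume(
        labels=mask,
        spacing_mm=prob.spacing_mm,
        origin_mm=prob.origin_mm,
        label_codes={"background": 0, "foreground": 1},
    )


def save_checkpoint(model: UNet2D, config: NetConfig, path) -> None:
    path = Path(path)
    state = model.state_dict()
    np.savez_compressed(path, __config__=np.array([repr(asdict(config))]), **state)


def load_checkpoint(path) -> tuple[UNet2D, NetConfig]:
    import ast

    with np.load(Path(path), allow_pickle=False) as data:
        cfg = NetConfig(**ast.literal_eval(str(data["__config__"][0])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    return UNet2D.from_state(state), cfg
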