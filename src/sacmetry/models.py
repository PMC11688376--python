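"""Segmentation model zoo, augmentation/cross-validation protocol, and a
desk-scale CPU training harness.

Four encoder-swapped architectures are provided, all on a ResNet50
backbone: ``unet``, ``unetpp`` (nested dense skips), ``deeplabv3`` (ASPP,
output stride 16), and ``resunet`` (UNet topology with residual decoder
blocks).  Decoder channel widths are (256, 128, 64, 32, 16).  Heads emit
two class logits (background/foreground); the public network output is the
single-channel softmax foreground probability at the input's spatial size.

The training protocol mirrors the reference study: Adam, learning rate
1e-4, batch size 2, Dice/Jaccard/BCE losses, 4x offline augmentation (one
45-degree rotation plus horizontal and vertical flips per image), 5-fold
stratified cross-validation, and early stopping when validation Dice
declines (patience 5, best checkpoint restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import _nn
from ._nn import SegmentationNet, Tensor, as_model_input

__all__ = [
    "ARCHITECTURES", "ModelSpec", "TrainConfig", "FoldSplit",
    "build_model", "count_trainable_params", "augment_training_set",
    "make_folds", "train", "predict_mask",
]

ARCHITECTURES = ("unet", "unetpp", "deeplabv3", "resunet")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture request: which decoder family on the ResNet50 encoder."""

    arch: str
    encoder: str = "resnet50"
    in_channels: int = 3
    out_channels: int = 1     # probability channels exposed to the caller
    pretrained: bool = False  # no weight download; random init only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; one of {ARCHITECTURES}")
        if self.encoder != "resnet50":
            raise ValueError("only the resnet50 encoder is supported")
        if self.in_channels != 3 or self.out_channels != 1:
            raise ValueError("models take 3-channel input and expose a "
                             "single-channel probability map")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    lr: float = 1e-4
    batch_size: int = 2
    optimizer: str = "adam"
    loss: str = "dl"          # dl | jl | bcel
    max_epochs: int = 50
    patience: int = 5         # early stop: epochs without val-Dice improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.loss not in _nn.TENSOR_LOSSES:
            raise ValueError(f"loss must be one of {tuple(_nn.TENSOR_LOSSES)}")


@dataclass(frozen=True)
class FoldSplit:
    """Stratified k-fold assignment: ``assignments[i]`` is item i's fold."""

    k: int
    assignments: np.ndarray

    def iter_splits(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (train_ids, test_ids) for each of the k iterations."""
        for fold in range(self.k):
            test = np.flatnonzero(self.assignments == fold)
            train_ids = np.flatnonzero(self.assignments != fold)
            yield train_ids, test


def build_model(spec: ModelSpec | str, seed: int | None = None) -> SegmentationNet:
    """Instantiate an architecture with deterministic random initialization.

    The network maps a (batch, 3, H, W) input (H, W divisible by 32) to a
    (batch, 1, H, W) probability map; see :class:`sacmetry._nn.SegmentationNet`.
    """
    if isinstance(spec, str):
        spec = ModelSpec(arch=spec)
    if seed is not None:
        spec = replace(spec, seed=seed)
    return _nn.build_net(spec.arch, seed=spec.seed)


def count_trainable_params(net: SegmentationNet) -> int:
    """Sum of element counts over all trainable parameters."""
    return int(sum(p.data.size for p in net.parameters()))


def _rotate45(image: np.ndarray, order: int) -> np.ndarray:
    return ndimage.rotate(image, 45.0, reshape=False, order=order, cval=0.0,
                          prefilter=order > 1)


def augment_training_set(images: Sequence[np.ndarray],
                         masks: Sequence[np.ndarray]
                         ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Offline 4x augmentation: original + 45-degree rotation + h-flip + v-flip.

    The identical geometric transform is applied to each image and its mask;
    rotations use bilinear interpolation for images and nearest-neighbor for
    masks (fill 0, output size preserved), so masks stay strictly binary.
    """
    images = list(images)
    masks = list(masks)
    if len(images) != len(masks):
        raise ValueError(f"unpaired inputs: {len(images)} images vs "
                         f"{len(masks)} masks")
    if not images:
        raise ValueError("need at least one image/mask pair")
    out_images: list[np.ndarray] = []
    out_masks: list[np.ndarray] = []
    for img, msk in zip(images, masks):
        img = np.asarray(img)
        msk = np.asarray(msk)
        if img.shape != msk.shape:
            raise ValueError("image and mask dimensions differ")
        out_images += [img, _rotate45(img, order=1), img[:, ::-1], img[::-1, :]]
        out_masks += [msk, _rotate45(msk, order=0), msk[:, ::-1], msk[::-1, :]]
    return out_images, out_masks


def make_folds(labels: Sequence, k: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified k-fold partition of items by class label.

    Folds have size ``n // k`` or ``n // k + 1`` and per-fold class counts
    within one item of the global fraction; reproducible under ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(n), labels)):
        assignments[test] = fold
    return FoldSplit(k=k, assignments=assignments)


def _epoch_metrics(net: SegmentationNet, images: np.ndarray, masks: np.ndarray,
                   loss_name: str, batch_size: int) -> tuple[float, float]:
    """Loss and hard Dice over a dataset in eval mode (no gradient)."""
    from .metrics import region_scores

    loss_fn = _nn.TENSOR_LOSSES[loss_name]
    losses, dices = [], []
    for lo in range(0, images.shape[0], batch_size):
        xb = as_model_input(images[lo:lo + batch_size])
        yb = masks[lo:lo + batch_size][:, None]
        p = net.forward_proba(Tensor(xb))
        losses.append(float(loss_fn(p, yb).data))
        for j in range(yb.shape[0]):
            dices.append(region_scores(yb[j, 0], p.data[j, 0] >= 0.5).dice)
    return float(np.mean(losses)), float(np.mean(dices))


def train(net: SegmentationNet,
          train_data: tuple[np.ndarray, np.ndarray],
          config: TrainConfig = TrainConfig(),
          val_data: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> tuple[pd.DataFrame, SegmentationNet]:
    """Desk-scale CPU training loop with optional early stopping.

    Parameters
    ----------
    net : SegmentationNet
        Model to train (modified in place; the best-validation weights are
        restored before returning when validation data is given).
    train_data, val_data : (images, masks)
        ``images`` float arrays (N, H, W) in [0, 1]; ``masks`` binary
        (N, H, W).  Grayscale is replicated to 3 channels internally.
    config : TrainConfig
        Optimizer/loss settings; ``patience`` epochs without a new best
        validation Dice stop the run early.

    Returns
    -------
    history : pandas.DataFrame
        One row per epoch: train/val loss and Dice.
    net : SegmentationNet
        The trained network (best checkpoint when validating).
    """
    images, masks = train_data
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if images.shape[0] == 0:
        raise ValueError("empty training data")
    if images.shape != masks.shape:
        raise ValueError("images and masks must align")

    rng = np.random.default_rng(config.seed)
    optimizer = _nn.Adam(net.parameters(), lr=config.lr)
    loss_fn = _nn.TENSOR_LOSSES[config.loss]
    from .metrics import region_scores

    rows = []
    best_val = -np.inf
    best_state = None
    stale = 0
    for epoch in range(config.max_epochs):
        net.train()
        order = rng.permutation(images.shape[0])
        ep_losses, ep_dices = [], []
        for lo in range(0, order.size, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb = as_model_input(images[idx])
            yb = masks[idx][:, None]
            optimizer.zero_grad()
            p = net.forward_proba(Tensor(xb))
            loss = loss_fn(p, yb)
            loss.backward()
            optimizer.step()
            ep_losses.append(float(loss.data))
            for j in range(yb.shape[0]):
                ep_dices.append(region_scores(yb[j, 0], p.data[j, 0] >= 0.5).dice)
        row = {"epoch": epoch + 1,
               "train_loss": float(np.mean(ep_losses)),
               "train_dice": float(np.mean(ep_dices)),
               "val_loss": np.nan, "val_dice": np.nan}
        if val_data is not None:
            net.eval()
            vl, vd = _epoch_metrics(net, np.asarray(val_data[0], dtype=np.float32),
                                    np.asarray(val_data[1], dtype=np.float32),
                                    config.loss, config.batch_size)
            row["val_loss"], row["val_dice"] = vl, vd
            if vd > best_val:
                best_val, best_state, stale = vd, net.state_dict(), 0
            else:
                stale += 1
        rows.append(row)
        if val_data is not None and stale > config.patience:
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    net.eval()
    return pd.DataFrame(rows), net


def predict_mask(net: SegmentationNet, image: np.ndarray,
                 threshold: float = 0.5) -> np.ndarray:
    """Binarize the network's probability map (``>= threshold`` is foreground)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    proba = net.predict_proba(image)
    mask = (proba >= threshold).astype(np.uint8)
    return mask[0] if np.asarray(image).ndim == 2 else mask
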