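"""Building, training, and running the 3D classifiers.

Label convention: class index 1 is "interaction", so positive examples are
one-hot encoded as [0, 1] and negatives as [1, 0]; ``p_positive`` is the
softmax output at index 1.  Training follows the reference recipe: initial
learning rate 1e-5, decoupled weight decay 1e-4, categorical cross-entropy,
per-epoch shuffling, batch size 32, 40 epochs, with per-example rotation
(uniform over the 24 cube rotations) and bounded displacement augmentation.
One trained model sees exactly one encoding; checkpoints carry the encoding
tag and refuse mismatched grids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .augment import enumerate_rotations, random_integer_shift, \
    rotate_values
from .nn import AdamW, VoxelNet
from .tensorize import VoxelGrid

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "densenet3d"
    n_blocks: int = 4
    convs_per_block: int = 4
    dropout_rate: float = 0.2
    base_filters: int = 16
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    epochs: int = 40
    batch_size: int = 32
    grid_side: int = 64
    in_channels: int = 8
    max_shift_cells: int = 6
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ModelError("dropout_rate must be in [0, 1)")
        for name in ("n_blocks", "convs_per_block", "base_filters",
                     "epochs", "batch_size", "grid_side", "in_channels"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")


@dataclass(frozen=True)
class PredictionResult:
    pair_key: tuple
    p_negative: float
    p_positive: float
    model_index: int = 1


def build_network(cfg: ModelConfig, resnet_shortcut: bool = True) -> VoxelNet:
    """Instantiate the configured backbone and log its parameter count."""
    net = VoxelNet(
        backbone=cfg.backbone, in_channels=cfg.in_channels,
        grid_side=cfg.grid_side, n_blocks=cfg.n_blocks,
        convs_per_block=cfg.convs_per_block, base_filters=cfg.base_filters,
        dropout_rate=cfg.dropout_rate, seed=cfg.seed,
        resnet_shortcut=resnet_shortcut)
    logger.info("%s built with %d trainable parameters", cfg.backbone,
                net.n_parameters)
    return net


def _augment_batch(x: np.ndarray, rotations, rng: np.random.Generator,
                   max_shift_cells: int) -> np.ndarray:
    """Per-example random rotation and integer-cell displacement.

    Rotations permute cells exactly.  The displacement here is the
    cached-tensor approximation (integer shifts with zero fill) of the
    re-render-at-shifted-center scheme; pipelines that keep structures
    around can re-render instead via ``augment.random_displacement``.
    """
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        o = rotations[rng.integers(len(rotations))]
        g = rotate_values(x[i], o)
        if max_shift_cells > 0:
            g = random_integer_shift(g, max_shift_cells, rng)
        out[i] = g
    return out


def train(net: VoxelNet, train_items, cfg: ModelConfig,
          augmentation: bool = True,
          stop_at_train_acc: float | None = None) -> list[dict]:
    """Train in place; returns the per-epoch history.

    ``train_items`` is a sequence of (grid_values, label) with label in
    {0, 1}.  Raises on a single-class training set.  Deterministic given
    ``cfg.seed`` (a single NumPy RNG drives shuffling, augmentation and
    dropout).
    """
    x = np.stack([np.asarray(g, dtype=np.float32) for g, _ in train_items])
    y = np.asarray([lbl for _, lbl in train_items], dtype=int)
    if len(set(y.tolist())) < 2:
        raise ModelError("training set must contain both classes")
    onehot = np.zeros((len(y), 2), dtype=np.float32)
    onehot[np.arange(len(y)), y] = 1.0  # positive -> [0, 1]

    rng = np.random.default_rng(cfg.seed)
    for block in net.blocks:  # route dropout through the training RNG
        for drop in getattr(block, "drops", []):
            drop.rng = rng
    rotations = enumerate_rotations()
    opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)

    history: list[dict] = []
    net.train_mode(True)
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(y))
            losses, correct = [], 0
            for start in range(0, len(y), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = x[idx]
                if augmentation:
                    xb = _augment_batch(xb, rotations, rng,
                                        cfg.max_shift_cells)
                loss = net.loss_and_grad(xb, onehot[idx])
                opt.step()
                losses.append(loss)
            probs = _batched_proba(net, x, cfg.batch_size)
            correct = int(((probs[:, 1] >= 0.5).astype(int) == y).sum())
            rec = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "train_acc": correct / len(y)}
            history.append(rec)
            logger.info("epoch %d: loss %.4f acc %.3f", epoch, rec["loss"],
                        rec["train_acc"])
            if stop_at_train_acc is not None \
                    and rec["train_acc"] >= stop_at_train_acc:
                break
    finally:
        net.train_mode(False)
    return history


def _batched_proba(net: VoxelNet, x: np.ndarray, batch_size: int) -> np.ndarray:
    return np.concatenate([net.predict_proba(x[i:i + batch_size])
                           for i in range(0, len(x), batch_size)])


def predict(net: VoxelNet, grid, pair_key=("", ""),
            model_index: int = 1) -> PredictionResult:
    """Classify one voxel grid (evaluation mode, deterministic)."""
    values = grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)
    if values.shape != (net.grid_side,) * 3 + (net.in_channels,):
        raise ModelError(
            f"grid shape {values.shape} does not match network input "
            f"{(net.grid_side,) * 3 + (net.in_channels,)}")
    p = net.predict_proba(values[None].astype(np.float32))[0]
    return PredictionResult(pair_key=tuple(pair_key),
                            p_negative=float(p[0]), p_positive=float(p[1]),
                            model_index=model_index)


def save_checkpoint(path, net: VoxelNet, cfg: ModelConfig,
                    encoding: str, history=None) -> None:
    meta = {"config": asdict(cfg), "encoding": encoding,
            "history": history or []}
    state = net.state_arrays()
    state["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> tuple[VoxelNet, ModelConfig, str]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        cfg = ModelConfig(**meta["config"])
        net = build_network(cfg)
        net.load_state_arrays({k: data[k] for k in data.files if k != "meta"})
    return net, cfg, meta["encoding"]


def predict_checked(net: VoxelNet, grid: VoxelGrid, encoding: str,
                    **kwargs) -> PredictionResult:
    """Predict, refusing a grid whose encoding mismatches the checkpoint's."""
    if grid.encoding != encoding:
        raise ModelError(
            f"grid encoding {grid.encoding!r} does not match the model's "
            f"training encoding {encoding!r}")
    return predict(net, grid, **kwargs)
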