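"""3D DenseNet / ResNet classifier networks.

Architecture: four backbone blocks of four 3x3x3 convolution layers each,
every convolution followed by dropout (rate 0.2).  ResNet blocks add the
block input to the block output through a shortcut (1x1x1 projection when
channel counts differ); DenseNet blocks concatenate the block input and all
earlier layer outputs into each later layer.  Each block output passes
batch normalization then ReLU.  Blocks 2-4 receive the previous block's
output downsampled by 2x2x2 average pooling.  The head is a global 3D max
pool feeding a dense layer with 2-way softmax, so the output reads as
[P(no interaction), P(interaction)].
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool3D, BatchNorm, Conv3D, Dense, Dropout,
                     GlobalMaxPool3D, Layer, ReLU, softmax,
                     softmax_cross_entropy)


class DenseBlock(Layer):
    """Four convolutions with dense connectivity (growth-rate filters)."""

    def __init__(self, in_channels: int, growth: int, n_convs: int,
                 dropout_rate: float, rng: np.random.Generator):
        self.convs, self.drops = [], []
        ch = in_channels
        for _ in range(n_convs):
            self.convs.append(Conv3D(ch, growth, rng))
            self.drops.append(Dropout(dropout_rate, rng))
            ch += growth
        self.out_channels = ch
        self._split = None

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()]

    @property
    def training(self):
        return self.convs[0].training

    @training.setter
    def training(self, flag):
        for lyr in self.convs + self.drops:
            lyr.training = flag

    def forward(self, x):
        feats = [x]
        for conv, drop in zip(self.convs, self.drops):
            inp = np.concatenate(feats, axis=-1)
            feats.append(drop.forward(conv.forward(inp)))
        self._split = [f.shape[-1] for f in feats]
        return np.concatenate(feats, axis=-1)

    def backward(self, dy):
        bounds = np.cumsum(self._split)
        d_feats = np.split(dy, bounds[:-1], axis=-1)
        d_feats = [d.copy() for d in d_feats]
        for i in range(len(self.convs) - 1, -1, -1):
            d_out = self.drops[i].backward(d_feats[i + 1])
            d_inp = self.convs[i].backward(d_out)
            in_bounds = np.cumsum(self._split[:i + 1])
            for j, dseg in enumerate(np.split(d_inp, in_bounds[:-1], axis=-1)):
                d_feats[j] += dseg
        return d_feats[0]


class ResBlock(Layer):
    """Four convolutions with an additive input shortcut.

    The shortcut is the identity when channel counts match, else a 1x1x1
    projection.  ``shortcut=False`` disables it (plain conv stack), kept
    for ablation checks.
    """

    def __init__(self, in_channels: int, filters: int, n_convs: int,
                 dropout_rate: float, rng: np.random.Generator,
                 shortcut: bool = True):
        self.convs, self.drops = [], []
        ch = in_channels
        for _ in range(n_convs):
            self.convs.append(Conv3D(ch, filters, rng))
            self.drops.append(Dropout(dropout_rate, rng))
            ch = filters
        self.use_shortcut = shortcut
        self.proj = (Conv3D(in_channels, filters, rng, kernel=1)
                     if shortcut and in_channels != filters else None)
        self.out_channels = filters

    def parameters(self):
        out = [p for c in self.convs for p in c.parameters()]
        if self.proj is not None:
            out += self.proj.parameters()
        return out

    @property
    def training(self):
        return self.convs[0].training

    @training.setter
    def training(self, flag):
        for lyr in self.convs + self.drops:
            lyr.training = flag
        if self.proj is not None:
            self.proj.training = flag

    def forward(self, x):
        h = x
        for conv, drop in zip(self.convs, self.drops):
            h = drop.forward(conv.forward(h))
        if not self.use_shortcut:
            return h
        sc = self.proj.forward(x) if self.proj is not None else x
        return h + sc

    def backward(self, dy):
        dx_short = 0.0
        if self.use_shortcut:
            dx_short = (self.proj.backward(dy) if self.proj is not None
                        else dy)
        dh = dy
        for conv, drop in zip(reversed(self.convs), reversed(self.drops)):
            dh = conv.backward(drop.backward(dh))
        return dh + dx_short


class VoxelNet:
    """The full classifier: blocks + transitions + head.

    ``backbone`` is "densenet3d" or "resnet3d".  ``base_filters`` is the
    DenseNet growth rate / ResNet block width.
    """

    def __init__(self, backbone: str, in_channels: int = 8,
                 grid_side: int = 64, n_blocks: int = 4,
                 convs_per_block: int = 4, base_filters: int = 16,
                 dropout_rate: float = 0.2, n_classes: int = 2,
                 seed: int = 0, resnet_shortcut: bool = True):
        if backbone not in ("densenet3d", "resnet3d"):
            raise ValueError(f"unknown backbone {backbone!r}")
        if grid_side < 2 ** (n_blocks - 1):
            raise ValueError("grid too small for the transition poolings")
        rng = np.random.default_rng(seed)
        self.backbone = backbone
        self.grid_side = grid_side
        self.in_channels = in_channels
        self.blocks, self.norms, self.acts, self.pools = [], [], [], []
        ch = in_channels
        for b in range(n_blocks):
            if b > 0:
                self.pools.append(AvgPool3D())
            if backbone == "densenet3d":
                block = DenseBlock(ch, base_filters, convs_per_block,
                                   dropout_rate, rng)
            else:
                block = ResBlock(ch, base_filters, convs_per_block,
                                 dropout_rate, rng,
                                 shortcut=resnet_shortcut)
            ch = block.out_channels
            self.blocks.append(block)
            self.norms.append(BatchNorm(ch))
            self.acts.append(ReLU())
        self.global_pool = GlobalMaxPool3D()
        self.head = Dense(ch, n_classes, rng)
        self._training = False

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        out = []
        for block, norm in zip(self.blocks, self.norms):
            out += block.parameters() + norm.parameters()
        out += self.head.parameters()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def train_mode(self, flag: bool = True):
        self._training = flag
        for block in self.blocks:
            block.training = flag
        for norm in self.norms:
            norm.training = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (N, n, n, n, C) batch."""
        if x.ndim != 5 or x.shape[1:] != (self.grid_side,) * 3 + (self.in_channels,):
            raise ValueError(
                f"expected input (N, {self.grid_side}, {self.grid_side}, "
                f"{self.grid_side}, {self.in_channels}), got {x.shape}")
        h = x.astype(np.float32)
        for b, (block, norm, act) in enumerate(
                zip(self.blocks, self.norms, self.acts)):
            if b > 0:
                h = self.pools[b - 1].forward(h)
            h = act.forward(norm.forward(block.forward(h)))
        h = self.global_pool.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dh = self.global_pool.backward(dh)
        for b in range(len(self.blocks) - 1, -1, -1):
            dh = self.blocks[b].backward(
                self.norms[b].backward(self.acts[b].backward(dh)))
            if b > 0:
                dh = self.pools[b - 1].backward(dh)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities in eval mode (dropout off, BN running stats)."""
        was_training = self._training
        self.train_mode(False)
        try:
            return softmax(self.forward(x))
        finally:
            self.train_mode(was_training)

    def loss_and_grad(self, x: np.ndarray, onehot: np.ndarray) -> float:
        self.zero_grad()
        logits = self.forward(x)
        loss, dlogits = softmax_cross_entropy(logits, onehot)
        self.backward(dlogits)
        return loss

    # -- (de)serialization -------------------------------------------------
    def state_arrays(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.value
        for i, norm in enumerate(self.norms):
            state[f"bn_{i}_mean"] = norm.running_mean
            state[f"bn_{i}_var"] = norm.running_var
        return state

    def load_state_arrays(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value = np.asarray(state[f"param_{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        for i, norm in enumerate(self.norms):
            norm.running_mean = np.asarray(state[f"bn_{i}_mean"],
                                           dtype=np.float32)
            norm.running_var = np.asarray(state[f"bn_{i}_var"],
                                          dtype=np.float32)
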