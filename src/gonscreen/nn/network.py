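"""Conv-net assembly, SGD training loop, and checkpoint (de)serialization.

Both backbones share the architecture contract required for class activation
mapping: every convolution is 3x3, the conv/pool trunk ends in global average
pooling, and a single fully connected layer maps the pooled features to the
two class logits.

``small_default`` is sized so that training on a few hundred 256x256 ROIs
completes in minutes on one CPU core: a 4x average-pool stem followed by four
conv blocks of widths 16/32/64/64 with 2x max-pools between.  ``vgg_like``
is a deeper variant (double-conv blocks, widths 32/64/128/128) for users with
real data and more compute; its conv stages can be initialized from stored
weights when available.
"""

from __future__ import annotations

import copy
import json

import numpy as np

from .layers import (
    AvgPool2D,
    Conv3x3,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool2D,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

BACKBONES = ("small_default", "vgg_like")


def build_backbone(name: str, rng: np.random.Generator, dropout_rate: float = 0.5,
                   n_classes: int = 2) -> list:
    """Layer list for a named backbone (input 256x256x3, output 2 logits)."""
    if name == "small_default":
        widths = [16, 32, 64, 64]
        layers = [AvgPool2D(4)]
        c_in = 3
        for i, c_out in enumerate(widths):
            layers += [Conv3x3(c_in, c_out, rng), ReLU()]
            if i < len(widths) - 1:
                layers.append(MaxPool2D(2))
            c_in = c_out
    elif name == "vgg_like":
        widths = [32, 64, 128, 128]
        layers = [AvgPool2D(2)]
        c_in = 3
        for i, c_out in enumerate(widths):
            layers += [Conv3x3(c_in, c_out, rng), ReLU(),
                       Conv3x3(c_out, c_out, rng), ReLU()]
            if i < len(widths) - 1:
                layers.append(MaxPool2D(2))
            c_in = c_out
    else:
        raise ValueError(f"unknown backbone {name!r}; choose from {BACKBONES}")
    layers += [GlobalAvgPool(), Dropout(dropout_rate), Dense(c_in, n_classes, rng)]
    return layers


class ConvNet:
    """A trainable conv net with a GAP + single-FC head.

    The head shape is load-bearing: class activation maps are computed by
    projecting the FC class weights onto the feature maps entering GAP.
    """

    def __init__(self, backbone: str, seed: int = 0, dropout_rate: float = 0.5):
        self.backbone = backbone
        self.seed = seed
        self.dropout_rate = dropout_rate
        ss = np.random.SeedSequence(seed)
        init_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
        self.layers = build_backbone(backbone, init_rng, dropout_rate)
        self._gap_index = next(
            i for i, l in enumerate(self.layers) if isinstance(l, GlobalAvgPool)
        )
        for l in self.layers:
            if isinstance(l, Dropout):
                l.set_rng(drop_rng)
        self._velocity = [
            [np.zeros_like(p) for p in l.params] for l in self.layers
        ]

    # -- introspection -----------------------------------------------------
    def conv_kernel_sizes(self) -> list[tuple[int, int]]:
        return [l.kernel_size for l in self.layers if isinstance(l, Conv3x3)]

    @property
    def fc_layer(self) -> Dense:
        fc = self.layers[-1]
        assert isinstance(fc, Dense)
        return fc

    def has_gap_fc_head(self) -> bool:
        tail = [l for l in self.layers[self._gap_index:]
                if not isinstance(l, Dropout)]
        return len(tail) == 2 and isinstance(tail[1], Dense)

    # -- forward / training ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Feature maps entering GAP, shape (n, h, w, c) — the CAM input."""
        for l in self.layers[: self._gap_index]:
            x = l.forward(x, train=False)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    def train_step(self, x, y, lr: float, momentum: float) -> float:
        logits = self.forward(x, train=True)
        loss, grad = softmax_cross_entropy(logits, y)
        for l in reversed(self.layers):
            grad = l.backward(grad)
        for l, vel in zip(self.layers, self._velocity):
            for p, g, v in zip(l.params, l.grads, vel):
                v *= momentum
                v -= lr * g
                p += v
        return loss

    def copy(self) -> "ConvNet":
        return copy.deepcopy(self)

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for i, l in enumerate(self.layers):
            for j, p in enumerate(l.params):
                arrays[f"layer{i}_param{j}"] = p
        meta = dict(backbone=self.backbone, seed=self.seed,
                    dropout_rate=self.dropout_rate,
                    class_order=["glaucoma", "normal"])
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "ConvNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        net = cls(meta["backbone"], meta["seed"], meta["dropout_rate"])
        for i, l in enumerate(net.layers):
            for j, p in enumerate(l.params):
                p[...] = data[f"layer{i}_param{j}"]
        return net
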