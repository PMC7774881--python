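"""LinkNet-style encoder-decoder for seven-channel boundary/seed prediction.

The encoder is a VGG16-style stack of 3x3 conv + batch-norm + ReLU blocks
(2, 2, 3, 3, 3 convolutions per stage) with 2x2 max pooling between
stages; the decoder mirrors it with nearest-neighbour upsampling, one conv
block per stage, and *additive* skip connections from each encoder stage
to the matching decoder stage. A final 1x1 convolution with a sigmoid head
emits seven probability planes. A ``width_multiplier`` < 1 shrinks every
stage width (the ``tiny`` preset uses 1/8) so the network trains on a CPU
in minutes; the full-width network is the production architecture.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    MaxPool2,
    ReLU,
    Sigmoid,
    UpsampleNearest2,
)

__all__ = ["ModelSpec", "TrainedModel", "build_model", "jaccard_loss", "jaccard_loss_grad"]

_VGG_WIDTHS = (64, 128, 256, 512, 512)
_VGG_DEPTHS = (2, 2, 3, 3, 3)


@dataclass
class ModelSpec:
    architecture: str = "linknet"
    encoder: str = "vgg16_style"  # {"vgg16_style", "tiny"}
    input_tile: int = 256
    out_channels: int = 7
    width_multiplier: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture != "linknet":
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.encoder not in ("vgg16_style", "tiny"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.out_channels != 7:
            raise ValueError("the pipeline requires exactly 7 output channels")
        if self.input_tile % 32 != 0:
            raise ValueError(
                f"input tile must be divisible by 32 (five 2x pooling stages), "
                f"got {self.input_tile}"
            )
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must lie in (0, 1]")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        wm = self.width_multiplier if self.encoder == "vgg16_style" else min(
            self.width_multiplier, 0.125
        )
        return tuple(max(4, int(round(w * wm))) for w in _VGG_WIDTHS)


def tiny_spec(input_tile: int = 64, rng_seed: int = 0) -> ModelSpec:
    """The CPU test-suite preset: 64-px tiles, 1/8-width encoder."""
    return ModelSpec(
        encoder="tiny", input_tile=input_tile, width_multiplier=0.125,
        rng_seed=rng_seed,
    )


class _ConvBlock:
    def __init__(self, c_in, c_out, rng):
        self.conv = Conv2d(c_in, c_out, 3, rng)
        self.bn = BatchNorm2d(c_out)
        self.act = ReLU()

    def forward(self, x, train=True):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))

    def layers(self):
        return (self.conv, self.bn)


class TrainedModel:
    """The network plus its training history and (de)serialization."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.history: list[dict] = []
        rng = np.random.default_rng(spec.rng_seed)
        widths = spec.stage_widths
        self.enc_stages: list[list[_ConvBlock]] = []
        c_prev = 1
        for width, depth in zip(widths, _VGG_DEPTHS):
            stage = []
            for _ in range(depth):
                stage.append(_ConvBlock(c_prev, width, rng))
                c_prev = width
            self.enc_stages.append(stage)
        self.pools = [MaxPool2() for _ in widths]
        self.ups = [UpsampleNearest2() for _ in widths]
        self.dec_blocks: list[_ConvBlock] = []
        c_prev = widths[-1]
        for width in reversed(widths):
            self.dec_blocks.append(_ConvBlock(c_prev, width, rng))
            c_prev = width
        self.head = Conv2d(widths[0], spec.out_channels, 1, rng)
        self.out_act = Sigmoid()

    # ---- plumbing -------------------------------------------------------
    def _blocks(self):
        for stage in self.enc_stages:
            yield from stage
        yield from self.dec_blocks

    def parameters(self):
        for i, block in enumerate(self._blocks()):
            for layer in block.layers():
                for name, value, grad in layer.params():
                    yield f"block{i}.{type(layer).__name__}.{name}", value, grad
        for name, value, grad in self.head.params():
            yield f"head.{name}", value, grad

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: value.copy() for name, value, _ in self.parameters()}
        for i, block in enumerate(self._blocks()):
            bn = block.bn
            state[f"block{i}.running_mean"] = bn.running_mean.copy()
            state[f"block{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value, _ in self.parameters():
            value[...] = state[name]
        for i, block in enumerate(self._blocks()):
            block.bn.running_mean[...] = state[f"block{i}.running_mean"]
            block.bn.running_var[...] = state[f"block{i}.running_var"]

    # ---- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) float32 in [0,1] -> (N, 7, H, W) probabilities."""
        skips = []
        h = x.astype(np.float32, copy=False)
        for stage, pool in zip(self.enc_stages, self.pools):
            for block in stage:
                h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            h = block.forward(h, train)
            h = h + skip
        logits = self.head.forward(h, train)
        return self.out_act.forward(logits, train)

    def backward(self, dprob: np.ndarray) -> None:
        d = self.out_act.backward(dprob.astype(np.float32, copy=False))
        d = self.head.backward(d)
        dskips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            dskips.append(d)  # additive skip passes gradient through unchanged
            d = block.backward(d)
            d = up.backward(d)
        dskips.reverse()  # dskips[i] pairs with encoder stage i (top-down order)
        for stage, pool, dskip in zip(
            reversed(self.enc_stages), reversed(self.pools), dskips
        ):
            d = pool.backward(d)
            d = d + dskip
            for block in reversed(stage):
                d = block.backward(d)

    def predict(self, tile: np.ndarray) -> np.ndarray:
        """Single tile (H, W) -> (7, H, W), inference mode."""
        out = self.forward(tile[None, None, :, :].astype(np.float32), train=False)
        return out[0]

    # ---- persistence ----------------------------------------------------
    def save(self, path: str | os.PathLike) -> None:
        path = os.fspath(path)
        np.savez_compressed(path, **self.state_dict())
        sidecar = {
            "model_spec": asdict(self.spec),
            "history": self.history,
        }
        with open(_sidecar_path(path), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedModel":
        path = os.fspath(path)
        with open(_sidecar_path(path)) as fh:
            sidecar = json.load(fh)
        model = cls(ModelSpec(**sidecar["model_spec"]))
        model.history = sidecar["history"]
        archive = path if path.endswith(".npz") else path + ".npz"
        with np.load(archive) as data:
            model.load_state_dict(dict(data))
        return model


def _sidecar_path(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"


def build_model(spec: ModelSpec) -> TrainedModel:
    """Construct an untrained network from its specification."""
    return TrainedModel(spec)


def jaccard_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    eps: float = 1.0,
    per_channel: bool = True,
) -> float:
    """Soft Jaccard (IoU) loss: 1 - mean over channels of
    (sum y*p + eps) / (sum y + sum p - sum y*p + eps).

    With ``per_channel=False`` the Jaccard index is computed once on the
    flattened seven-channel tensor instead of averaged across channels.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("shape mismatch between targets and predictions")
    axes = tuple(i for i in range(y.ndim) if not (per_channel and i == y.ndim - 3))
    inter = (y * p).sum(axis=axes)
    union = y.sum(axis=axes) + p.sum(axis=axes) - inter
    j = (inter + eps) / (union + eps)
    return float(1.0 - np.mean(j))


def jaccard_loss_grad(
    y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1.0, per_channel: bool = True
) -> np.ndarray:
    """d(loss)/d(y_pred) for the soft Jaccard loss above."""
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    axes = tuple(i for i in range(y.ndim) if not (per_channel and i == y.ndim - 3))
    inter = (y * p).sum(axis=axes, keepdims=True)
    union = y.sum(axis=axes, keepdims=True) + p.sum(axis=axes, keepdims=True) - inter
    n_terms = y.shape[y.ndim - 3] if per_channel else 1
    dj = (y * (union + eps) - (inter + eps) * (1.0 - y)) / (union + eps) ** 2
    return (-dj / n_terms).astype(np.float32)
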