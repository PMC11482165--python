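"""U-Net regressors mapping an N-channel B-scan block to a decorrelation map.

Two encoder-decoder variants share one implementation: the conventional
2D U-Net, and the proposed variant in which a squeeze-and-excitation
(SE) block follows every double-convolution block in both encoder and
decoder.  Each input channel is one of the N co-located B-scans, so the
SE gates learn which repeats carry the most decorrelation information.

The full-scale default (depth 4, 64 base features, SE reduction 16)
follows the standard U-Net/SE conventions; tests and the desk-scale
pipeline run a small variant (depth 2-3, 8-16 base features, r = 4)
that trains in seconds on one CPU.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass

import numpy as np

from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    InstanceNorm2d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
    SEBlock,
    Sigmoid,
    Upsample2d,
)

__all__ = [
    "ModelConfig",
    "SEBlockSpec",
    "ConfigurationError",
    "UNet2D",
    "se_block_forward",
    "unet_forward",
    "se_extra_parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` counts encoder levels (pooling stages); feature maps start
    at ``base_features`` and double per level.  ``se_enabled`` inserts an
    SE block (bottleneck reduction ``se_reduction``) after every
    double-convolution block.  ``final_activation`` is linear by default
    since targets are normalized decorrelation trained with MSE.  With
    ``pad_inputs`` the forward pass reflect-pads inputs whose spatial
    size is not divisible by 2**depth and crops the output back.
    """

    n_channels_in: int = 3
    depth: int = 4
    base_features: int = 64
    se_enabled: bool = False
    se_reduction: int = 16
    final_activation: str = "none"
    norm: str = "instance"
    pad_inputs: bool = False

    def __post_init__(self) -> None:
        if self.n_channels_in < 1 or self.depth < 1 or self.base_features < 1:
            raise ConfigurationError("n_channels_in, depth and base_features must be >= 1")
        if self.se_enabled and self.base_features % self.se_reduction != 0:
            raise ConfigurationError(
                f"base_features={self.base_features} must be divisible by "
                f"se_reduction={self.se_reduction} when SE is enabled"
            )
        if self.final_activation not in ("none", "sigmoid"):
            raise ConfigurationError("final_activation must be 'none' or 'sigmoid'")
        if self.norm not in ("instance", "batch"):
            raise ConfigurationError("norm must be 'instance' or 'batch'")


@dataclass(frozen=True)
class SEBlockSpec:
    """Channel count C and bottleneck reduction ratio r of one SE block."""

    channels: int
    reduction: int

    def __post_init__(self) -> None:
        if self.channels % self.reduction != 0:
            raise ConfigurationError(
                f"channels={self.channels} not divisible by reduction={self.reduction}"
            )


class _DoubleConv(Layer):
    """(conv3x3 → BN → ReLU) × 2, optionally followed by an SE block."""

    def __init__(self, c_in: int, c_out: int, se_reduction: int | None,
                 rng: np.random.Generator, norm: str = "instance"):
        norm_cls = InstanceNorm2d if norm == "instance" else BatchNorm2d
        self.layers: list[Layer] = [
            Conv2d(c_in, c_out, 3, rng),
            norm_cls(c_out),
            ReLU(),
            Conv2d(c_out, c_out, 3, rng),
            norm_cls(c_out),
            ReLU(),
        ]
        if se_reduction is not None:
            self.layers.append(SEBlock(c_out, se_reduction, rng))

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet2D:
    """Encoder-decoder network with skip connections.

    Encoder: ``depth`` double-conv blocks with 2×2 max pooling between
    them, features doubling per level; a bottleneck double-conv at the
    bottom.  Decoder: nearest ×2 upsampling, concatenation with the
    matching encoder skip, and a double-conv back down to the skip's
    width.  A 1×1 convolution maps to the single output channel.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_features
        red = config.se_reduction if config.se_enabled else None
        self.enc: list[_DoubleConv] = []
        c_in = config.n_channels_in
        feats = [f * 2**i for i in range(config.depth)]
        for c_out in feats:
            self.enc.append(_DoubleConv(c_in, c_out, red, rng, config.norm))
            c_in = c_out
        self.bottleneck = _DoubleConv(c_in, c_in * 2, red, rng, config.norm)
        self.dec: list[_DoubleConv] = []
        c_up = c_in * 2
        for c_skip in reversed(feats):
            self.dec.append(_DoubleConv(c_skip + c_up, c_skip, red, rng, config.norm))
            c_up = c_skip
        self.final = Conv2d(f, 1, 1, rng)
        self.final_act = Sigmoid() if config.final_activation == "sigmoid" else None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        blocks = self.enc + [self.bottleneck] + self.dec
        out = [p for blk in blocks for p in blk.params()]
        out += self.final.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ConfigurationError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ConfigurationError(f"shape mismatch {p.value.shape} vs {w.shape}")
            p.value[...] = w

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def _bn_layers(self) -> list[BatchNorm2d]:
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for blk in blocks for l in blk.layers if isinstance(l, BatchNorm2d)]

    def get_state(self) -> dict:
        """Weights plus BatchNorm running statistics (a restorable snapshot)."""
        return {
            "weights": self.get_weights(),
            "bn": [(l.running_mean.copy(), l.running_var.copy()) for l in self._bn_layers()],
        }

    def set_state(self, state: dict) -> None:
        self.set_weights(state["weights"])
        for l, (rm, rv) in zip(self._bn_layers(), state["bn"]):
            l.running_mean = rm.copy()
            l.running_var = rv.copy()

    def calibrate_bn(self, x: np.ndarray, batch_size: int = 4, max_batches: int = 16) -> None:
        """Set BN statistics to average batch moments over ``x`` (precise BN)."""
        bns = self._bn_layers()
        if not bns:
            return
        for l in bns:
            l.start_calibration()
        for start in range(0, min(len(x), max_batches * batch_size), batch_size):
            self(x[start : start + batch_size], train=True)
        for l in bns:
            l.finish_calibration()

    # -- forward / backward -------------------------------------------------
    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        div = 2**self.config.depth
        b, c, h, w = x.shape
        if c != self.config.n_channels_in:
            raise ConfigurationError(
                f"expected {self.config.n_channels_in} input channels, got {c}"
            )
        ph = pw = 0
        if h % div or w % div:
            if not self.config.pad_inputs:
                raise ConfigurationError(
                    f"spatial size ({h}, {w}) not divisible by 2**depth={div}; "
                    "enable pad_inputs to pad-and-crop"
                )
            ph, pw = (-h) % div, (-w) % div
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        self._pad = (h, w, ph, pw)

        self._pools = [MaxPool2d() for _ in self.enc]
        self._ups = [Upsample2d() for _ in self.dec]
        skips = []
        for blk, pool in zip(self.enc, self._pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for blk, up, skip in zip(self.dec, self._ups, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = blk.forward(np.concatenate([skip, x], axis=1), train)
        x = self.final.forward(x, train)
        if self.final_act is not None:
            x = self.final_act.forward(x, train)
        if ph or pw:
            x = x[:, :, :h, :w]
        return x

    def backward(self, dy: np.ndarray) -> None:
        h, w, ph, pw = self._pad
        if ph or pw:
            dy = np.pad(dy, ((0, 0), (0, 0), (0, ph), (0, pw)))
        if self.final_act is not None:
            dy = self.final_act.backward(dy)
        dy = self.final.backward(dy)
        dskips = []
        for blk, up, c_skip in zip(reversed(self.dec), reversed(self._ups), reversed(self._skip_channels)):
            dcat = blk.backward(dy)
            dskips.append(dcat[:, :c_skip])
            dy = up.backward(dcat[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        # dskips were collected shallowest-first; the encoder unwinds deepest-first
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self._pools), reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = blk.backward(dy)

    # -- SE diagnostics -----------------------------------------------------
    def se_blocks(self) -> list[SEBlock]:
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for blk in blocks for l in blk.layers if isinstance(l, SEBlock)]


def se_extra_parameter_count(config: ModelConfig) -> int:
    """Closed-form parameter overhead of enabling SE on a given topology.

    Each SE block on C channels adds two linear maps plus biases:
    C²/r + C²/r + C/r + C parameters.
    """
    f, r = config.base_features, config.se_reduction
    feats = [f * 2**i for i in range(config.depth)]
    channels = feats + [feats[-1] * 2] + list(reversed(feats))
    return sum(2 * c * c // r + c // r + c for c in channels)


def se_block_forward(features: np.ndarray, spec: SEBlockSpec, weights: dict[str, np.ndarray]) -> np.ndarray:
    """Functional SE block on a single (C, h, w) feature map.

    ``weights`` holds ``w1`` (C/r × C), ``b1``, ``w2`` (C × C/r), ``b2``.
    """
    blk = SEBlock(spec.channels, spec.reduction)
    blk.fc1.w.value[...] = weights["w1"]
    blk.fc1.b.value[...] = weights["b1"]
    blk.fc2.w.value[...] = weights["w2"]
    blk.fc2.b.value[...] = weights["b2"]
    return blk.forward(features[None], train=False)[0]


def unet_forward(instance: np.ndarray, config: ModelConfig, model: UNet2D | None = None) -> np.ndarray:
    """Functional forward pass: (N, h, w) instance → (1, h, w) map.

    Builds a freshly initialised network when no ``model`` carrying
    trained weights is supplied.
    """
    net = model if model is not None else UNet2D(config)
    return net(instance[None], train=False)[0]


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path: str | pathlib.Path, model: UNet2D, provenance: dict | None = None) -> None:
    arrays = {f"p{i}": w for i, w in enumerate(model.get_weights())}
    bn_state = {}
    for i, l in enumerate(model._bn_layers()):
        bn_state[f"rm{i}"] = l.running_mean
        bn_state[f"rv{i}"] = l.running_var
    meta = json.dumps({"config": asdict(model.config), "provenance": provenance or {}})
    np.savez(pathlib.Path(path), _meta=np.array(meta), **arrays, **bn_state)


def load_checkpoint(path: str | pathlib.Path) -> tuple[UNet2D, dict]:
    with np.load(pathlib.Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        config = ModelConfig(**meta["config"])
        model = UNet2D(config)
        model.set_weights([data[f"p{i}"] for i in range(len(model.params()))])
        for i, l in enumerate(model._bn_layers()):
            l.running_mean = data[f"rm{i}"]
            l.running_var = data[f"rv{i}"]
    return model, meta["provenance"]
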