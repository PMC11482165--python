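"""MSE training loop for the decorrelation U-Nets.

Optimisation follows the standard recipe for this task: Adam with a
small weight decay, mean-squared error between the predicted map and
the 10-frame label, and a reduce-on-plateau schedule that cuts the
learning rate by 10× after two consecutive epochs without validation
improvement.  The checkpoint with the lowest validation loss is
returned.  Given a seed, data order and initialisation are fixed, so a
run is exactly reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core_io import BScanBlock, DecorrelationMap, OCTVolume, normalize_intensity
from .dataset import LearningSet, TrainingPair
from .model import ModelConfig, UNet2D
from .nn.layers import Param

__all__ = [
    "TrainConfig",
    "TrainLog",
    "Adam",
    "ReduceLROnPlateau",
    "DivergenceError",
    "train_model",
    "predict_block",
    "predict_volume",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule hyper-parameters.

    Defaults are the full-scale recipe: batch size 2, 20 epochs,
    learning rate 5e-4, Adam weight decay 1e-5, plateau patience 2
    epochs with factor 0.1.  ``improvement_threshold`` is the relative
    validation-loss decrease that counts as an improvement.
    """

    batch_size: int = 2
    epochs: int = 20
    lr: float = 5e-4
    weight_decay: float = 1e-5
    plateau_patience: int = 2
    plateau_factor: float = 0.1
    improvement_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("batch_size, epochs, lr must be positive; weight_decay >= 0")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


@dataclass
class TrainLog:
    """One record per completed epoch, plus selection bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    wall_time_s: float = 0.0


class Adam:
    """Adam with decoupled-from-nothing (classic L2-style) weight decay."""

    def __init__(self, params: list[Param], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Cut the learning rate when the monitored loss stops improving.

    An epoch improves when its loss is below ``best * (1 - threshold)``.
    After ``patience`` consecutive non-improving epochs the rate is
    multiplied by ``factor`` and the counter resets (so a loss that
    stalls for exactly two epochs under the default patience drops the
    rate once, e.g. 5e-4 → 5e-5).
    """

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 2,
                 threshold: float = 1e-4, min_lr: float = 0.0):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> float:
        if loss < self.best * (1.0 - self.threshold):
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.lr


def _stack(pairs: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.instance for p in pairs])
    y = np.stack([p.label for p in pairs])[:, None]
    return x, y


def train_model(
    pairs: LearningSet,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[UNet2D, TrainLog]:
    """Fit a U-Net to instance→label pairs by MSE; return best-val weights.

    Raises :class:`DivergenceError` if the loss becomes non-finite.
    """
    if not pairs.train or not pairs.val:
        raise ValueError("train and validation splits must be non-empty")
    x_tr, y_tr = _stack(pairs.train)
    x_va, y_va = _stack(pairs.val)
    if x_tr.shape[1] != model_config.n_channels_in:
        raise ValueError(
            f"pairs have {x_tr.shape[1]} channels but model expects "
            f"{model_config.n_channels_in}"
        )

    rng = np.random.default_rng(train_config.seed)
    model = UNet2D(model_config, seed=train_config.seed)
    opt = Adam(model.params(), train_config.lr, train_config.weight_decay)
    sched = ReduceLROnPlateau(
        train_config.lr,
        factor=train_config.plateau_factor,
        patience=train_config.plateau_patience,
        threshold=train_config.improvement_threshold,
    )
    log = TrainLog()
    best_val = np.inf
    best_state = model.get_state()
    t0 = time.perf_counter()

    for _epoch in range(train_config.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            out = model(xb, train=True)
            resid = out - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(f"training loss became {loss} at step {opt.t}")
            model.zero_grad()
            model.backward(2.0 * resid / resid.size)
            opt.step()
            losses.append(loss)
        # re-estimate BN statistics over a fixed training slice so eval-mode
        # behaviour does not depend on which batches ended the epoch
        model.calibrate_bn(x_tr, train_config.batch_size)
        val = evaluate_mse(model, x_va, y_va, train_config.batch_size)
        if not np.isfinite(val):
            raise DivergenceError(f"validation loss became {val}")
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_state = model.get_state()
            log.best_epoch = _epoch
        opt.lr = sched.step(val)
        log.lr.append(opt.lr)

    model.set_state(best_state)
    log.wall_time_s = time.perf_counter() - t0
    return model, log


def evaluate_mse(model: UNet2D, x: np.ndarray, y: np.ndarray, batch_size: int = 4) -> float:
    """Mean squared error of the model over a pair set (eval mode)."""
    total, n = 0.0, 0
    for start in range(0, len(x), batch_size):
        out = model(x[start : start + batch_size], train=False)
        resid = out - y[start : start + batch_size]
        total += float((resid**2).sum())
        n += resid.size
    return total / n


def _tile_starts(extent: int, tile: int, stride: int) -> list[int]:
    if tile >= extent:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)
    return starts


def predict_block(
    model: UNet2D,
    block: BScanBlock,
    normalized: bool = False,
    tile: tuple[int, int] | None = None,
    tile_overlap: int = 8,
    z_start: int | None = None,
    tile_margin: int = 0,
) -> DecorrelationMap:
    """Predict a decorrelation map for one B-scan block.

    Normalizes intensity (unless already done) and feeds the first
    ``n_channels_in`` frames through the network in eval mode.  When
    ``tile`` is given (normally the training patch size), the image is
    covered by overlapping tiles of that size and overlapping outputs
    are averaged — channel statistics inside each tile then match what
    the network's BN layers and SE gates saw in training, which
    full-frame inference on a differently sized image would violate.
    With ``z_start`` (normally the training z-offset) only the depth
    window ``[z_start, z_start + tile_h)`` is predicted and rows outside
    it are zero: the network has seen no content from other depths, so
    its output there would be extrapolation, not reconstruction.
    The output is clamped at zero (decorrelation is non-negative).
    """
    n = model.config.n_channels_in
    if not normalized:
        block = normalize_intensity(block)
    x = block.frames[:n]
    h, w = x.shape[1:]
    if tile is None:
        out = model(x[None], train=False)[0, 0]
    else:
        th, tw = min(tile[0], h), min(tile[1], w)
        acc = np.zeros((h, w))
        cnt = np.ones((h, w)) * 1e-12
        if z_start is None:
            z_starts = _tile_starts(h, th, max(th - tile_overlap, 1))
        else:
            z_starts = [min(max(z_start, 0), h - th)]
        for z0 in z_starts:
            for x0 in _tile_starts(w, tw, max(tw - tile_overlap, 1)):
                pred = model(x[None, :, z0 : z0 + th, x0 : x0 + tw], train=False)[0, 0]
                # zero-padded convolutions distort a band at the tile border:
                # keep only the interior except where the tile meets the image
                # (or depth-window) edge
                mz0 = 0 if z0 == z_starts[0] else tile_margin
                mz1 = th if z0 == z_starts[-1] else th - tile_margin
                mx0 = 0 if x0 == 0 else tile_margin
                mx1 = tw if x0 + tw >= w else tw - tile_margin
                acc[z0 + mz0 : z0 + mz1, x0 + mx0 : x0 + mx1] += pred[mz0:mz1, mx0:mx1]
                cnt[z0 + mz0 : z0 + mz1, x0 + mx0 : x0 + mx1] += 1.0
        out = acc / cnt
    return DecorrelationMap(
        values=np.maximum(out, 0.0),
        y_index=block.y_index,
        source="unet_se" if model.config.se_enabled else "unet",
        n_used=n,
    )


def predict_volume(
    model: UNet2D,
    volume: OCTVolume,
    tile: tuple[int, int] | None = None,
    tile_overlap: int = 8,
    z_start: int | None = None,
    tile_margin: int = 0,
) -> list[DecorrelationMap]:
    return [
        predict_block(
            model, b, tile=tile, tile_overlap=tile_overlap, z_start=z_start,
            tile_margin=tile_margin,
        )
        for b in volume.blocks
    ]
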