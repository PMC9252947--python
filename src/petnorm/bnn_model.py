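"""Heteroscedastic U-Net regression of function (SUV) from anatomy.

The normative model: a 2-D U-Net maps a normalized anatomy slice to a
per-pixel predicted mean ``mu_i`` and log-variance ``s_i = log
sigma_i^2`` of the functional value, trained on normal scans only with
the heteroscedastic Gaussian negative log-likelihood

    L = mean_i [ 1/2 * exp(-s_i) * (y_i - mu_i)^2 + 1/2 * s_i ].

Because training data contain no lesions, the two heads estimate the
normal-population mean and variance of uptake given anatomy; the
variance head learns tissue-dependent spread (aleatoric uncertainty).
At inference, Monte-Carlo dropout can add an epistemic variance term:
total variance = mean of per-sample aleatoric variances + population
variance of per-sample means.

A mean-only variant (``predict_variance=False``) with a squared-error
loss serves as the non-probabilistic baseline.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from collections.abc import Sequence

import numpy as np

from .io_volumes import Volume, VolumePair, iter_axial_slices
from .nn import Adam, Conv2d, Dropout, MaxPool2, ReLU, Upsample2

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PredictiveMap",
    "TrainingHistory",
    "ScanRecord",
    "UNet",
    "build_unet",
    "heteroscedastic_loss",
    "train",
    "predict_distribution",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture and normalization settings.

    ``input_norm = (center, scale)`` is a fixed affine applied to anatomy
    values (``(x - center) / scale``); it is deliberately not per-slice,
    so no slice content leaks into the normative prediction.
    ``logvar_clamp`` bounds the log-variance head for numerical
    stability, and ``variance_floor`` (SUV^2) keeps Z-score denominators
    strictly positive.
    """

    depth: int = 3
    base_channels: int = 4
    dropout_rate: float = 0.0
    logvar_clamp: tuple[float, float] = (-10.0, 6.0)
    input_norm: tuple[float, float] = (-400.0, 500.0)
    variance_floor: float = 1e-6
    predict_variance: bool = True

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        lo, hi = self.logvar_clamp
        if not lo < hi:
            raise ValueError("logvar_clamp must satisfy lo < hi")
        if self.input_norm[1] <= 0:
            raise ValueError("input_norm scale must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``mse_warmup_epochs`` trains the mean head alone with a squared-error
    loss before switching on the heteroscedastic NLL.  Without it the NLL
    can collapse in high-variance regions: the variance head inflates,
    the 1/sigma^2 weight vanishes, and the mean head stops learning
    there.  Warm-up fits the mean under uniform weighting first, so the
    variance head then fits residuals around a sound mean.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    val_fraction: float = 0.1
    mse_warmup_epochs: int = 5
    lr_schedule: str = "cosine"  # "cosine" decay to ~0, or "constant"

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.mse_warmup_epochs < 0:
            raise ValueError("mse_warmup_epochs must be >= 0")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    @property
    def effective_warmup_epochs(self) -> int:
        """Warm-up never exceeds a quarter of the schedule."""
        return min(self.mse_warmup_epochs, self.epochs // 4)


@dataclasses.dataclass
class PredictiveMap:
    """Per-pixel predictive distribution: mean and decomposed variance."""

    mean: np.ndarray
    aleatoric_variance: np.ndarray
    epistemic_variance: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.mean.shape
            == self.aleatoric_variance.shape
            == self.epistemic_variance.shape
            == self.variance.shape
        ):
            raise ValueError("all PredictiveMap fields must share a shape")
        if np.any(self.variance <= 0):
            raise ValueError("variance must be strictly positive (floor not applied?)")
        diff = self.variance - (self.aleatoric_variance + self.epistemic_variance)
        # the floor may only raise the total above the sum of its parts
        if not np.all((np.abs(diff) <= 1e-6) | (diff > 0)):
            raise ValueError("variance != aleatoric + epistemic")


@dataclasses.dataclass
class TrainingHistory:
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ScanRecord:
    """One scan of a dataset: id, manifest role, and the image pair."""

    scan_id: str
    role: str
    pair: VolumePair


class ShapeError(ValueError):
    pass


class _ConvBlock:
    """(conv 3x3 -> ReLU) x2, with optional dropout after each ReLU."""

    def __init__(self, c_in, c_out, rng, dropout_rate=0.0, dtype=np.float32):
        self.conv1 = Conv2d(c_in, c_out, 3, rng=rng, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng, dtype=dtype)
        self.relu2 = ReLU()
        self.drop1 = Dropout(dropout_rate)
        self.drop2 = Dropout(dropout_rate)

    def forward(self, x, rng=None):
        x = self.drop1.forward(self.relu1.forward(self.conv1.forward(x)), rng)
        return self.drop2.forward(self.relu2.forward(self.conv2.forward(x)), rng)

    def backward(self, dy):
        dy = self.conv2.backward(self.relu2.backward(self.drop2.backward(dy)))
        return self.conv1.backward(self.relu1.backward(self.drop1.backward(dy)))

    def convs(self):
        return [self.conv1, self.conv2]


class UNet:
    """Encoder-decoder with skip connections and a 1- or 2-channel head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, dtype=np.float32):
        self.config = config
        c = config.base_channels
        d = config.depth
        self.dtype = dtype
        self.enc: list[_ConvBlock] = []
        self.pools: list[MaxPool2] = []
        c_in = 1
        for level in range(d - 1):
            c_out = c * 2**level
            self.enc.append(_ConvBlock(c_in, c_out, rng, dtype=dtype))
            self.pools.append(MaxPool2())
            c_in = c_out
        # dropout only in the deepest (bottleneck) block
        self.bottleneck = _ConvBlock(c_in, c * 2 ** (d - 1), rng,
                                     dropout_rate=config.dropout_rate, dtype=dtype)
        self.ups: list[Upsample2] = []
        self.dec: list[_ConvBlock] = []
        c_in = c * 2 ** (d - 1)
        for level in reversed(range(d - 1)):
            c_skip = c * 2**level
            self.ups.append(Upsample2())
            self.dec.append(_ConvBlock(c_in + c_skip, c_skip, rng, dtype=dtype))
            c_in = c_skip
        self.out_channels = 2 if config.predict_variance else 1
        self.head = Conv2d(c_in, self.out_channels, 1, rng=rng,
                           weight_scale=0.01, dtype=dtype)

    # -- plumbing ---------------------------------------------------------
    def convs(self) -> list[Conv2d]:
        out = []
        for blk in self.enc:
            out += blk.convs()
        out += self.bottleneck.convs()
        for blk in self.dec:
            out += blk.convs()
        out.append(self.head)
        return out

    def params(self):
        out = []
        for conv in self.convs():
            out += conv.params()
        return out

    def check_input(self, h: int, w: int) -> None:
        f = 2 ** (self.config.depth - 1)
        if h % f or w % f:
            raise ShapeError(
                f"input shape {(h, w)} not divisible by {f} "
                f"(depth {self.config.depth}); pad the slices to a multiple of {f}"
            )

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None
                ) -> np.ndarray:
        """x: (N, H, W, 1) normalized anatomy -> (N, H, W, out_channels)."""
        self.check_input(x.shape[1], x.shape[2])
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x, dropout_rng)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append((x.shape[-1], skip.shape[-1]))
            x = np.concatenate([x, skip], axis=-1)
            x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, dout: np.ndarray) -> None:
        dx = self.head.backward(dout)
        # decoder ran deepest-first, so walk it last-to-first; collect the
        # gradient flowing into each skip connection on the way up
        dskips = []
        for i in range(len(self.dec) - 1, -1, -1):
            dx = self.dec[i].backward(dx)
            c_up, _ = self._skip_channels[i]
            dskips.append(dx[..., c_up:])
            dx = self.ups[i].backward(dx[..., :c_up])
        dx = self.bottleneck.backward(dx)
        # the decoder was walked shallowest-first just above, so dskips[k]
        # already holds the gradient for enc[k]'s output
        for i in range(len(self.enc) - 1, -1, -1):
            dx = self.pools[i].backward(dx)
            dx = dx + dskips[i]
            dx = self.enc[i].backward(dx)


def build_unet(config: ModelConfig, seed: int | np.random.Generator = 0,
               dtype=np.float32) -> UNet:
    """Construct a U-Net with seeded He-normal initialization."""
    rng = np.random.default_rng(seed)
    return UNet(config, rng, dtype=dtype)


def heteroscedastic_loss(mean: np.ndarray, logvar: np.ndarray,
                         target: np.ndarray) -> float:
    """Gaussian NLL (up to the constant): mean of 1/2 e^{-s} r^2 + 1/2 s."""
    if not mean.shape == logvar.shape == target.shape:
        raise ValueError(
            f"shape mismatch: {mean.shape}, {logvar.shape}, {target.shape}"
        )
    r2 = (target - mean) ** 2
    return float(np.mean(0.5 * np.exp(-logvar) * r2 + 0.5 * logvar))


def _loss_and_grad(model: UNet, out: np.ndarray, target: np.ndarray,
                   mean_only: bool = False) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the network output (clamp-aware)."""
    n_pix = target.size
    mu = out[..., 0]
    dout = np.zeros_like(out)
    if model.config.predict_variance and not mean_only:
        lo, hi = model.config.logvar_clamp
        s_raw = out[..., 1]
        s = np.clip(s_raw, lo, hi)
        inv_var = np.exp(-s)
        r = mu - target
        loss = float(np.mean(0.5 * inv_var * r**2 + 0.5 * s))
        dout[..., 0] = inv_var * r / n_pix
        ds = 0.5 * (1.0 - inv_var * r**2) / n_pix
        dout[..., 1] = np.where((s_raw > lo) & (s_raw < hi), ds, 0.0)
    else:
        r = mu - target
        loss = float(np.mean(r**2))
        dout[..., 0] = 2.0 * r / n_pix
    return loss, dout


def slices_from_scans(records: Sequence[ScanRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all axial slices of the given scans: (anatomy, function) arrays."""
    xs, ys = [], []
    for rec in records:
        for sl in iter_axial_slices(rec.pair):
            xs.append(sl.anatomy_slice)
            ys.append(sl.function_slice)
    return np.stack(xs), np.stack(ys)


def train(
    model: UNet,
    dataset: Sequence[ScanRecord],
    config: TrainConfig,
    checkpoint_path: str | Path | None = None,
) -> tuple[UNet, TrainingHistory]:
    """Train on normal scans with the NLL (or MSE for mean-only models).

    Scans are split into train/validation groups scan-wise; per-epoch
    mean train loss and end-of-epoch validation loss are recorded.
    Deterministic given ``config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    for rec in dataset:
        if "abnormal" in rec.role:
            raise ValueError(
                f"scan {rec.scan_id} has role {rec.role!r}: training data "
                "must contain only normal scans"
            )
    rng = np.random.default_rng([config.seed, 17])
    dropout_rng = np.random.default_rng([config.seed, 23])

    n_scans = len(dataset)
    order = rng.permutation(n_scans)
    n_val = max(1, int(round(config.val_fraction * n_scans))) if n_scans > 1 else 0
    val_recs = [dataset[i] for i in order[:n_val]]
    train_recs = [dataset[i] for i in order[n_val:]]

    center, scale = model.config.input_norm
    x_train, y_train = slices_from_scans(train_recs)
    x_train = ((x_train - center) / scale).astype(model.dtype)[..., None]
    y_train = y_train.astype(model.dtype)
    if val_recs:
        x_val, y_val = slices_from_scans(val_recs)
        x_val = ((x_val - center) / scale).astype(model.dtype)[..., None]
        y_val = y_val.astype(model.dtype)
    else:
        x_val, y_val = x_train, y_train

    model.check_input(x_train.shape[1], x_train.shape[2])
    opt = Adam(model.params(), lr=config.learning_rate)
    history = TrainingHistory()
    n = len(x_train)
    bs = min(config.batch_size, n)
    warmup_epochs = config.effective_warmup_epochs
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / config.epochs)
            )
        warmup = epoch < warmup_epochs
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            out = model.forward(x_train[idx], dropout_rng=dropout_rng)
            loss, dout = _loss_and_grad(model, out, y_train[idx], mean_only=warmup)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss}; "
                    "lower the learning rate or tighten logvar_clamp"
                )
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(_eval_loss(model, x_val, y_val, bs))
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, train_config=config)
    return model, history


def _eval_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    losses, weights = [], []
    for start in range(0, len(x), batch):
        out = model.forward(x[start : start + batch])
        loss, _ = _loss_and_grad(model, out, y[start : start + batch])
        losses.append(loss)
        weights.append(len(x[start : start + batch]))
    return float(np.average(losses, weights=weights))


def predict_distribution(
    model: UNet,
    anatomy_slice: np.ndarray,
    mc_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> PredictiveMap:
    """Predictive mean/variance for one anatomy slice (raw units).

    ``mc_samples=1`` is the deterministic aleatoric-only mode.  With
    ``mc_samples=T > 1`` and dropout active, the mean is the average of
    the ``T`` sampled means, the aleatoric variance the average of the
    sampled variances, and the epistemic variance the population variance
    of the sampled means.
    """
    maps = predict_batch(model, anatomy_slice[None, ...], mc_samples, rng)
    return PredictiveMap(
        mean=maps.mean[0],
        aleatoric_variance=maps.aleatoric_variance[0],
        epistemic_variance=maps.epistemic_variance[0],
        variance=maps.variance[0],
    )


def predict_batch(
    model: UNet,
    anatomy_slices: np.ndarray,
    mc_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> PredictiveMap:
    """Vectorized :func:`predict_distribution` over a stack of slices."""
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    if not model.config.predict_variance:
        raise ValueError("model has no variance head; use predict_mean_batch")
    center, scale = model.config.input_norm
    x = ((np.asarray(anatomy_slices) - center) / scale).astype(model.dtype)[..., None]
    lo, hi = model.config.logvar_clamp
    floor = model.config.variance_floor
    if mc_samples == 1:
        out = model.forward(x)
        mean = out[..., 0].astype(np.float64)
        alea = np.exp(np.clip(out[..., 1], lo, hi)).astype(np.float64)
        epi = np.zeros_like(mean)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        mus, als = [], []
        for _ in range(mc_samples):
            dr = rng if model.config.dropout_rate > 0 else None
            out = model.forward(x, dropout_rng=dr)
            mus.append(out[..., 0].astype(np.float64))
            als.append(np.exp(np.clip(out[..., 1], lo, hi)).astype(np.float64))
        mus_arr = np.stack(mus)
        mean = mus_arr.mean(axis=0)
        alea = np.mean(als, axis=0)
        epi = np.mean(mus_arr**2, axis=0) - mean**2
        np.clip(epi, 0.0, None, out=epi)
    variance = np.maximum(alea + epi, floor)
    return PredictiveMap(mean=mean, aleatoric_variance=alea,
                         epistemic_variance=epi, variance=variance)


def predict_mean_batch(model: UNet, anatomy_slices: np.ndarray) -> np.ndarray:
    """Deterministic mean prediction of a mean-only (baseline) model."""
    center, scale = model.config.input_norm
    x = ((np.asarray(anatomy_slices) - center) / scale).astype(model.dtype)[..., None]
    return model.forward(x)[..., 0].astype(np.float64)


def predict_volume(
    model: UNet,
    anatomy: Volume,
    mc_samples: int = 1,
    rng: np.random.Generator | None = None,
) -> PredictiveMap:
    """Slice-wise prediction stacked back into (x, y, z) volumes."""
    slices = np.moveaxis(anatomy.data, 2, 0)  # (z, x, y)
    if model.config.predict_variance:
        maps = predict_batch(model, slices, mc_samples, rng)
        return PredictiveMap(
            mean=np.moveaxis(maps.mean, 0, 2),
            aleatoric_variance=np.moveaxis(maps.aleatoric_variance, 0, 2),
            epistemic_variance=np.moveaxis(maps.epistemic_variance, 0, 2),
            variance=np.moveaxis(maps.variance, 0, 2),
        )
    mean = np.moveaxis(predict_mean_batch(model, slices), 0, 2)
    floor = model.config.variance_floor
    ones = np.full_like(mean, floor)
    return PredictiveMap(mean=mean, aleatoric_variance=ones.copy(),
                         epistemic_variance=np.zeros_like(mean), variance=ones)


# -- checkpointing --------------------------------------------------------

def save_checkpoint(model: UNet, path: str | Path,
                    train_config: TrainConfig | None = None) -> None:
    arrays = {}
    for i, conv in enumerate(model.convs()):
        arrays[f"W{i}"] = conv.W
        arrays[f"b{i}"] = conv.b
    meta = {"model": dataclasses.asdict(model.config)}
    if train_config is not None:
        meta["train"] = dataclasses.asdict(train_config)
    np.savez(path, config_json=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["config_json"]).decode())
        cfg_dict = dict(meta["model"])
        for key in ("logvar_clamp", "input_norm"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        model = build_unet(config, seed=0)
        for i, conv in enumerate(model.convs()):
            conv.W = data[f"W{i}"].copy()
            conv.b = data[f"b{i}"].copy()
    return model
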