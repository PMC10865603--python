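"""The InsightSleepNet architecture for continuous-PPG sleep staging.

Five components in sequence: a causal local-attention module (one kernel
spanning 7 epochs, so each attention score sees the preceding ~3 minutes),
an InceptionTime feature extractor, a time-distributed dense layer, a stack
of dilated causal temporal blocks, and a 1x1 convolutional head producing
4-class logits per 30-s epoch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .nn.losses import softmax
from .preprocess import EpochizedInput


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults reproduce the full network.

    The attention width (124), inception-head width (256) and dense width
    (104) are the calibrated combination under which the default network
    has exactly 1,922,397 trainable parameters; see docs/methods.md.
    """

    n_classes: int = 4
    epoch_len: int = 1024
    n_epochs: int = 1200
    attention_channels: int = 124
    stem_channels: int = 32
    stem_kernel: int = 40
    stem_stride: int = 20
    inception_filters: tuple = (8, 16, 16, 32, 64, 128)
    inception_bottleneck: tuple = (8, 16, 16, 16, 32, 32)
    inception_kernels: tuple = (5, 11, 23)
    inception_out_channels: int = 256
    tdd_width: int = 104
    tcn_blocks: int = 5
    tcn_channels: int = 64
    tcn_kernel: int = 8
    tcn_dropout: float = 0.2
    seed: int = 0

    @property
    def attention_kernel(self) -> int:
        return 7 * self.epoch_len

    @property
    def inception_in_channels(self) -> tuple:
        ins = [self.stem_channels]
        for f in self.inception_filters[:-1]:
            ins.append(4 * f)
        return tuple(ins)

    @property
    def tcn_dilations(self) -> tuple:
        return tuple(2**i for i in range(self.tcn_blocks))

    def validate(self) -> None:
        if self.attention_kernel != 7 * self.epoch_len:
            raise ValueError("attention kernel must span exactly 7 epochs")
        n_blocks = len(self.inception_filters)
        if not (n_blocks == len(self.inception_bottleneck) == 6):
            raise ValueError("exactly 6 inception blocks are required")
        if (self.n_epochs * self.epoch_len) % self.stem_stride != 0:
            raise ValueError(
                "total input length must be divisible by the stem stride"
            )
        d = self.tcn_dilations
        if any(d[i + 1] != 2 * d[i] for i in range(len(d) - 1)) or d[0] != 1:
            raise ValueError("temporal dilations must double from 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def with_overrides(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    @classmethod
    def reduced(cls, n_epochs: int = 240, seed: int = 0) -> "ModelConfig":
        """A narrow configuration for CPU-scale experiments and tests."""
        return cls(
            n_epochs=n_epochs,
            attention_channels=4,
            stem_channels=8,
            inception_filters=(2, 4, 4, 8, 8, 16),
            inception_bottleneck=(2, 2, 2, 2, 4, 4),
            inception_out_channels=16,
            tdd_width=16,
            tcn_channels=16,
            seed=seed,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for k in ("inception_filters", "inception_bottleneck", "inception_kernels"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LogitsGrid:
    """Per-epoch pre-softmax scores f(x) of shape (n_epochs, n_classes)."""

    values: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return softmax(self.values, axis=1)


@dataclass
class AttentionMap:
    """Sample-resolution sigmoid attention plus its per-epoch mean."""

    per_sample: np.ndarray
    per_epoch: np.ndarray
    normalized: np.ndarray


class LocalAttention(nn.Module):
    """Causal conv (k = 7 epochs) -> 1x1 conv -> sigmoid -> gate the input."""

    def __init__(self, config: ModelConfig, rng, dtype):
        self.causal = nn.CausalConv1d(
            1, config.attention_channels, config.attention_kernel, rng=rng, dtype=dtype
        )
        self.proj = nn.Conv1d(config.attention_channels, 1, 1, rng=rng, dtype=dtype)
        self.sigmoid = nn.Sigmoid()
        self.last_attention: np.ndarray | None = None

    def forward(self, x, training=False):
        h = self.causal.forward(x, training=training)
        s = self.proj.forward(h, training=training)
        a = self.sigmoid.forward(s, training=training)
        self.last_attention = a[0]
        if training:
            self._x = x
            self._a = a
        return x * a

    def backward(self, dy):
        dx_direct = dy * self._a
        da = dy * self._x
        ds = self.sigmoid.backward(da)
        dh = self.proj.backward(ds)
        dx_attn = self.causal.backward(dh)
        self._x = self._a = None
        return dx_direct + dx_attn


class InceptionBlock(nn.Module):
    """Bottleneck -> three parallel convs (k=5,11,23) + maxpool/1x1 branch,
    concatenated, with a per-block residual shortcut (1x1 projection when
    channel counts differ) and a ReLU on the sum."""

    def __init__(self, in_channels, filters, bottleneck, kernels, rng, dtype):
        self.in_channels = in_channels
        self.out_channels = 4 * filters
        self.bottleneck = nn.Conv1d(in_channels, bottleneck, 1, rng=rng, dtype=dtype)
        self.branches = [
            nn.Conv1d(
                bottleneck,
                filters,
                k,
                pad_left=(k - 1) // 2,
                pad_right=k // 2,
                rng=rng,
                dtype=dtype,
            )
            for k in kernels
        ]
        self.pool = nn.MaxPool1dSame(3)
        self.pool_proj = nn.Conv1d(in_channels, filters, 1, rng=rng, dtype=dtype)
        self.shortcut = (
            nn.Conv1d(in_channels, self.out_channels, 1, rng=rng, dtype=dtype)
            if in_channels != self.out_channels
            else None
        )
        self.relu = nn.ReLU()
        self._splits = None

    def forward(self, x, training=False):
        b = self.bottleneck.forward(x, training=training)
        outs = [m.forward(b, training=training) for m in self.branches]
        outs.append(self.pool_proj.forward(self.pool.forward(x, training=training), training=training))
        cat = np.concatenate(outs, axis=0)
        res = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        y = self.relu.forward(cat + res, training=training)
        if training:
            self._splits = np.cumsum([o.shape[0] for o in outs])[:-1]
        return y

    def backward(self, dy):
        d = self.relu.backward(dy)
        parts = np.split(d, self._splits, axis=0)
        dx = d if self.shortcut is None else self.shortcut.backward(d)
        db = None
        for m, dpart in zip(self.branches, parts[:-1]):
            g = m.backward(dpart)
            db = g if db is None else db + g
        dx = dx + self.pool.backward(self.pool_proj.backward(parts[-1]))
        dx = dx + self.bottleneck.backward(db)
        return dx


class TemporalBlock(nn.Module):
    """Dilated causal conv -> ReLU -> dropout, twice, plus a residual path."""

    def __init__(self, in_channels, channels, kernel, dilation, dropout, rng_box, rng, dtype):
        self.conv1 = nn.CausalConv1d(in_channels, channels, kernel, dilation=dilation, rng=rng, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.drop1 = nn.Dropout(dropout, rng_box)
        self.conv2 = nn.CausalConv1d(channels, channels, kernel, dilation=dilation, rng=rng, dtype=dtype)
        self.relu2 = nn.ReLU()
        self.drop2 = nn.Dropout(dropout, rng_box)
        self.downsample = (
            nn.Conv1d(in_channels, channels, 1, rng=rng, dtype=dtype)
            if in_channels != channels
            else None
        )
        self.relu_out = nn.ReLU()

    def forward(self, x, training=False):
        h = self.drop1.forward(
            self.relu1.forward(self.conv1.forward(x, training=training), training=training),
            training=training,
        )
        h = self.drop2.forward(
            self.relu2.forward(self.conv2.forward(h, training=training), training=training),
            training=training,
        )
        res = x if self.downsample is None else self.downsample.forward(x, training=training)
        return self.relu_out.forward(h + res, training=training)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dres = d if self.downsample is None else self.downsample.backward(d)
        dh = self.conv2.backward(self.relu2.backward(self.drop2.backward(d)))
        dx = self.conv1.backward(self.relu1.backward(self.drop1.backward(dh)))
        return dx + dres


class InsightSleepNet(nn.Module):
    """Full network: (n_epochs x epoch_len) input -> (n_epochs x n_classes) logits."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        config.validate()
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        self.rng_box = {"rng": np.random.default_rng(config.seed + 1)}
        self.attention = LocalAttention(config, rng, dtype)
        self.stem = nn.Conv1d(
            1,
            config.stem_channels,
            config.stem_kernel,
            stride=config.stem_stride,
            pad_left=(config.stem_kernel - config.stem_stride) // 2,
            pad_right=(config.stem_kernel - config.stem_stride + 1) // 2,
            rng=rng,
            dtype=dtype,
        )
        self.stem_relu = nn.ReLU()
        self.blocks = [
            InceptionBlock(
                ic, f, b, config.inception_kernels, rng, dtype
            )
            for ic, f, b in zip(
                config.inception_in_channels,
                config.inception_filters,
                config.inception_bottleneck,
            )
        ]
        self.pool = nn.AdaptiveAvgPool1d(config.n_epochs)
        self.inception_head = nn.Conv1d(
            4 * config.inception_filters[-1],
            config.inception_out_channels,
            1,
            rng=rng,
            dtype=dtype,
        )
        self.tdd = nn.Conv1d(
            config.inception_out_channels, config.tdd_width, 1, rng=rng, dtype=dtype
        )
        self.tcn = [
            TemporalBlock(
                config.tdd_width if i == 0 else config.tcn_channels,
                config.tcn_channels,
                config.tcn_kernel,
                d,
                config.tcn_dropout,
                self.rng_box,
                rng,
                dtype,
            )
            for i, d in enumerate(config.tcn_dilations)
        ]
        self.head = nn.Conv1d(config.tcn_channels, config.n_classes, 1, rng=rng, dtype=dtype)

    # -- forward/backward ----------------------------------------------------
    def forward_values(self, values: np.ndarray, training: bool = False) -> np.ndarray:
        """values: (n_epochs, epoch_len) in [0,1] -> logits (n_epochs, n_classes)."""
        cfg = self.config
        if values.shape != (cfg.n_epochs, cfg.epoch_len):
            raise ValueError(
                f"expected input shape ({cfg.n_epochs}, {cfg.epoch_len}), got {values.shape}"
            )
        x = values.reshape(1, -1).astype(self.dtype)
        x = self.attention.forward(x, training=training)
        x = self.stem_relu.forward(self.stem.forward(x, training=training), training=training)
        for b in self.blocks:
            x = b.forward(x, training=training)
        x = self.pool.forward(x, training=training)
        x = self.inception_head.forward(x, training=training)
        x = self.tdd.forward(x, training=training)
        for t in self.tcn:
            x = t.forward(x, training=training)
        x = self.head.forward(x, training=training)
        return x.T.astype(np.float64)

    def forward(self, epochized: EpochizedInput, training: bool = False) -> LogitsGrid:
        return LogitsGrid(self.forward_values(epochized.values, training=training))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits.T.astype(self.dtype)
        d = self.head.backward(d)
        for t in reversed(self.tcn):
            d = t.backward(d)
        d = self.tdd.backward(d)
        d = self.inception_head.backward(d)
        d = self.pool.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        d = self.stem.backward(self.stem_relu.backward(d))
        d = self.attention.backward(d)
        return d.reshape(self.config.n_epochs, self.config.epoch_len)

    # -- attention extraction --------------------------------------------------
    def extract_attention(self, epochized: EpochizedInput) -> AttentionMap:
        self.forward_values(epochized.values, training=False)
        per_sample = np.asarray(self.attention.last_attention, dtype=np.float64)
        per_epoch = per_sample.reshape(self.config.n_epochs, self.config.epoch_len).mean(axis=1)
        valid = epochized.epoch_mask
        sel = per_sample.reshape(self.config.n_epochs, -1)[valid].ravel()
        lo, hi = (sel.min(), sel.max()) if sel.size else (0.0, 1.0)
        span = hi - lo if hi > lo else 1.0
        normalized = (per_sample - lo) / span
        return AttentionMap(per_sample, per_epoch, normalized)

    # -- (de)serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)[:5]} ...")
        for name, p in mine.items():
            arr = np.asarray(state[name])
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.value[...] = arr.astype(p.value.dtype)

    def reseed_dropout(self, seed: int) -> None:
        self.rng_box["rng"] = np.random.default_rng(seed)


def build_model(config: ModelConfig | None = None, dtype=np.float32) -> InsightSleepNet:
    return InsightSleepNet(config or ModelConfig(), dtype=dtype)


def count_trainable_parameters(model: InsightSleepNet) -> int:
    return model.n_parameters()


def save_checkpoint(path, model: InsightSleepNet) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.config.to_json().encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path, dtype=np.float32) -> InsightSleepNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode("utf-8"))
        model = InsightSleepNet(cfg, dtype=dtype)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
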