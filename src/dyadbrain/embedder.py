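"""Shallow convolutional EEG embedder h_theta: one (C, T) epoch -> R^D.

Architecture (in order): per-channel temporal convolution, spatial aggregation
across electrodes, batch normalization, squaring non-linearity, temporal
average pooling, safe log, dropout, flatten, linear map to the embedding
dimension D.  The square/log pair around average pooling makes the features
approximate log band power of the learned temporal filters, which is why a
linear readout on embedding differences can discriminate temporal order in
slowly drifting EEG.

At the full scale used for real recordings (61 channels, 501 samples, 40
temporal filters, kernel 25, pooling 75/15, D = 100) the embedder has 206,820
trainable parameters; together with the 201-parameter linear pretext head the
pretext model totals 207,021.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from ._nn import (
    AvgPool,
    BatchNorm,
    Dropout,
    Flatten,
    LogEps,
    Linear,
    Network,
    Square,
    SpatialConv,
    TemporalConv,
)
from .types import InvalidConfigError

__all__ = ["EmbedderConfig", "EmbedderModel", "build_embedder", "count_parameters", "embed"]


@dataclass(frozen=True)
class EmbedderConfig:
    """Hyperparameters of the shallow-ConvNet embedder.

    Defaults target 1-s epochs of 61-channel EEG at 500 Hz (501 samples with
    the inclusive-endpoint epoching convention).
    """

    n_channels: int = 61
    n_times: int = 501
    n_temporal_filters: int = 40
    k_time: int = 25
    pool_len: int = 75
    pool_stride: int = 15
    D: int = 100
    dropout: float = 0.4
    log_eps: float = 1e-6

    def validate(self) -> None:
        if self.k_time >= self.n_times:
            raise InvalidConfigError("k_time must be shorter than n_times")
        t_conv = self.n_times - self.k_time + 1
        if self.pool_len > t_conv:
            raise InvalidConfigError("pool_len exceeds post-convolution length")
        if self.pool_stride < 1 or self.D < 1 or self.n_temporal_filters < 1:
            raise InvalidConfigError("sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidConfigError("dropout must be in [0, 1)")
        if not self.log_eps > 0:
            raise InvalidConfigError("log_eps must be positive")

    @property
    def t_conv(self) -> int:
        return self.n_times - self.k_time + 1

    @property
    def t_pool(self) -> int:
        return AvgPool.out_len(self.t_conv, self.pool_len, self.pool_stride)

    @property
    def flat_dim(self) -> int:
        return self.n_temporal_filters * self.t_pool


def count_parameters(cfg: EmbedderConfig) -> int:
    """Closed-form trainable-parameter count implied by the config.

    temporal conv (F*k + F biases) + spatial conv (F*F*C, no bias) + batch
    norm affine (2F) + output linear (flat*D + D).
    """
    cfg.validate()
    f = cfg.n_temporal_filters
    return (
        f * cfg.k_time
        + f
        + f * f * cfg.n_channels
        + 2 * f
        + cfg.flat_dim * cfg.D
        + cfg.D
    )


class EmbedderModel:
    """A built embedder: the layer stack plus its config.

    ``forward(..., train=True)`` records caches for :meth:`backward`;
    evaluation-mode forward is deterministic (dropout off, batch norm running
    statistics).
    """

    def __init__(self, net: Network, config: EmbedderConfig, dropout_layer: Dropout) -> None:
        self.net = net
        self.config = config
        self._dropout = dropout_layer

    def set_rng(self, rng: np.random.Generator) -> None:
        """Redirect the dropout mask stream (used when training restarts)."""
        self._dropout.rng = rng

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (self.config.n_channels, self.config.n_times):
            raise ValueError(
                f"input shape {x.shape} does not match "
                f"(C={self.config.n_channels}, T={self.config.n_times})"
            )
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._check_input(x), train)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        return self.net.backward(dz)

    def n_params(self) -> int:
        return self.net.n_params()

    def copy(self, seed: int = 0) -> "EmbedderModel":
        """An independent model with identical weights (and BN statistics)."""
        clone = build_embedder(self.config, seed=seed)
        clone.net.set_flat(self.net.get_flat())
        for src, dst in zip(self.net.modules, clone.net.modules):
            if isinstance(src, BatchNorm):
                dst.running_mean = src.running_mean.copy()
                dst.running_var = src.running_var.copy()
        return clone

    def save(self, path: str) -> None:
        bn = next(m for m in self.net.modules if isinstance(m, BatchNorm))
        np.savez(
            path,
            flat=self.net.get_flat(),
            running_mean=bn.running_mean,
            running_var=bn.running_var,
            config_yaml=yaml.safe_dump(asdict(self.config)),
        )

    @classmethod
    def load(cls, path: str) -> "EmbedderModel":
        with np.load(path, allow_pickle=False) as archive:
            cfg = EmbedderConfig(**yaml.safe_load(str(archive["config_yaml"])))
            model = build_embedder(cfg)
            model.net.set_flat(archive["flat"])
            bn = next(m for m in model.net.modules if isinstance(m, BatchNorm))
            bn.running_mean = archive["running_mean"].copy()
            bn.running_var = archive["running_var"].copy()
        return model


def build_embedder(cfg: EmbedderConfig, seed: int = 0) -> EmbedderModel:
    """Construct an embedder with freshly initialized weights."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    dropout = Dropout(cfg.dropout, rng)
    f = cfg.n_temporal_filters
    net = Network(
        [
            TemporalConv(f, cfg.k_time, rng),
            SpatialConv(f, f, cfg.n_channels, rng),
            BatchNorm(f),
            Square(),
            AvgPool(cfg.pool_len, cfg.pool_stride),
            LogEps(cfg.log_eps),
            dropout,
            Flatten(),
            Linear(cfg.flat_dim, cfg.D, rng),
        ]
    )
    model = EmbedderModel(net, cfg, dropout)
    assert model.n_params() == count_parameters(cfg)
    return model


def embed(model: EmbedderModel, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode embeddings: (C, T) -> (D,) or (B, C, T) -> (B, D)."""
    single = np.asarray(x).ndim == 2
    z = model.forward(x, train=False)
    return z[0] if single else z
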