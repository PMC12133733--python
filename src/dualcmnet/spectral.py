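"""Spectral branch: a compact 1-D CNN over full-range reflectance spectra.

Three conv blocks (16/32/64 channels; each conv -> batch norm -> ReLU ->
max-pool, the first block adding dropout) reduce the 2151-point spectrum to
a 64 x 134 map; the flattened 8576-d vector is the feature tap used by the
fusion model, and two fully connected layers form the pretraining head.
With the default hyperparameters the full classifier holds ~0.28M
trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError


@dataclass
class SpectralNetConfig:
    in_length: int = 2151
    channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    pool_sizes: tuple[int, int, int] = (2, 2, 4)
    fc1_width: int = 32
    n_classes: int = 11
    dropout_conv: float = 0.2
    dropout_fc: float = 0.5

    def __post_init__(self):
        if len(self.channels) != 3 or len(self.pool_sizes) != 3:
            raise ConfigurationError("exactly three conv blocks are required")
        if not (self.channels[0] < self.channels[1] < self.channels[2]):
            raise ConfigurationError("channels must be strictly increasing")

    def pooled_lengths(self) -> list[int]:
        """Length after each block (length-preserving conv, floor pooling)."""
        L = self.in_length
        out = []
        for p in self.pool_sizes:
            L = L // p
            out.append(L)
        return out

    @property
    def flat_dim(self) -> int:
        return self.channels[-1] * self.pooled_lengths()[-1]


class SpectralNet(nn.Module):
    def __init__(self, config: SpectralNetConfig):
        super().__init__()
        if config.pooled_lengths()[-1] < 1:
            raise ConfigurationError("pooling reduces the spectrum to length 0")
        self.config = config
        k, pad = config.kernel_size, config.kernel_size // 2
        c1, c2, c3 = config.channels
        p1, p2, p3 = config.pool_sizes
        self.features = nn.Sequential(
            nn.Conv1d(1, c1, k, padding=pad), nn.BatchNorm(c1), nn.ReLU(),
            nn.MaxPool1d(p1), nn.Dropout(config.dropout_conv),
            nn.Conv1d(c1, c2, k, padding=pad), nn.BatchNorm(c2), nn.ReLU(),
            nn.MaxPool1d(p2),
            nn.Conv1d(c2, c3, k, padding=pad), nn.BatchNorm(c3), nn.ReLU(),
            nn.MaxPool1d(p3),
            nn.Flatten(),
        )
        self.head = nn.Sequential(
            nn.Linear(config.flat_dim, config.fc1_width), nn.ReLU(),
            nn.Dropout(config.dropout_fc),
            nn.Linear(config.fc1_width, config.n_classes),
        )
        self.flat_dim = config.flat_dim

    def forward(self, x: np.ndarray, mode: str = "logits"):
        x = np.asarray(x)
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[-1] != self.config.in_length:
            raise ValidationError(
                f"expected spectra of length {self.config.in_length}, "
                f"got {x.shape[-1]}")
        feat = self.features(x)
        if mode == "features":
            return feat
        logits = self.head(feat)
        if mode == "logits":
            return logits
        if mode == "both":
            return feat, logits
        raise ValidationError(f"unknown mode {mode!r}")

    def backward(self, grad_logits):
        """Backprop from the classifier logits (pretraining path)."""
        return self.features.backward(self.head.backward(grad_logits))

    def backward_features(self, grad_feat):
        """Backprop from the flattened feature tap (fused-model path)."""
        return self.features.backward(grad_feat)


def build_spectral_net(config: SpectralNetConfig | None = None) -> SpectralNet:
    return SpectralNet(config or SpectralNetConfig())
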