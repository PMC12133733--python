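"""Spatial branch: MobileNetV3-Small over single-kernel RGB images.

Stem 3x3 conv (16 ch, hard-swish) -> 11 inverted-residual bottlenecks with
squeeze-excitation and ReLU/hard-swish per the standard small stack ->
1x1 conv to 576 -> adaptive average pool -> FC to 1024 (hard-swish, the
feature tap) -> FC classifier head.  With an 11-class head the network
holds ~1.53M trainable parameters and ~0.057 GMACs at 224x224.

The network is fully convolutional up to the adaptive pool, so smaller
input sizes are accepted; 224 is the reference resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ValidationError

# (kernel, expanded dim, output channels, SE, activation, stride) per
# bottleneck; strides reproduce the 224->112->56->28->28->14->...->7 ladder.
SMALL_BOTTLENECKS: tuple = (
    (3, 16, 16, True, "RE", 2),
    (3, 72, 24, False, "RE", 2),
    (3, 88, 24, False, "RE", 1),
    (5, 96, 40, True, "HS", 2),
    (5, 240, 40, True, "HS", 1),
    (5, 240, 40, True, "HS", 1),
    (5, 120, 48, True, "HS", 1),
    (5, 144, 48, True, "HS", 1),
    (5, 288, 96, True, "HS", 2),
    (5, 576, 96, True, "HS", 1),
    (5, 576, 96, True, "HS", 1),
)


@dataclass
class SpatialNetConfig:
    input_size: int = 224
    n_classes: int = 11
    bottlenecks: tuple = SMALL_BOTTLENECKS
    stem_channels: int = 16
    last_conv_channels: int = 576
    feature_dim: int = 1024
    dropout: float = 0.2


def make_divisible(v: float, divisor: int = 8) -> int:
    """Round channel counts to hardware-friendly multiples (standard rule)."""
    new_v = max(divisor, int(v + divisor / 2) // divisor * divisor)
    if new_v < 0.9 * v:
        new_v += divisor
    return new_v


def _act(name: str) -> nn.Module:
    return nn.ReLU() if name == "RE" else nn.Hardswish()


class SqueezeExcite(nn.Module):
    """Channel gating: global pool -> 1x1 conv bottleneck -> hard sigmoid."""

    def __init__(self, channels: int):
        super().__init__()
        squeeze = make_divisible(channels // 4, 8)
        self.fc1 = nn.Conv2d(channels, squeeze, 1, bias=True)
        self.relu = nn.ReLU()
        self.fc2 = nn.Conv2d(squeeze, channels, 1, bias=True)
        self.hsig = nn.Hardsigmoid()

    def forward(self, x):
        self._x = x
        self._hw = x.shape[2] * x.shape[3]
        z = x.mean((2, 3), keepdims=True)
        s = self.hsig(self.fc2(self.relu(self.fc1(z))))
        self._s = s
        return x * s

    def backward(self, grad):
        gs = (grad * self._x).sum((2, 3), keepdims=True)
        gx = grad * self._s
        gz = self.fc1.backward(self.relu.backward(
            self.fc2.backward(self.hsig.backward(gs))))
        return gx + gz / self._hw


class InvertedResidual(nn.Module):
    def __init__(self, in_ch, k, exp, out_ch, se, act, stride):
        super().__init__()
        layers: list[nn.Module] = []
        if exp != in_ch:
            layers += [nn.Conv2d(in_ch, exp, 1), nn.BatchNorm(exp), _act(act)]
        layers += [nn.Conv2d(exp, exp, k, stride=stride, padding=k // 2,
                             groups=exp),
                   nn.BatchNorm(exp), _act(act)]
        if se:
            layers.append(SqueezeExcite(exp))
        layers += [nn.Conv2d(exp, out_ch, 1), nn.BatchNorm(out_ch)]
        self.block = nn.Sequential(*layers)
        self.use_res = stride == 1 and in_ch == out_ch

    def forward(self, x):
        y = self.block(x)
        return y + x if self.use_res else y

    def backward(self, grad):
        gx = self.block.backward(grad)
        return gx + grad if self.use_res else gx


class MobileNetV3Small(nn.Module):
    def __init__(self, config: SpatialNetConfig):
        super().__init__()
        self.config = config
        layers: list[nn.Module] = [
            nn.Conv2d(3, config.stem_channels, 3, stride=2, padding=1),
            nn.BatchNorm(config.stem_channels), nn.Hardswish()]
        in_ch = config.stem_channels
        for k, exp, out_ch, se, act, stride in config.bottlenecks:
            layers.append(InvertedResidual(in_ch, k, exp, out_ch, se, act,
                                           stride))
            in_ch = out_ch
        layers += [nn.Conv2d(in_ch, config.last_conv_channels, 1),
                   nn.BatchNorm(config.last_conv_channels), nn.Hardswish()]
        self.features = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool2d()
        self.fc1 = nn.Linear(config.last_conv_channels, config.feature_dim)
        self.fc1_act = nn.Hardswish()
        self.drop = nn.Dropout(config.dropout)
        self.classifier = nn.Linear(config.feature_dim, config.n_classes)

    def forward(self, x: np.ndarray, mode: str = "logits"):
        x = np.asarray(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValidationError("expected an (N, 3, H, W) image batch")
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValidationError("spatial size too small (min 32)")
        feat = self.fc1_act(self.fc1(self.pool(self.features(x))))
        if mode == "features":
            return feat
        logits = self.classifier(self.drop(feat))
        if mode == "logits":
            return logits
        if mode == "both":
            return feat, logits
        raise ValidationError(f"unknown mode {mode!r}")

    def backward(self, grad_logits):
        g = self.drop.backward(self.classifier.backward(grad_logits))
        return self.backward_features(g)

    def backward_features(self, grad_feat):
        g = self.pool.backward(self.fc1.backward(self.fc1_act.backward(grad_feat)))
        return self.features.backward(g)


def build_spatial_net(config: SpatialNetConfig | None = None) -> MobileNetV3Small:
    return MobileNetV3Small(config or SpatialNetConfig())
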