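"""Fusion core: HShuffleBlock, CBAM attention, gated fusion and the
assembled dual-branch classifier.

The two branch feature vectors (8576-d spectral, 1024-d spatial) are mapped
into a shared 384-d space by two-stage grouped affine transforms with
channel shuffling (a g-fold parameter reduction over dense maps, with the
shuffle restoring cross-group information flow), refined by channel+spatial
attention, and merged by a scalar-gated convex combination of their
elementwise product and sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .nn import ChannelShuffle, GroupedLinear, channel_shuffle  # re-export

__all__ = [
    "HShuffleConfig", "CBAMConfig", "GateConfig", "channel_shuffle",
    "GroupedLinear", "HShuffleBlock", "CBAM", "GatedFusion", "DualCMNet",
    "ConcatBaseline", "build_dualcmnet",
]


@dataclass
class HShuffleConfig:
    in_dim: int
    mid_dim: int = 512
    out_dim: int = 384
    groups: int = 8

    def __post_init__(self):
        for name in ("in_dim", "mid_dim", "out_dim"):
            if getattr(self, name) % self.groups:
                raise ConfigurationError(
                    f"{name}={getattr(self, name)} not divisible by "
                    f"groups={self.groups}")


@dataclass
class CBAMConfig:
    channels: int = 384
    reduction: int = 16
    spatial_kernel: int = 7
    #: optional (C, H, W) reshape giving spatial attention real extent;
    #: None treats the vector as C channels of 1x1 extent
    reshape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.channels % self.reduction:
            raise ConfigurationError("channels must be divisible by reduction")
        if self.spatial_kernel % 2 == 0:
            raise ConfigurationError("spatial_kernel must be odd")
        if self.reshape is not None and int(np.prod(self.reshape)) != self.channels:
            raise ConfigurationError("reshape must preserve the feature size")


@dataclass
class GateConfig:
    in_dim: int = 2 * 384
    hidden: int = 48
    dropout: float = 0.2


class HShuffleBlock(nn.Module):
    """Two stages of grouped affine map -> channel shuffle -> BN -> ReLU,
    taking any g-divisible input to the 384-d common feature space."""

    def __init__(self, config: HShuffleConfig):
        super().__init__()
        self.config = config
        g = config.groups
        self.net = nn.Sequential(
            GroupedLinear(config.in_dim, config.mid_dim, g), ChannelShuffle(g),
            nn.BatchNorm(config.mid_dim), nn.ReLU(),
            GroupedLinear(config.mid_dim, config.out_dim, g), ChannelShuffle(g),
            nn.BatchNorm(config.out_dim), nn.ReLU(),
        )

    def forward(self, x):
        if x.shape[1] != self.config.in_dim:
            raise ValidationError(
                f"expected {self.config.in_dim}-d input, got {x.shape[1]}")
        return self.net(x)

    def backward(self, grad):
        return self.net.backward(grad)


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention.

    Channel attention pools globally (average and max in parallel), passes
    both statistics through a shared bias-free two-layer MLP and gates the
    channels with the sigmoid of the summed responses.  Spatial attention
    concatenates the channel-wise mean and max maps and gates positions
    with a sigmoid-activated 7x7 convolution.
    """

    def __init__(self, config: CBAMConfig):
        super().__init__()
        self.config = config
        C, r = config.channels, config.reduction
        self.w1 = nn.Parameter(nn._kaiming((C // r, C), C))
        self.w2 = nn.Parameter(nn._kaiming((C, C // r), C // r))
        k = config.spatial_kernel
        self.conv = nn.Conv2d(2, 1, k, padding=k // 2, bias=True)

    # -- functional pieces (also used directly by tests) ------------------
    def _mlp(self, z):
        h_pre = z @ self.w1.value.T
        h = np.maximum(h_pre, 0)
        return h_pre, h, h @ self.w2.value.T

    def channel_attention(self, F):
        """Sigmoid channel weights in (0, 1), shape (N, C)."""
        zavg = F.mean((2, 3))
        zmax = F.max((2, 3))
        _, _, a = self._mlp(zavg)
        _, _, b = self._mlp(zmax)
        return 1.0 / (1.0 + np.exp(-(a + b)))

    def spatial_attention(self, F):
        """Sigmoid spatial weight map in (0, 1), shape (N, 1, H, W)."""
        s = np.stack([F.mean(1), F.max(1)], axis=1)
        return 1.0 / (1.0 + np.exp(-self.conv(s)))

    # -- forward/backward --------------------------------------------------
    def forward(self, F):
        if F.shape[1] != self.config.channels:
            raise ValidationError(
                f"expected {self.config.channels} channels, got {F.shape[1]}")
        N, C, H, W = F.shape
        zavg = F.mean((2, 3))
        flat = F.reshape(N, C, H * W)
        self._sp_arg = flat.argmax(-1)
        zmax = np.take_along_axis(flat, self._sp_arg[..., None], -1)[..., 0]
        ha_pre, ha, a = self._mlp(zavg)
        hm_pre, hm, b = self._mlp(zmax)
        mc = 1.0 / (1.0 + np.exp(-(a + b)))
        F1 = F * mc[:, :, None, None]

        savg = F1.mean(1)
        self._ch_arg = F1.argmax(1)
        smax = np.take_along_axis(F1, self._ch_arg[:, None], 1)[:, 0]
        s = np.stack([savg, smax], axis=1)
        ms = 1.0 / (1.0 + np.exp(-self.conv(s)))
        out = F1 * ms

        self._cache = (F, zavg, zmax, ha_pre, ha, hm_pre, hm, mc, F1, ms)
        return out

    def _mlp_backward(self, ga, z, h_pre, h):
        self.w2.grad += ga.T @ h
        gh = (ga @ self.w2.value) * (h_pre > 0)
        self.w1.grad += gh.T @ z
        return gh @ self.w1.value

    def backward(self, grad):
        F, zavg, zmax, ha_pre, ha, hm_pre, hm, mc, F1, ms = self._cache
        N, C, H, W = F.shape
        gms = (grad * F1).sum(1, keepdims=True)
        gF1 = grad * ms
        gs = self.conv.backward(gms * ms * (1.0 - ms))
        gF1 = gF1 + gs[:, 0:1] / C
        # scatter the channel-max path gradient
        gF1_flat = np.zeros_like(F1)
        np.put_along_axis(gF1_flat, self._ch_arg[:, None], gs[:, 1:2], 1)
        gF1 = gF1 + gF1_flat

        gmc = (gF1 * F).sum((2, 3))
        gF = gF1 * mc[:, :, None, None]
        gz = gmc * mc * (1.0 - mc)
        gzavg = self._mlp_backward(gz, zavg, ha_pre, ha)
        gzmax = self._mlp_backward(gz, zmax, hm_pre, hm)
        gF = gF + gzavg[:, :, None, None] / (H * W)
        gmax_sp = np.zeros((N, C, H * W), grad.dtype)
        np.put_along_axis(gmax_sp, self._sp_arg[..., None], gzmax[..., None], -1)
        return gF + gmax_sp.reshape(N, C, H, W)


class GatedFusion(nn.Module):
    """fused = g * (Fs o Fr) + (1 - g) * (Fs + Fr), with the scalar gate
    g = sigmoid(MLP([Fs, Fr])) learned from the concatenated features."""

    def __init__(self, config: GateConfig | None = None):
        super().__init__()
        self.config = config or GateConfig()
        self.fc1 = nn.Linear(self.config.in_dim, self.config.hidden)
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(self.config.dropout)
        self.fc2 = nn.Linear(self.config.hidden, 1)
        self.sig = nn.Sigmoid()

    def forward(self, fs, fr):
        if fs.shape != fr.shape or 2 * fs.shape[1] != self.config.in_dim:
            raise ValidationError("gated fusion inputs must both be "
                                  f"{self.config.in_dim // 2}-d")
        cat = np.concatenate([fs, fr], axis=1)
        g = self.sig(self.fc2(self.drop(self.relu(self.fc1(cat)))))
        self._fs, self._fr, self._g = fs, fr, g
        return g * (fs * fr) + (1.0 - g) * (fs + fr)

    def backward(self, grad):
        fs, fr, g = self._fs, self._fr, self._g
        gg = (grad * (fs * fr - fs - fr)).sum(1, keepdims=True)
        gfs = grad * (g * fr + (1.0 - g))
        gfr = grad * (g * fs + (1.0 - g))
        gcat = self.fc1.backward(self.relu.backward(
            self.drop.backward(self.fc2.backward(self.sig.backward(gg)))))
        d = fs.shape[1]
        return gfs + gcat[:, :d], gfr + gcat[:, d:]

    @property
    def last_gate(self):
        return self._g


class DualCMNet(nn.Module):
    """Assembled dual-branch fusion classifier.

    spectral branch -> flattened conv features -> HShuffleBlock -> CBAM
    spatial branch  -> 1024-d features         -> HShuffleBlock -> CBAM
    then gated fusion and a dropout + affine classifier head.
    """

    def __init__(self, spectral_net, spatial_net, out_dim: int = 384,
                 groups: int = 8, cbam: CBAMConfig | None = None,
                 n_classes: int = 11, head_dropout: float = 0.2):
        super().__init__()
        self.spectral = spectral_net
        self.spatial = spatial_net
        self.hshuffle_spec = HShuffleBlock(
            HShuffleConfig(spectral_net.flat_dim, out_dim=out_dim, groups=groups))
        self.hshuffle_spat = HShuffleBlock(
            HShuffleConfig(spatial_net.config.feature_dim, out_dim=out_dim,
                           groups=groups))
        cbam = cbam or CBAMConfig(channels=out_dim)
        self._cbam_shape = cbam.reshape or (out_dim, 1, 1)
        self.cbam_spec = CBAM(cbam)
        self.cbam_spat = CBAM(cbam)
        self.gate = GatedFusion(GateConfig(in_dim=2 * out_dim))
        self.head_drop = nn.Dropout(head_dropout)
        self.head = nn.Linear(out_dim, n_classes)
        self.out_dim = out_dim

    def _attend(self, cbam, x):
        n = x.shape[0]
        return cbam(x.reshape(n, *self._cbam_shape)).reshape(n, -1)

    def branch_features(self, spectra, images) -> tuple[np.ndarray, np.ndarray]:
        """Raw branch feature taps (flattened conv features, 1024-d FC)."""
        return (self.spectral(spectra, "features"),
                self.spatial(images, "features"))

    def fuse_features(self, fs0, fr0, mode: str = "logits"):
        """Run the fusion stack on precomputed branch features."""
        fs = self._attend(self.cbam_spec, self.hshuffle_spec(fs0))
        fr = self._attend(self.cbam_spat, self.hshuffle_spat(fr0))
        fused = self.gate(fs, fr)
        logits = self.head(self.head_drop(fused))
        if mode == "logits":
            return logits
        if mode == "fused":
            return fused, logits
        raise ValidationError(f"unknown mode {mode!r}")

    def forward(self, spectra, images, mode: str = "logits"):
        return self.fuse_features(*self.branch_features(spectra, images), mode)

    def backward(self, grad_logits, through_branches: bool = True):
        g = self.head_drop.backward(self.head.backward(grad_logits))
        gfs, gfr = self.gate.backward(g)
        n = gfs.shape[0]
        gfs = self.cbam_spec.backward(
            gfs.reshape(n, *self._cbam_shape)).reshape(n, -1)
        gfr = self.cbam_spat.backward(
            gfr.reshape(n, *self._cbam_shape)).reshape(n, -1)
        gspec = self.hshuffle_spec.backward(gfs)
        gspat = self.hshuffle_spat.backward(gfr)
        if through_branches:
            self.spectral.backward_features(gspec)
            self.spatial.backward_features(gspat)

    def parameters(self) -> list[nn.Parameter]:
        # the branch pretraining heads are bypassed by the feature taps and
        # are not part of the fused model
        excluded = {id(p) for p in self.spectral.head.parameters()}
        excluded |= {id(p) for p in self.spatial.classifier.parameters()}
        return [p for p in super().parameters() if id(p) not in excluded]

    def branch_parameters(self) -> list[nn.Parameter]:
        """Pretrained feature-extractor parameters (frozen in phase 1)."""
        spat = {id(p) for p in self.spatial.classifier.parameters()}
        return (self.spectral.features.parameters()
                + [p for p in self.spatial.parameters() if id(p) not in spat])

    def fusion_parameters(self) -> list[nn.Parameter]:
        """HShuffleBlocks, CBAM, gate and classifier head parameters."""
        branch = {id(p) for p in self.branch_parameters()}
        return [p for p in self.parameters() if id(p) not in branch]


class ConcatBaseline(nn.Module):
    """Plain feature-concatenation fusion, kept as a smoke-test baseline."""

    def __init__(self, spectral_net, spatial_net, n_classes: int = 11,
                 dropout: float = 0.2):
        super().__init__()
        self.spectral = spectral_net
        self.spatial = spatial_net
        in_dim = spectral_net.flat_dim + spatial_net.config.feature_dim
        self.drop = nn.Dropout(dropout)
        self.head = nn.Linear(in_dim, n_classes)

    def forward(self, spectra, images):
        cat = np.concatenate([self.spectral(spectra, "features"),
                              self.spatial(images, "features")], axis=1)
        self._split = self.spectral.flat_dim
        return self.head(self.drop(cat))

    def backward(self, grad_logits, through_branches: bool = True):
        g = self.drop.backward(self.head.backward(grad_logits))
        if through_branches:
            self.spectral.backward_features(g[:, :self._split])
            self.spatial.backward_features(g[:, self._split:])


def build_dualcmnet(spectral_net=None, spatial_net=None, **kwargs) -> DualCMNet:
    from .spatial import build_spatial_net
    from .spectral import build_spectral_net

    return DualCMNet(spectral_net or build_spectral_net(),
                     spatial_net or build_spatial_net(), **kwargs)
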