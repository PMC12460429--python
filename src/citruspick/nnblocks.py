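"""Lightweight segmentation-network building blocks as numpy forward passes.

Three architectural components are provided as standalone, shape-checked
modules: GhostConv (half the output channels from a primary convolution, half
from cheap depthwise transforms of those maps, concatenated), CBAM
(sequential channel then spatial attention, F' = M_C(F) (x) F and
F'' = M_S(F') (x) F' with (x) element-wise), and a four-branch multi-scale
head that adds a stride-4 (P2) output to the usual P3/P4/P5 trio so that
small, slender targets such as fruit stems are seen at high resolution.

These are inference-only components with exact learnable-parameter ledgers;
no training loop or weight loading is provided.  Feature maps are arrays of
shape (C, H, W); convolutions are stride-1 with "same" zero padding.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Module:
    """Minimal parameter container: children and arrays are discovered by attribute."""

    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for value in vars(self).values():
            if isinstance(value, np.ndarray):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def count_parameters(block: Module) -> int:
    """Exact count of learnable scalars in a block."""
    return int(sum(p.size for p in block.parameters()))


def _conv2d_same(x: np.ndarray, weight: np.ndarray, groups: int = 1) -> np.ndarray:
    """Stride-1 'same' cross-correlation; weight shape (C_out, C_in/groups, k, k)."""
    c_in, h, w = x.shape
    c_out, c_in_g, kh, kw = weight.shape
    if c_in % groups or c_out % groups or c_in // groups != c_in_g:
        raise ValueError("inconsistent channel/group configuration")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)))
    # windows: (C_in, H, W, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    out = np.empty((c_out, h, w))
    cpg_in, cpg_out = c_in // groups, c_out // groups
    for g in range(groups):
        wg = weight[g * cpg_out : (g + 1) * cpg_out]  # (cpg_out, cpg_in, kh, kw)
        xg = win[g * cpg_in : (g + 1) * cpg_in]  # (cpg_in, H, W, kh, kw)
        out[g * cpg_out : (g + 1) * cpg_out] = np.einsum(
            "oikl,ihwkl->ohw", wg, xg, optimize=True
        )
    return out


class Conv2d(Module):
    """Plain stride-1 same-padding convolution layer (optionally grouped/depthwise)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        if in_channels % groups or out_channels % groups:
            raise ValueError("in/out channels must be divisible by groups")
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = rng.normal(0.0, scale, (out_channels, in_channels // groups, kernel_size, kernel_size))
        self.bias = np.zeros(out_channels) if bias else None
        self.groups = groups
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def __call__(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[0]}")
        out = _conv2d_same(x, self.weight, groups=self.groups)
        if self.bias is not None:
            out += self.bias[:, None, None]
        return out


class GhostConv(Module):
    """Ghost convolution: primary conv for C_out/2 maps + cheap depthwise maps.

    The primary k x k convolution produces half the output channels; each of
    those maps is transformed by a cheap d x d depthwise convolution to
    produce the other half; the two sets are concatenated.  Parameter count
    (no bias) is C_in * C_out/2 * k^2 + C_out/2 * d^2, always below the
    standard convolution's C_in * C_out * k^2 for C_in >= 1.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        cheap_kernel_size: int = 3,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if out_channels % 2:
            raise ValueError("GhostConv requires an even number of output channels")
        rng = rng or np.random.default_rng(0)
        half = out_channels // 2
        self.primary = Conv2d(in_channels, half, kernel_size, bias=bias, rng=rng)
        self.cheap = Conv2d(half, half, cheap_kernel_size, groups=half, bias=bias, rng=rng)
        self.out_channels = out_channels

    def __call__(self, x: np.ndarray) -> np.ndarray:
        primary = self.primary(x)
        ghost = self.cheap(primary)
        return np.concatenate([primary, ghost], axis=0)


class ChannelAttention(Module):
    """Squeeze channel descriptors by global average+max pooling through a shared MLP."""

    def __init__(self, channels: int, reduction: int = 16, rng: np.random.Generator | None = None):
        if channels % reduction:
            raise ValueError("channels must be divisible by the reduction ratio")
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / channels), (hidden, channels))
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / hidden), (channels, hidden))

    def _mlp(self, v: np.ndarray) -> np.ndarray:
        return self.w2 @ np.maximum(self.w1 @ v, 0.0)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=(1, 2))
        return sigmoid(self._mlp(avg) + self._mlp(mx))[:, None, None]  # (C,1,1)


class SpatialAttention(Module):
    """Convolve the channel-wise average/max planes into a spatial gate."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv = Conv2d(2, 1, kernel_size, bias=False, rng=rng)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        planes = np.stack([x.mean(axis=0), x.max(axis=0)])
        return sigmoid(self.conv(planes))  # (1,H,W)


class CBAM(Module):
    """Convolutional block attention: channel gate then spatial gate.

    Returns the gated feature map together with the two attention maps
    (channel map shape (C,1,1), spatial map shape (1,H,W), both sigmoid
    outputs in (0,1)); the output never exceeds the input in magnitude.
    """

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        spatial_kernel: int = 7,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)
        self.channels = channels

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        if x.shape[0] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[0]}")
        m_c = self.channel(x)
        f_prime = m_c * x
        m_s = self.spatial(f_prime)
        f_double_prime = m_s * f_prime
        return f_double_prime, {"channel_map": m_c, "spatial_map": m_s}


class MultiScaleHeads(Module):
    """Top-down fused output branches over pyramid levels at strides 4/8/16/32.

    Given backbone feature maps ordered shallow to deep with halving spatial
    sizes, each level gets a lateral 1x1 projection to the head width; deeper
    projections are upsampled (nearest, x2) and added top-down; a 3x3 smoothing
    convolution produces each branch.  Passing four levels (strides 4..32)
    yields the extra high-resolution P2 branch; passing three reproduces the
    baseline P3-P5 behaviour.
    """

    def __init__(
        self,
        level_channels: list[int],
        head_width: int = 64,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.lateral = [Conv2d(c, head_width, 1, rng=rng) for c in level_channels]
        self.smooth = [Conv2d(head_width, head_width, 3, rng=rng) for _ in level_channels]
        self.head_width = head_width
        self.n_levels = len(level_channels)

    @staticmethod
    def _upsample2(x: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
        up = x.repeat(2, axis=1).repeat(2, axis=2)
        return up[:, : target_hw[0], : target_hw[1]]

    def __call__(self, levels: list[np.ndarray]) -> list[np.ndarray]:
        if len(levels) != self.n_levels:
            raise ValueError(f"expected {self.n_levels} levels, got {len(levels)}")
        for shallow, deep in zip(levels, levels[1:]):
            eh, ew = (shallow.shape[1] + 1) // 2, (shallow.shape[2] + 1) // 2
            if (deep.shape[1], deep.shape[2]) != (eh, ew):
                raise ValueError(
                    f"level sizes must halve: got {shallow.shape[1:]} -> {deep.shape[1:]}"
                )
        laterals = [lat(x) for lat, x in zip(self.lateral, levels)]
        fused = [None] * self.n_levels
        fused[-1] = laterals[-1]
        for i in range(self.n_levels - 2, -1, -1):
            fused[i] = laterals[i] + self._upsample2(fused[i + 1], laterals[i].shape[1:])
        return [sm(f) for sm, f in zip(self.smooth, fused)]


def build_multiscale_heads(
    backbone_levels: list[np.ndarray],
    head_width: int = 64,
    seed: int = 0,
) -> tuple[list[np.ndarray], MultiScaleHeads]:
    """Build heads sized for the given pyramid and run the forward pass."""
    rng = np.random.default_rng(seed)
    heads = MultiScaleHeads([lvl.shape[0] for lvl in backbone_levels], head_width, rng=rng)
    return heads(backbone_levels), heads


def standard_conv_param_count(in_channels: int, out_channels: int, kernel_size: int) -> int:
    """Parameter count of the plain convolution GhostConv replaces (no bias)."""
    return in_channels * out_channels * kernel_size * kernel_size
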