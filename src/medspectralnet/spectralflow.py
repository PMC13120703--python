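"""SpectralFlow: dynamic-convolution frequency decomposition of a feature map.

The module approximates self-attention at linear cost by splitting a feature
map into a piecewise-smooth low-frequency stream and its high-frequency
residue, then recombining them with learned per-stream channel attention:

1. a 1x1 conv reduces the input x (B,C,H,W) to x_l (B,C/r,H,W);
2. a global descriptor (GAP of x) generates, via a 1x1 conv, one softmax-
   normalized k*k filter per reduced channel — a dynamic convolution whose
   coefficients carry global context and are shared across spatial patches;
3. each non-overlapping k*k patch of x_l is replaced by its filter-weighted
   mean (broadcast to the whole patch), giving the low-frequency map x_la;
4. x_la is projected back to C channels (x_la_proj) and the high-frequency
   residue is defined as x_h = x - x_la_proj, so the two streams always
   reconstruct the input exactly;
5. per-stream attention vectors a_l, a_h (from GAP + 1x1 conv, normalized
   across the pair) weight the streams, and a final 1x1 conv mixes the sum.

Spatial extents that are not multiples of k are reflection-padded on the
bottom/right before smoothing and cropped afterwards (edge replication when
an axis is too short to reflect, e.g. 1x1 maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Module, global_avg_pool

STREAM_NORMS = ("softmax_pair", "sigmoid")


@dataclass
class SpectralFlowConfig:
    """Hyperparameters of one SpectralFlow instance.

    channels: width C of the input/output feature map.
    patch_size: side k of the non-overlapping smoothing patches (3 or 5 typical).
    reduction: channel reduction factor r of the low-frequency stream (C/r wide).
    stream_norm: how the two per-stream attention logits are normalized —
        "softmax_pair" gives a convex pair (a_l + a_h = 1), "sigmoid" squashes
        each independently.
    zero_init_bias: start all 1x1-conv biases at zero (makes the module map
        zero to zero at init).
    """

    channels: int
    patch_size: int = 3
    reduction: int = 2
    stream_norm: str = "softmax_pair"
    zero_init_bias: bool = True

    def __post_init__(self):
        if self.channels < 1 or self.patch_size < 1 or self.reduction < 1:
            raise ValueError("channels, patch_size and reduction must be positive")
        if self.channels < self.reduction or self.channels % self.reduction:
            raise ValueError("channels must be a positive multiple of reduction")
        if self.stream_norm not in STREAM_NORMS:
            raise ValueError(f"stream_norm must be one of {STREAM_NORMS}")

    @property
    def reduced(self):
        return self.channels // self.reduction


@dataclass
class SpectralDecomposition:
    """All named intermediates of one SpectralFlow pass."""

    global_descriptor: Tensor   # B×C×1×1 pooled descriptor
    patch_weights: Tensor       # B×(C/r)×k², softmax-normalized
    x_l: Tensor                 # reduced low-frequency stream
    x_la: Tensor                # patch-smoothed low-frequency map
    x_la_proj: Tensor           # low stream projected back to C channels
    x_h: Tensor                 # high-frequency residue (input − x_la_proj)
    a_l: Tensor                 # per-channel low-stream attention, B×C×1×1
    a_h: Tensor                 # per-channel high-stream attention
    x_f: Tensor                 # fused output, same shape as input


def smooth(x_l, patch_weights, k):
    """Replace every non-overlapping k×k patch by its weighted mean.

    ``patch_weights`` (B, C, k²) must be normalized over the k² axis; the
    weighted patch mean is broadcast back to all k² positions, producing a
    piecewise-constant (low-frequency) map of the original extent.
    """
    if not isinstance(x_l, Tensor):
        x_l = Tensor(x_l)
    if not isinstance(patch_weights, Tensor):
        patch_weights = Tensor(patch_weights)
    B, C, H, W = x_l.shape
    if patch_weights.shape != (B, C, k * k):
        raise ValueError(f"patch_weights must be {(B, C, k * k)}, got {patch_weights.shape}")
    if k == 1:
        return x_l
    pad_h = (-H) % k
    pad_w = (-W) % k
    xp = ag.pad_bottom_right(x_l, pad_h, pad_w)
    nh, nw = (H + pad_h) // k, (W + pad_w) // k
    patches = ag.reshape(xp, (B, C, nh, k, nw, k))
    w6 = ag.reshape(patch_weights, (B, C, 1, k, 1, k))
    means = ag.sum_(ag.mul(patches, w6), axis=(3, 5), keepdims=True)
    ones = ag.constant(np.ones((1, 1, 1, k, 1, k), dtype=x_l.dtype))
    full = ag.reshape(ag.mul(means, ones), (B, C, H + pad_h, W + pad_w))
    if pad_h or pad_w:
        full = full[:, :, :H, :W]
    return full


class SpectralFlow(Module):
    """One SpectralFlow block; preserves the input shape B×C×H×W."""

    def __init__(self, cfg: SpectralFlowConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C, Cr, k = cfg.channels, cfg.reduced, cfg.patch_size
        zb = cfg.zero_init_bias
        self.reduce = Conv2d(C, Cr, 1, rng, zero_init_bias=zb)
        self.filter_gen = Conv2d(C, Cr * k * k, 1, rng, zero_init_bias=zb)
        self.proj = Conv2d(Cr, C, 1, rng, zero_init_bias=zb)
        self.attn_low = Conv2d(C, C, 1, rng, zero_init_bias=zb)
        self.attn_high = Conv2d(C, C, 1, rng, zero_init_bias=zb)
        self.fuse = Conv2d(C, C, 1, rng, zero_init_bias=zb)

    def _check_channels(self, x):
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"SpectralFlow configured for {self.cfg.channels} channels, input has {x.shape[1]}")

    def patch_filter_weights(self, x, return_descriptor=False):
        """Softmax-normalized dynamic filter coefficients, B×(C/r)×k².

        The coefficients derive from the global average-pooled descriptor, so
        every spatial patch shares the same (globally informed) filter.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_channels(x)
        k, Cr = self.cfg.patch_size, self.cfg.reduced
        g = global_avg_pool(x)                                  # B×C×1×1
        logits = self.filter_gen(g)                             # B×(C/r)k²×1×1
        logits = ag.reshape(logits, (x.shape[0], Cr, k * k))
        w = ag.softmax(logits, axis=-1)
        return (w, g) if return_descriptor else w

    def decompose(self, x, x_la):
        """Project the low stream back to C channels and take the residue (x_h = x − x̃_la)."""
        x_la_proj = self.proj(x_la)
        x_h = ag.sub(x, x_la_proj)
        return x_la_proj, x_h

    def stream_fuse(self, x_la_proj, x_h, return_attention=False):
        """Attention-weight the two streams and mix with the final 1×1 conv."""
        if x_la_proj.shape != x_h.shape:
            raise ValueError("stream shapes differ")
        ll = self.attn_low(global_avg_pool(x_la_proj))
        lh = self.attn_high(global_avg_pool(x_h))
        if self.cfg.stream_norm == "softmax_pair":
            a_l = ag.sigmoid(ag.sub(ll, lh))    # pairwise softmax
            a_h = ag.sub(1.0, a_l)
        else:
            a_l = ag.sigmoid(ll)
            a_h = ag.sigmoid(lh)
        x_f = self.fuse(ag.add(ag.mul(a_l, x_la_proj), ag.mul(a_h, x_h)))
        return (x_f, a_l, a_h) if return_attention else x_f

    def forward(self, x, return_decomposition=False):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_channels(x)
        k = self.cfg.patch_size
        w, g = self.patch_filter_weights(x, return_descriptor=True)
        x_l = self.reduce(x)
        x_la = smooth(x_l, w, k)
        x_la_proj, x_h = self.decompose(x, x_la)
        x_f, a_l, a_h = self.stream_fuse(x_la_proj, x_h, return_attention=True)
        if return_decomposition:
            return x_f, SpectralDecomposition(
                global_descriptor=g, patch_weights=w, x_l=x_l, x_la=x_la,
                x_la_proj=x_la_proj, x_h=x_h, a_l=a_l, a_h=a_h, x_f=x_f)
        return x_f
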