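"""ContextGate: three-pathway gated feature modulation with a residual.

For an input x (B,C,H,W), three pathways run in parallel:

* spatial   — depthwise 3×3 conv, refinement by an internal SpectralFlow at
              full width, then a 1×1 conv down to floor(C/3) channels (c_out);
* gating    — 1×1 conv to floor(C/3) channels followed by a nonlinearity
              (GELU by default, sigmoid optionally) giving the gate g;
* identity  — plain 1×1 conv to floor(C/3) channels (i).

The gate multiplicatively modulates the channel concatenation of the spatial
and identity halves (x_mod = g̃ ⊙ Concat(c_out, i), with g repeated once along
channels to match the 2·floor(C/3) width), a final 1×1 conv restores C
channels (x_out), and the block output is the residual sum x_final = x_out + x.
With all learned parameters zeroed the block is exactly the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Module
from .spectralflow import SpectralFlow, SpectralFlowConfig

GATE_NONLINEARITIES = ("gelu", "sigmoid")


@dataclass
class ContextGateConfig:
    """Hyperparameters of one ContextGate block.

    branch_width defaults to floor(channels/3); spatial_kernel is fixed at 3.
    inner_spectralflow configures the SpectralFlow refining the spatial path
    (independent parameters from any network-level SpectralFlow).
    """

    channels: int
    branch_width: int | None = None
    gate_nonlinearity: str = "gelu"
    spatial_kernel: int = 3
    zero_init_bias: bool = True
    inner_spectralflow: SpectralFlowConfig | None = None

    def __post_init__(self):
        if self.branch_width is None:
            self.branch_width = self.channels // 3
        if self.branch_width < 1:
            raise ValueError("branch_width must be >= 1 (need channels >= 3)")
        if self.spatial_kernel != 3:
            raise ValueError("spatial_kernel is fixed at 3")
        if self.gate_nonlinearity not in GATE_NONLINEARITIES:
            raise ValueError(f"gate_nonlinearity must be one of {GATE_NONLINEARITIES}")
        if self.inner_spectralflow is None:
            self.inner_spectralflow = SpectralFlowConfig(
                channels=self.channels,
                reduction=2 if self.channels % 2 == 0 else 1,
                zero_init_bias=self.zero_init_bias)


@dataclass
class GateDecomposition:
    """Named intermediates of one ContextGate pass."""

    c_out: Tensor    # spatial pathway output, B×⌊C/3⌋×H×W
    g: Tensor        # gating tensor, B×⌊C/3⌋×H×W
    i: Tensor        # identity pathway projection
    x_mod: Tensor    # gated concatenation, B×2⌊C/3⌋×H×W
    x_out: Tensor    # projected back to C channels
    x_final: Tensor  # residual output, x_out + input


def gate_fuse(c_out, i, g):
    """x_mod = g̃ ⊙ Concat(c_out, i); the gate is repeated across both halves."""
    if c_out.shape != i.shape or g.shape != c_out.shape:
        raise ValueError("gate_fuse inputs must share the same B×⌊C/3⌋×H×W shape")
    stacked = ag.concat([c_out, i], axis=1)
    gate = ag.concat([g, g], axis=1)
    return ag.mul(gate, stacked)


class ContextGate(Module):
    def __init__(self, cfg: ContextGateConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C, bw = cfg.channels, cfg.branch_width
        zb = cfg.zero_init_bias
        self.dw = Conv2d(C, C, 3, rng, padding=1, groups=C, zero_init_bias=zb)
        self.inner_sf = SpectralFlow(cfg.inner_spectralflow, rng)
        self.spatial_reduce = Conv2d(C, bw, 1, rng, zero_init_bias=zb)
        self.gate_conv = Conv2d(C, bw, 1, rng, zero_init_bias=zb)
        self.id_conv = Conv2d(C, bw, 1, rng, zero_init_bias=zb)
        self.proj = Conv2d(2 * bw, C, 1, rng, zero_init_bias=zb)

    def spatial_path(self, x, return_depthwise=False):
        """Depthwise 3×3 → SpectralFlow refinement → 1×1 reduction to ⌊C/3⌋."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        d = self.dw(x)
        c_out = self.spatial_reduce(self.inner_sf(d))
        return (c_out, d) if return_depthwise else c_out

    def gating_path(self, x):
        pre = self.gate_conv(x if isinstance(x, Tensor) else Tensor(x))
        if self.cfg.gate_nonlinearity == "gelu":
            return ag.gelu(pre)
        return ag.sigmoid(pre)

    def identity_path(self, x):
        return self.id_conv(x if isinstance(x, Tensor) else Tensor(x))

    def forward(self, x, return_decomposition=False):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"ContextGate configured for {self.cfg.channels} channels, input has {x.shape[1]}")
        c_out, self._last_depthwise = self.spatial_path(x, return_depthwise=True)
        g = self.gating_path(x)
        i = self.identity_path(x)
        x_mod = gate_fuse(c_out, i, g)
        x_out = self.proj(x_mod)
        x_final = ag.add(x_out, x)
        if return_decomposition:
            return x_final, GateDecomposition(c_out=c_out, g=g, i=i, x_mod=x_mod,
                                              x_out=x_out, x_final=x_final)
        return x_final
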