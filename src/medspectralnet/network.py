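"""Full MedSpectralNet assembly.

Pipeline: backbone features f_b → two parallel pathways on the same f_b
(a SpectralFlow "USM" and a ContextGate "GM") → elementwise residual fusion
f_b + USM(f_b) + GM(f_b) → a second SpectralFlow refinement → batch norm →
global average pooling → linear classifier producing logits. Softmax is
applied only when probabilities are requested, never inside the training
forward pass.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .backbone import ResNet18Features
from .contextgate import ContextGate, ContextGateConfig
from .nn import BatchNorm2d, Linear, Module, global_avg_pool
from .spectralflow import SpectralFlow, SpectralFlowConfig

BACKBONES = ("resnet18",)


@dataclass
class ModelConfig:
    num_classes: int
    input_size: int = 224
    backbone: str = "resnet18"
    pretrained: bool = False
    backbone_channels: int = 512
    usm: SpectralFlowConfig | None = None
    gm: ContextGateConfig | None = None
    second_usm: SpectralFlowConfig | None = None

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.backbone == "resnet18" and self.backbone_channels != 512:
            raise ValueError("resnet18 backbone has 512 output channels")
        C = self.backbone_channels
        if self.usm is None:
            self.usm = SpectralFlowConfig(channels=C)
        if self.gm is None:
            self.gm = ContextGateConfig(channels=C)
        if self.second_usm is None:
            self.second_usm = SpectralFlowConfig(channels=C)

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if d.get("usm"):
            d["usm"] = SpectralFlowConfig(**d["usm"])
        if d.get("second_usm"):
            d["second_usm"] = SpectralFlowConfig(**d["second_usm"])
        if d.get("gm"):
            gm = dict(d["gm"])
            if gm.get("inner_spectralflow"):
                gm["inner_spectralflow"] = SpectralFlowConfig(**gm["inner_spectralflow"])
            d["gm"] = ContextGateConfig(**gm)
        return cls(**d)


def fuse_pathways(f_b, usm_out, gm_out):
    """Elementwise residual fusion of the backbone map with both pathway outputs."""
    if f_b.shape != usm_out.shape or f_b.shape != gm_out.shape:
        raise ValueError("fuse_pathways requires three equally shaped maps")
    return ag.add(ag.add(f_b, usm_out), gm_out)


def predict_proba(logits):
    """Row-wise softmax over classes; accepts a Tensor or ndarray of logits."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logits must be finite")
    shifted = arr - arr.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class MedSpectralNet(Module):
    """Dual-stream frequency-decomposition classifier."""

    # names of the activation sites registered for Grad-CAM
    ACTIVATION_SITES = ("contextgate.spatial", "spectralflow2.output")

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        C = cfg.backbone_channels
        self.backbone = ResNet18Features(rng)
        self.usm = SpectralFlow(cfg.usm, rng)
        self.gm = ContextGate(cfg.gm, rng)
        self.usm2 = SpectralFlow(cfg.second_usm, rng)
        self.bn = BatchNorm2d(C)
        self.fc = Linear(C, cfg.num_classes, rng)
        self.activations = {}

    def backbone_forward(self, images):
        return self.backbone(images)

    def forward(self, images):
        f_b = self.backbone_forward(images)
        usm_out = self.usm(f_b)
        gm_out = self.gm(f_b)
        fused = fuse_pathways(f_b, usm_out, gm_out)
        refined = self.usm2(fused)
        # Grad-CAM hooks: post-depthwise spatial activation and the second
        # SpectralFlow output
        self.activations = {
            "contextgate.spatial": self.gm._last_depthwise,
            "spectralflow2.output": refined,
        }
        pooled = self.bn(refined)
        f_c = ag.reshape(global_avg_pool(pooled), (pooled.shape[0], self.cfg.backbone_channels))
        return self.fc(f_c)


def save_checkpoint(model: MedSpectralNet, path, seed=None, extra=None):
    """Serialize parameters+buffers (npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **{k: v for k, v in model.state_dict().items()})
    sidecar = {"model_config": model.cfg.to_dict(), "seed": seed}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path):
    """Rebuild a MedSpectralNet from an archive + sidecar written by save_checkpoint."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(sidecar["model_config"])
    model = MedSpectralNet(cfg, np.random.default_rng(0))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model, sidecar
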