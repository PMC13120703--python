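"""18-layer residual backbone (standard basic-block ResNet layout).

The feature extractor maps B×3×H×W images to B×512×(H/32)×(W/32) maps; the
classifier variant adds global average pooling and a fully connected head and
exists mainly as the parameter/MAC reference model for the profiler
(11,689,512 trainable parameters with a 1000-class head).

Convolutions carry no bias (batch norm follows each), matching the standard
layout and its published parameter count. Weights are Kaiming-normal; a
state-dict of pretrained weights can be loaded via ``Module.load_state_dict``
but random initialization is the default.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .nn import BatchNorm2d, Conv2d, Linear, MaxPool2d, Module, ReLU, global_avg_pool


class BasicBlock(Module):
    def __init__(self, in_channels, out_channels, rng, stride=1):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.down_conv = Conv2d(in_channels, out_channels, 1, rng, stride=stride, bias=False)
            self.down_bn = BatchNorm2d(out_channels)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x):
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return ag.relu(ag.add(out, identity))


class ResNet18Features(Module):
    """Backbone truncated before pooling/classifier; output B×512×H/32×W/32."""

    out_channels = 512

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = BatchNorm2d(64)
        self.maxpool = MaxPool2d(3, stride=2, padding=1)
        self.layer1 = [BasicBlock(64, 64, rng), BasicBlock(64, 64, rng)]
        self.layer2 = [BasicBlock(64, 128, rng, stride=2), BasicBlock(128, 128, rng)]
        self.layer3 = [BasicBlock(128, 256, rng, stride=2), BasicBlock(256, 256, rng)]
        self.layer4 = [BasicBlock(256, 512, rng, stride=2), BasicBlock(512, 512, rng)]

    def forward(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(x)
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {H}x{W}")
        x = ag.relu(self.bn1(self.conv1(x)))
        x = self.maxpool(x)
        for block in (*self.layer1, *self.layer2, *self.layer3, *self.layer4):
            x = block(x)
        return x


class ResNet18Classifier(Module):
    """Backbone + GAP + fully connected head (reference/baseline model)."""

    def __init__(self, rng: np.random.Generator, num_classes=1000):
        super().__init__()
        self.features = ResNet18Features(rng)
        self.fc = Linear(512, num_classes, rng)

    def forward(self, x):
        f = self.features(x)
        pooled = ag.reshape(global_avg_pool(f), (f.shape[0], 512))
        return self.fc(pooled)
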