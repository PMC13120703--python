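"""Grad-CAM heatmaps over named internal activation sites.

For a registered activation A (captured during the forward pass) and a class
logit y_c, the channel weights are the spatial means of dy_c/dA, the raw map
is ReLU(sum_c w_c * A_c), bilinearly upsampled to the input size and min-max
normalized to [0,1]. A raw map whose maximum is below 1e-8 is returned as all
zeros with ``low_evidence`` set — activation failure is itself a useful
uncertainty signal rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from . import autograd as ag
from .autograd import Tensor

LOW_EVIDENCE_THRESHOLD = 1e-8


@dataclass
class Heatmap:
    values: np.ndarray        # H×W in [0,1]
    target_layer: str
    class_index: int
    low_evidence: bool = False
    input_reference: str | None = None


def gradcam(model, image, target_layer, class_index, input_reference=None):
    """Grad-CAM heatmap of one image (3×H×W or 1×3×H×W) at a registered site."""
    sites = getattr(model, "ACTIVATION_SITES", ())
    if target_layer not in sites:
        raise ValueError(f"unknown target layer {target_layer!r}; registered sites: {list(sites)}")
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[0] != 1:
        raise ValueError("gradcam expects a single image")
    H, W = arr.shape[2], arr.shape[3]

    model.eval()
    model.zero_grad()
    # requires_grad on the input keeps the graph alive through parameter-free
    # stretches, so the registered activations always receive gradients
    logits = model(Tensor(arr, requires_grad=True))
    if not 0 <= class_index < logits.shape[1]:
        raise ValueError(f"class_index must be in [0, {logits.shape[1]})")
    activation = model.activations[target_layer]
    onehot = np.zeros_like(logits.data)
    onehot[0, class_index] = 1.0
    logits.backward(onehot)

    A = activation.data[0]
    dA = activation.grad[0] if activation.grad is not None else np.zeros_like(A)
    weights = dA.mean(axis=(1, 2))
    raw = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)

    if raw.max() < LOW_EVIDENCE_THRESHOLD:
        return Heatmap(values=np.zeros((H, W), dtype=np.float32),
                       target_layer=target_layer, class_index=class_index,
                       low_evidence=True, input_reference=input_reference)

    up = sktransform.resize(raw, (H, W), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    lo, hi = up.min(), up.max()
    values = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return Heatmap(values=values.astype(np.float32), target_layer=target_layer,
                   class_index=class_index, low_evidence=False,
                   input_reference=input_reference)


def save_overlay_png(heatmap: Heatmap, image_rgb, path, alpha=0.5):
    """Blend the heatmap (simple blue→red ramp) over an H×W×3 [0,1] image."""
    from PIL import Image

    h = heatmap.values
    color = np.stack([h, np.zeros_like(h), 1.0 - h], axis=-1)
    img = np.asarray(image_rgb, dtype=np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    blend = np.clip((1 - alpha) * img + alpha * color, 0, 1)
    Image.fromarray((blend * 255).astype(np.uint8)).save(path)
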