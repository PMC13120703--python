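"""Seeded training and evaluation loops.

Supports the ablation arms (Adam / SGD / RMSprop; plain vs CutMix-augmented
training) with cross-entropy on logits; under CutMix the loss is the convex
mixture lam*CE(logits, labels_a) + (1-lam)*CE(logits, labels_b). Benchmark
defaults follow the reported protocol (200 epochs, batch 128); the synthetic
smoke configuration in the tests uses far smaller sizes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import metrics as M
from .datapipe import AugmentationConfig, augment, cutmix, normalize, resize
from .network import MedSpectralNet, predict_proba
from .nn import cross_entropy

OPTIMIZERS = ("adam", "sgd", "rmsprop")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    momentum: float = 0.9            # SGD only
    epochs: int = 200
    batch_size: int = 128
    augmentation: str = "none"       # "none", "normal" or "cutmix"
    input_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}; valid: {OPTIMIZERS}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.augmentation not in ("none", "normal", "cutmix"):
            raise ValueError("augmentation must be 'none', 'normal' or 'cutmix'")


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "test_loss", "train_accuracy", "test_accuracy"])
            for i in range(len(self)):
                writer.writerow([i + 1, self.train_loss[i], self.test_loss[i],
                                 self.train_accuracy[i], self.test_accuracy[i]])


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params, lr, momentum=0.0, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data if self.weight_decay else p.grad
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.data = p.data - self.lr * g

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        bc1 = 1 - self.b1 ** self._t
        bc2 = 1 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data if self.weight_decay else p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    zero_grad = SGD.zero_grad


class RMSprop:
    def __init__(self, params, lr, alpha=0.99, eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.weight_decay = weight_decay
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data if self.weight_decay else p.grad
            s *= self.alpha
            s += (1 - self.alpha) * g * g
            p.data = p.data - self.lr * g / (np.sqrt(s) + self.eps)

    zero_grad = SGD.zero_grad


def make_optimizer(name, params, cfg: TrainConfig):
    if name == "adam":
        return Adam(params, cfg.learning_rate, weight_decay=cfg.weight_decay)
    if name == "sgd":
        return SGD(params, cfg.learning_rate, momentum=cfg.momentum,
                   weight_decay=cfg.weight_decay)
    if name == "rmsprop":
        return RMSprop(params, cfg.learning_rate, weight_decay=cfg.weight_decay)
    raise ValueError(f"unknown optimizer {name!r}; valid: {OPTIMIZERS}")


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def _prepare(images, input_size):
    """Raw HWC images (uint8 or [0,1] float) → normalized N×3×S×S float32."""
    return normalize(resize(images, input_size))


def mixed_cross_entropy(logits, labels_a, labels_b, lam):
    """CutMix loss; degenerates to plain cross-entropy at lam = 1."""
    if lam == 1.0:
        return cross_entropy(logits, labels_a)
    return ag.add(ag.mul(cross_entropy(logits, labels_a), lam),
                  ag.mul(cross_entropy(logits, labels_b), 1.0 - lam))


def evaluate(model, data, input_size=None, batch_size=64, num_classes=None):
    """Deterministic evaluation: loss, accuracy, confusion matrix, OvR curves."""
    images, labels = data
    if len(labels) == 0:
        raise ValueError("empty evaluation dataset")
    input_size = input_size or model.cfg.input_size
    num_classes = num_classes or model.cfg.num_classes
    x = _prepare(images, input_size)
    model.eval()
    probs, losses = [], []
    for start in range(0, len(labels), batch_size):
        xb = ag.Tensor(x[start:start + batch_size])
        yb = labels[start:start + batch_size]
        logits = model(xb)
        losses.append(cross_entropy(logits, yb).item() * len(yb))
        probs.append(predict_proba(logits))
    probs = np.concatenate(probs)
    preds = probs.argmax(axis=1)
    confusion = M.confusion_matrix(labels, preds, num_classes)
    roc_curves, roc_areas, roc_macro = M.one_vs_rest(probs, labels, kind="roc")
    pr_curves, pr_areas, pr_macro = M.one_vs_rest(probs, labels, kind="pr")
    return {
        "loss": float(sum(losses) / len(labels)),
        "accuracy": M.accuracy(confusion),
        "confusion": confusion,
        "probabilities": probs,
        "roc_curves": roc_curves, "roc_auc": roc_areas, "roc_auc_macro": roc_macro,
        "pr_curves": pr_curves, "pr_auc": pr_areas, "pr_auc_macro": pr_macro,
    }


def train(model: MedSpectralNet, train_data, eval_data, cfg: TrainConfig,
          aug_cfg: AugmentationConfig | None = None, verbose=False):
    """Epoch loop with seeded shuffling; returns (model, History).

    The model with the best evaluation accuracy seen during training is
    restored at the end. Raises on a non-finite loss, naming epoch and batch.
    """
    images, labels = train_data
    rng = np.random.default_rng(cfg.seed)
    optimizer = make_optimizer(cfg.optimizer, model.parameters(), cfg)
    if aug_cfg is None:
        aug_cfg = AugmentationConfig(mode="cutmix" if cfg.augmentation == "cutmix" else "normal")
    history = History()
    best_acc, best_state = -1.0, None

    static = None
    if cfg.augmentation == "none":
        static = _prepare(images, cfg.input_size)

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(labels))
        epoch_loss, epoch_correct = 0.0, 0
        for bi, start in enumerate(range(0, len(labels), cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            yb = labels[idx]
            if static is not None:
                xb = static[idx]
            else:
                raw = resize(images[idx], cfg.input_size)
                raw = raw.astype(np.float32) / (255.0 if raw.dtype == np.uint8 else 1.0)
                raw = np.stack([augment(im, aug_cfg, rng) for im in raw])
                xb = normalize(raw)
            labels_a, labels_b, lam = yb, yb, 1.0
            if cfg.augmentation == "cutmix":
                xb, labels_a, labels_b, lam = cutmix(xb, yb, aug_cfg, rng)
            logits = model(ag.Tensor(xb))
            loss = mixed_cross_entropy(logits, labels_a, labels_b, lam)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite loss at epoch {epoch + 1}, batch {bi + 1}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item() * len(idx)
            epoch_correct += int((logits.data.argmax(axis=1) == yb).sum())
        stats = evaluate(model, eval_data, cfg.input_size)
        history.train_loss.append(epoch_loss / len(labels))
        history.train_accuracy.append(epoch_correct / len(labels))
        history.test_loss.append(stats["loss"])
        history.test_accuracy.append(stats["accuracy"])
        if stats["accuracy"] > best_acc:
            best_acc = stats["accuracy"]
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: train_loss={history.train_loss[-1]:.4f} "
                  f"test_acc={stats['accuracy']:.4f}")

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
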