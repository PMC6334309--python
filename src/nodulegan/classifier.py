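"""AlexNet-style nodule classifier with the two-stage training protocol.

Stage 1 (*pretrain*): train the full network from random initialization on
GAN-generated benign vs malignant images.

Stage 2 (*fine-tune*): re-initialize the three fully connected layers, keep
the pretrained convolutional weights as starting values, and retrain the
whole network on real (here: phantom) nodule patches with SGD.

The full-scale architecture is the canonical AlexNet layout with a 2-way
softmax: five convolution layers, three overlapping 3x3/stride-2 max-pool
layers, three fully connected layers with dropout 0.5. Input images are
resized to 256x256 and center-cropped to 227x227, which makes the layer
arithmetic exact: conv1 (96 kernels, 11x11, stride 4) gives 55x55x96 and
pool1 gives 27x27x96. A ``tiny`` preset (32x32 input, narrow channels)
keeps the same code path at CPU test scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import hu_to_unit, resize_square


@dataclass(frozen=True)
class ClassifierArch:
    """Architecture description; `paper()` and `tiny()` are the two presets."""

    input_size: int = 227
    resize_size: int = 256
    # (out_channels, kernel, stride, pad) per conv layer
    conv: tuple = ((96, 11, 4, 0), (256, 5, 1, 2), (384, 3, 1, 1), (384, 3, 1, 1), (256, 3, 1, 1))
    pool_after: tuple = (0, 1, 4)  # conv indices followed by 3x3 stride-2 max-pool
    fc: tuple = (4096, 4096)
    n_classes: int = 2
    dropout: float = 0.5
    # FC weight init std; None = fan-in (He) scaling. The fixed 0.01 matches the
    # Caffe convention and suits the 4096-wide paper head; narrow tiny heads
    # need fan-in scaling to produce usable gradients.
    fc_init_std: float | None = 0.01

    @classmethod
    def paper(cls) -> "ClassifierArch":
        return cls()

    @classmethod
    def tiny(cls) -> "ClassifierArch":
        return cls(
            input_size=32,
            resize_size=32,  # no crop at test scale
            conv=((8, 5, 1, 2), (16, 3, 1, 1), (16, 3, 1, 1)),
            pool_after=(0, 1, 2),
            fc=(32,),
            fc_init_std=None,
        )

    def shape_trace(self) -> list[tuple[int, int]]:
        """(spatial side, channels) after each conv/pool stage; validates arithmetic."""
        side, ch = self.input_size, 1
        trace = []
        for i, (out_ch, k, s, p) in enumerate(self.conv):
            side = (side + 2 * p - k) // s + 1
            ch = out_ch
            trace.append((side, ch))
            if i in self.pool_after:
                side = (side - 3) // 2 + 1
                trace.append((side, ch))
            if side < 1:
                raise ValueError(f"architecture collapses to {side} px after conv {i + 1}")
        return trace


@dataclass
class PretrainConfig:
    """Stage-1 hyperparameters (unspecified upstream; SGD+momentum defaults)."""

    epochs: int = 10
    lr: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FinetuneConfig:
    epochs: int = 30
    lr: float = 0.0001
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


class NoduleClassifier:
    """Conv feature stack + FC head; benign = class 0, malignant = class 1."""

    def __init__(self, arch: ClassifierArch, seed: int = 0):
        self.arch = arch
        self.trace = arch.shape_trace()
        ss = np.random.SeedSequence(seed)
        s_conv, s_fc, s_drop = ss.spawn(3)
        rng = np.random.default_rng(s_conv)
        layers = []
        in_ch = 1
        for i, (out_ch, k, s, p) in enumerate(arch.conv):
            layers.append(nn.Conv2d(in_ch, out_ch, k, stride=s, pad=p, rng=rng))
            layers.append(nn.ReLU())
            if i in arch.pool_after:
                layers.append(nn.MaxPool2d(3, 2))
            in_ch = out_ch
        self.features = nn.Sequential(*layers)
        self._dropout_rng = np.random.default_rng(s_drop)
        self.head = self._make_head(np.random.default_rng(s_fc))

    def _make_head(self, rng: np.random.Generator) -> nn.Sequential:
        side, ch = self.trace[-1]
        in_f = side * side * ch
        layers: list[nn.Layer] = [nn.Flatten()]
        for width in self.arch.fc:
            layers.extend(
                [
                    nn.Linear(in_f, width, rng=rng, w_std=self.arch.fc_init_std),
                    nn.ReLU(),
                    nn.Dropout(self.arch.dropout, rng=self._dropout_rng),
                ]
            )
            in_f = width
        layers.append(nn.Linear(in_f, self.arch.n_classes, rng=rng, w_std=self.arch.fc_init_std))
        return nn.Sequential(*layers)

    # -- forward / predict ------------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        self.features.set_training(training)
        self.head.set_training(training)
        return self.head.forward(self.features.forward(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (inference mode: dropout off, deterministic)."""
        return nn.softmax(self.forward_logits(x, training=False))

    def backward(self, dlogits: np.ndarray):
        self.features.backward(self.head.backward(dlogits))

    def parameters(self):
        yield from self.features.parameters()
        yield from self.head.parameters()

    def zero_grad(self):
        self.features.zero_grad()
        self.head.zero_grad()

    # -- transfer ----------------------------------------------------------
    def clone(self) -> "NoduleClassifier":
        other = NoduleClassifier(self.arch, seed=0)
        other.features.load_state_dict(self.features.state_dict())
        other.head.load_state_dict(self.head.state_dict())
        return other

    def replace_fc(self, seed: int):
        """Re-initialize the FC head (Gaussian std 0.01, zero bias); conv kept."""
        self.head = self._make_head(np.random.default_rng(np.random.SeedSequence(seed)))


def preprocess(patch, arch: ClassifierArch, assume_unit_scale: bool = False) -> np.ndarray:
    """Patch -> network input plane: resize, center-crop, scale to [-1, 1].

    Accepts a PatchImage or a square 2-D array. HU-scale inputs are windowed
    to [-1, 1]; set ``assume_unit_scale`` for GAN-generated images that are
    already on that scale.
    """
    pixels = np.asarray(getattr(patch, "pixels", patch), dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"patch must be square 2-D, got shape {pixels.shape}")
    if not assume_unit_scale:
        pixels = hu_to_unit(pixels)
    pixels = resize_square(pixels, arch.resize_size)
    off = (arch.resize_size - arch.input_size) // 2
    if off < 0:
        raise ValueError("input_size larger than resize_size")
    pixels = pixels[off : off + arch.input_size, off : off + arch.input_size]
    return pixels.astype(np.float32)


def _stack(patches, arch, assume_unit_scale=False) -> np.ndarray:
    return np.stack([preprocess(p, arch, assume_unit_scale) for p in patches])[:, None]


def _sgd_train(model: NoduleClassifier, x: np.ndarray, y: np.ndarray, epochs, lr, momentum, batch_size, rng):
    """Plain shuffled-minibatch SGD with softmax cross-entropy; returns loss curve."""
    opt = nn.SGD(_ModelView(model), lr=lr, momentum=momentum)
    n = x.shape[0]
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward_logits(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
    return losses


class _ModelView:
    """Adapter so optimizers can traverse a NoduleClassifier like a Sequential."""

    def __init__(self, model: NoduleClassifier):
        self._model = model

    def parameters(self):
        yield from self._model.parameters()


def pretrain(
    generated_benign: np.ndarray,
    generated_malignant: np.ndarray,
    config: PretrainConfig,
    arch: ClassifierArch | None = None,
) -> tuple[NoduleClassifier, list]:
    """Stage 1: train from random init on GAN-generated images ([-1,1] scale)."""
    arch = arch or ClassifierArch.paper()
    if len(generated_benign) == 0 or len(generated_malignant) == 0:
        raise ValueError("both generated classes must be non-empty")
    x = np.concatenate(
        [_stack(generated_benign, arch, True), _stack(generated_malignant, arch, True)]
    )
    y = np.array([0] * len(generated_benign) + [1] * len(generated_malignant))
    model = NoduleClassifier(arch, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    losses = _sgd_train(model, x, y, config.epochs, config.lr, config.momentum, config.batch_size, rng)
    return model, losses


def finetune(
    pretrained: NoduleClassifier,
    patches,
    labels,
    config: FinetuneConfig,
) -> NoduleClassifier:
    """Stage 2: replace the FC head, keep conv weights, retrain everything.

    ``patches``: PatchImages (HU scale). ``labels``: 0 benign / 1 malignant.
    ``epochs=0`` returns the replaced-head model untouched.
    """
    model = pretrained.clone()
    model.replace_fc(seed=config.seed)
    if config.epochs == 0:
        return model
    x = _stack(patches, model.arch)
    y = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    _sgd_train(model, x, y, config.epochs, config.lr, config.momentum, config.batch_size, rng)
    return model


def predict(model: NoduleClassifier, patches, assume_unit_scale: bool = False, batch_size: int = 64) -> np.ndarray:
    """Per-patch malignant probability in [0, 1]; deterministic (dropout off)."""
    x = _stack(patches, model.arch, assume_unit_scale)
    out = []
    for start in range(0, x.shape[0], batch_size):
        out.append(model.forward(x[start : start + batch_size])[:, 1])
    return np.concatenate(out)
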