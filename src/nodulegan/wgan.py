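"""Per-class Wasserstein GAN for nodule image synthesis.

Generator: a 100-d latent drawn uniformly from [-1, 1] is projected to a
4x4 feature map and upsampled by fractionally strided 5x5 convolutions
(stride 2), doubling the spatial side per layer until the configured image
size (4 -> 8 -> 16 -> 32 -> 64 at the default 64 px, i.e. four such layers);
batch normalization on every layer except the output, which is tanh.

Critic: the mirror-image stack of strided 5x5 convolutions (spatial side
halved, channels doubled per layer), batch normalization on each
convolution layer, ending in a single unbounded linear score (no sigmoid).

Training alternates ``n_critic`` critic updates - maximize
mean score(real) - mean score(fake), then clip every critic parameter into
[-c, c] - with one generator update (maximize mean score of generated),
both via RMSprop. One GAN is trained per nodule class; the pipeline never
mixes benign and malignant images in one fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import hu_to_unit, resize_square


@dataclass
class WGANConfig:
    latent_dim: int = 100
    lr: float = 0.00005
    epochs: int = 1000
    clip_value: float = 0.01
    n_critic: int = 5
    batch_size: int = 64
    image_size: int = 64
    base_channels: int = 64  # critic first-layer width; generator widths mirror it
    batchnorm_critic: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.clip_value <= 0:
            raise ValueError("clip_value must be > 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        n = self.image_size
        if n < 8 or n & (n - 1) != 0:
            raise ValueError(f"image_size must be a power of two >= 8, got {n}")

    @property
    def n_layers(self) -> int:
        """Upsampling (and critic conv) layer count: 4 at 64 px."""
        return int(np.log2(self.image_size // 4))

    @classmethod
    def tiny(cls, image_size: int = 32, **kwargs) -> "WGANConfig":
        """CPU-scale preset: narrow channels, small batches."""
        kwargs.setdefault("base_channels", 8)
        kwargs.setdefault("batch_size", 16)
        kwargs.setdefault("epochs", 1)
        return cls(image_size=image_size, **kwargs)


@dataclass
class TrainTrace:
    critic_loss: list = field(default_factory=list)
    gen_loss: list = field(default_factory=list)
    w_estimate: list = field(default_factory=list)
    epoch: list = field(default_factory=list)


def build_generator(config: WGANConfig, rng: np.random.Generator) -> nn.Sequential:
    n_up = config.n_layers
    c0 = config.base_channels * 2 ** (n_up - 1)
    layers = [
        nn.Linear(config.latent_dim, c0 * 4 * 4, rng=rng, w_std=0.02),
        nn.Reshape((c0, 4, 4)),
        nn.BatchNorm2d(c0),
        nn.ReLU(),
    ]
    size = 4
    ch = c0
    for i in range(n_up):
        out_ch = 1 if i == n_up - 1 else ch // 2
        ct = nn.ConvTranspose2d(ch, out_ch, 5, stride=2, pad=2, output_padding=1, rng=rng, w_std=0.02)
        assert ct.out_size(size) == 2 * size  # 4 -> 8 -> ... -> image_size
        layers.append(ct)
        size *= 2
        if i == n_up - 1:
            layers.append(nn.Tanh())
        else:
            layers.extend([nn.BatchNorm2d(out_ch), nn.ReLU()])
            ch = out_ch
    assert size == config.image_size
    return nn.Sequential(*layers)


def build_critic(config: WGANConfig, rng: np.random.Generator) -> nn.Sequential:
    n_down = config.n_layers
    layers = []
    size = config.image_size
    in_ch = 1
    ch = config.base_channels
    for _ in range(n_down):
        conv = nn.Conv2d(in_ch, ch, 5, stride=2, pad=2, rng=rng, w_std=0.02)
        assert conv.out_size(size) == size // 2  # image_size -> ... -> 4
        layers.append(conv)
        if config.batchnorm_critic:
            layers.append(nn.BatchNorm2d(ch))
        layers.append(nn.LeakyReLU(0.2))
        size //= 2
        in_ch, ch = ch, ch * 2
    assert size == 4
    layers.extend([nn.Flatten(), nn.Linear(in_ch * 4 * 4, 1, rng=rng, w_std=0.02)])
    return nn.Sequential(*layers)


def sample_latent(n: int, config: WGANConfig, seed) -> np.ndarray:
    """n latent vectors, entries i.i.d. uniform on [-1, 1]."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, (n, config.latent_dim)).astype(np.float32)


def generate_images(gen: nn.Sequential, latents: np.ndarray) -> np.ndarray:
    """Inference-mode generation: (n, latent_dim) -> (n, size, size) in [-1, 1]."""
    latents = np.asarray(latents, dtype=np.float32)
    in_features = gen.layers[0].params["w"].shape[1]
    if latents.ndim != 2 or latents.shape[1] != in_features:
        raise ValueError(f"latents must be (n, {in_features}), got {latents.shape}")
    gen.set_training(False)
    out = gen.forward(latents)
    return out[:, 0]


def _as_batch(images: np.ndarray, size: int) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    if images.shape[2:] != (size, size) or images.shape[1] != 1:
        raise ValueError(f"expected (n, {size}, {size}) images, got {images.shape}")
    return images


def critic_score(critic: nn.Sequential, images: np.ndarray, image_size: int | None = None) -> np.ndarray:
    """One unbounded real score per image (inference mode)."""
    if image_size is None:
        # infer from the first conv layer's expected input: images must be square
        image_size = int(np.asarray(images).shape[-1])
    x = _as_batch(images, image_size)
    critic.set_training(False)
    return critic.forward(x)[:, 0]


def wasserstein_estimate(critic: nn.Sequential, real: np.ndarray, fake: np.ndarray) -> float:
    """Critic-based distance estimate: mean score(real) - mean score(fake)."""
    return float(critic_score(critic, real).mean() - critic_score(critic, fake).mean())


def patches_to_wgan_images(patches, config: WGANConfig) -> np.ndarray:
    """HU-scale patches -> (n, size, size) arrays on [-1, 1] for training."""
    out = np.stack([resize_square(hu_to_unit(p.pixels), config.image_size) for p in patches])
    return np.clip(out, -1.0, 1.0).astype(np.float32)


def train_wgan(images: np.ndarray, config: WGANConfig, debug_check_clip: bool = False):
    """Train generator + critic on one class's images.

    ``images``: (n, size, size) floats on [-1, 1], all of one class.
    Returns (generator, critic, trace). Deterministic for a fixed config.seed.
    """
    images = _as_batch(images, config.image_size)
    n = images.shape[0]
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} images, got {n}")

    ss = np.random.SeedSequence(config.seed)
    s_gw, s_cw, s_lat, s_shuf = ss.spawn(4)
    gen = build_generator(config, np.random.default_rng(s_gw))
    critic = build_critic(config, np.random.default_rng(s_cw))
    lat_rng = np.random.default_rng(s_lat)
    shuf_rng = np.random.default_rng(s_shuf)
    opt_c = nn.RMSprop(critic, config.lr)
    opt_g = nn.RMSprop(gen, config.lr)
    trace = TrainTrace()

    steps_per_epoch = max(1, n // config.batch_size)
    bs = config.batch_size
    gen.set_training(True)
    critic.set_training(True)

    for epoch in range(config.epochs):
        for _ in range(steps_per_epoch):
            # --- n_critic critic updates ---
            w_est = 0.0
            for _ in range(config.n_critic):
                idx = shuf_rng.choice(n, bs, replace=False)
                real = images[idx]
                z = lat_rng.uniform(-1.0, 1.0, (bs, config.latent_dim)).astype(np.float32)
                fake = gen.forward(z)
                critic.zero_grad()
                s_real = critic.forward(real)
                # loss_c = -(mean s_real - mean s_fake); accumulate both passes
                critic.backward(np.full_like(s_real, -1.0 / bs))
                s_fake = critic.forward(fake)
                critic.backward(np.full_like(s_fake, 1.0 / bs))
                opt_c.step()
                critic.clip_params(config.clip_value)
                if debug_check_clip:
                    assert critic.max_abs_param() <= config.clip_value + 1e-12
                w_est = float(s_real.mean() - s_fake.mean())
            # --- one generator update ---
            z = lat_rng.uniform(-1.0, 1.0, (bs, config.latent_dim)).astype(np.float32)
            gen.zero_grad()
            critic.zero_grad()
            fake = gen.forward(z)
            s_fake = critic.forward(fake)
            gin = critic.backward(np.full_like(s_fake, -1.0 / bs))  # maximize critic score
            gen.backward(gin)
            opt_g.step()
            trace.critic_loss.append(-w_est)
            trace.gen_loss.append(float(-s_fake.mean()))
            trace.w_estimate.append(w_est)
            trace.epoch.append(epoch)
    return gen, critic, trace
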