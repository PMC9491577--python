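"""EEG-feature-conditioned image generation.

The generator seeds a stack of transposed convolutions with
z = eeg ⊙ (μ + σ ⊙ ε): a trainable weighted-Gaussian layer whose mean and
variance vectors mix standard-normal noise ε with the classifier's
2048-dim EEG feature vector.  z is reshaped to a 1×1 spatial map and
upsampled through five transposed-convolution blocks (512/256/128/64/3
filters, kernel 4, strides 1/2/2/2/2, valid then same padding) to a
64×64×3 image in [−1, 1].

The discriminator is a VGG-style stack of ten conv/batch-norm/LeakyReLU
blocks with max pooling after blocks 2, 4, 7 and 10, feeding two heads:
a real/fake probability and a 40-way class posterior.  The discriminator
loss is BCE(real→1) + BCE(fake→0) + CE(class | real); the generator loss
is BCE(fake→1) + CE(class | fake).  Training uses Adam (lr 1e-4, β₁ 0.5,
batch 16) on paired (EEG feature, image, label) data from the visual task.

Reduced-scale configurations (fewer blocks, smaller images) are provided
for smoke-scale training; the layer arithmetic is identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor, no_grad

__all__ = ["WeightedGaussianLayer", "GeneratorConfig", "Generator",
           "DiscriminatorConfig", "Discriminator", "gan_losses",
           "GanTrainConfig", "train_gan", "smoke_generator_config",
           "smoke_discriminator_config", "class_separability",
           "save_generator", "load_generator"]


class WeightedGaussianLayer(nn.Module):
    """z = eeg ⊙ (μ + σ ⊙ ε) with trainable mean and variance vectors.

    σ is stored unconstrained and used as-is; ε is standard normal noise
    drawn by the caller (redrawn per forward pass during training, fixed
    by seed for reproducible sampling).
    """

    def __init__(self, dim: int):
        super().__init__()
        self.dim = dim
        self.mu = nn.Parameter(np.ones(dim))
        self.sigma = nn.Parameter(np.full(dim, 0.1))

    def __call__(self, eeg, eps) -> Tensor:
        if not isinstance(eeg, Tensor):
            eeg = Tensor(np.asarray(eeg, dtype=np.float64))
        eps = np.asarray(eps, dtype=np.float64)
        if eeg.shape[-1] != self.dim or eps.shape[-1] != self.dim:
            raise ValueError(f"expected feature dim {self.dim}, got "
                             f"eeg {eeg.shape[-1]}, eps {eps.shape[-1]}")
        return eeg * (self.mu + self.sigma * eps)


@dataclass
class GeneratorConfig:
    feature_dim: int = 2048
    # (filters, kernel, stride, padding) per transposed-convolution block
    blocks: tuple = ((512, 4, 1, "valid"), (256, 4, 2, "same"),
                     (128, 4, 2, "same"), (64, 4, 2, "same"),
                     (3, 4, 2, "same"))
    leaky_slope: float = 0.2
    seed: int = 0

    @property
    def image_size(self) -> int:
        size = 1
        for _f, k, s, pad in self.blocks:
            size = size * s + (k - s if pad == "valid" else 0)
        return size


def smoke_generator_config(feature_dim: int = 64,
                           seed: int = 0) -> GeneratorConfig:
    """Three-block stack producing 16×16 images — same arithmetic, desk scale."""
    return GeneratorConfig(
        feature_dim=feature_dim,
        blocks=((64, 4, 1, "valid"), (32, 4, 2, "same"), (3, 4, 2, "same")),
        seed=seed)


class Generator(nn.Module):
    def __init__(self, config: GeneratorConfig = GeneratorConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng([config.seed % (2**31), 211])
        self.gaussian = WeightedGaussianLayer(config.feature_dim)
        self.weights: list[nn.Parameter] = []
        self.norms: list[nn.BatchNorm] = []
        c_in = config.feature_dim
        for i, (f, k, _s, _pad) in enumerate(config.blocks):
            w = nn.Parameter(rng.normal(0.0, 0.02, size=(c_in, f, k, k)))
            self.weights.append(w)
            if i < len(config.blocks) - 1:
                self.norms.append(nn.BatchNorm(f, axes=(0, 2, 3)))
            c_in = f

    def forward_z(self, z: Tensor) -> Tensor:
        cfg = self.config
        h = z.reshape(z.shape[0], cfg.feature_dim, 1, 1)
        last = len(cfg.blocks) - 1
        for i, (_f, _k, s, pad) in enumerate(cfg.blocks):
            h = nn.conv_transpose2d(h, self.weights[i], s, pad)
            if i < last:
                h = self.norms[i](h)
                h = h.leaky_relu(cfg.leaky_slope)
            else:
                h = h.tanh()
        return h

    def __call__(self, eeg_features, eps) -> Tensor:
        z = self.gaussian(eeg_features, eps)
        return self.forward_z(z)


def generate(generator: Generator, eeg_features: np.ndarray,
             noise_seed: int = 0) -> np.ndarray:
    """Sample images (batch × C × H × W in [−1, 1]) with seeded noise."""
    eeg_features = np.asarray(eeg_features, dtype=np.float64)
    if not np.all(np.isfinite(eeg_features)):
        raise ValueError("non-finite EEG features")
    rng = np.random.default_rng([noise_seed % (2**31), 977])
    eps = rng.standard_normal(eeg_features.shape)
    generator.eval()
    with no_grad():
        return generator(eeg_features, eps).data


@dataclass
class DiscriminatorConfig:
    n_classes: int = 40
    image_size: int = 64
    in_channels: int = 3
    filters: tuple = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512)
    kernel: int = 3
    pool_after: frozenset = frozenset({2, 4, 7, 10})  # 1-based block index
    real_hidden: int = 1024
    class_hidden: tuple = (1024, 1024)
    dropout: float = 0.3
    leaky_slope: float = 0.2
    seed: int = 0

    @property
    def final_size(self) -> int:
        size = self.image_size
        for _ in self.pool_after:
            size //= 2
        return size

    @property
    def flat_width(self) -> int:
        return self.filters[-1] * self.final_size ** 2


def smoke_discriminator_config(n_classes: int = 8, image_size: int = 16,
                               seed: int = 0) -> DiscriminatorConfig:
    return DiscriminatorConfig(
        n_classes=n_classes, image_size=image_size,
        filters=(16, 32), pool_after=frozenset({1, 2}),
        real_hidden=64, class_hidden=(64,), seed=seed)


class Discriminator(nn.Module):
    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng([config.seed % (2**31), 307])
        self.convs: list[nn.Parameter] = []
        self.norms: list[nn.BatchNorm] = []
        c_in = config.in_channels
        k = config.kernel
        for f in config.filters:
            self.convs.append(nn.Parameter(
                rng.normal(0.0, np.sqrt(2.0 / (c_in * k * k)),
                           size=(f, c_in, k, k))))
            self.norms.append(nn.BatchNorm(f, axes=(0, 2, 3)))
            c_in = f
        self.drop = nn.Dropout(config.dropout, rng)
        self.real_fc1 = nn.Dense(config.flat_width, config.real_hidden, rng)
        self.real_fc2 = nn.Dense(config.real_hidden, 1, rng)
        dims = (config.flat_width,) + tuple(config.class_hidden)
        self.class_fcs = [nn.Dense(a, b, rng)
                          for a, b in zip(dims[:-1], dims[1:])]
        self.class_out = nn.Dense(dims[-1], config.n_classes, rng)

    def __call__(self, images) -> tuple[Tensor, Tensor]:
        """Returns (real/fake probability, class logits)."""
        cfg = self.config
        if not isinstance(images, Tensor):
            images = Tensor(np.asarray(images, dtype=np.float64))
        expected = (cfg.in_channels, cfg.image_size, cfg.image_size)
        if images.shape[1:] != expected:
            raise ValueError(f"expected images (batch, {expected[0]}, "
                             f"{expected[1]}, {expected[2]}), "
                             f"got {images.shape}")
        h = images
        for i, (w, bn) in enumerate(zip(self.convs, self.norms), start=1):
            h = nn.conv2d(h, w)
            h = bn(h)
            h = h.leaky_relu(cfg.leaky_slope)
            if i in cfg.pool_after:
                h = nn.max_pool2d(h, 2)
                h = self.drop(h)
        h = h.reshape(h.shape[0], cfg.flat_width)
        real = self.real_fc2(self.drop(self.real_fc1(h).relu())).sigmoid()
        c = h
        for fc in self.class_fcs:
            c = self.drop(fc(c).relu())
        class_logits = self.class_out(c)
        return real, class_logits


def discriminate(disc: Discriminator,
                 images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eval-mode (real probability, class probabilities) as plain arrays."""
    disc.eval()
    with no_grad():
        real, logits = disc(images)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return real.data, e / e.sum(axis=-1, keepdims=True)


def gan_losses(real_prob_real: Tensor, real_prob_fake: Tensor,
               class_logits_real: Tensor, class_logits_fake: Tensor,
               labels: np.ndarray) -> tuple[Tensor, Tensor]:
    """(discriminator loss, generator loss).

    d = BCE(real→1) + BCE(fake→0) + CE(class | real);
    g = BCE(fake→1) + CE(class | fake).
    """
    d_loss = (nn.binary_cross_entropy(real_prob_real, 1.0)
              + nn.binary_cross_entropy(real_prob_fake, 0.0)
              + nn.cross_entropy(class_logits_real, labels))
    g_loss = (nn.binary_cross_entropy(real_prob_fake, 1.0)
              + nn.cross_entropy(class_logits_fake, labels))
    return d_loss, g_loss


def save_generator(generator: Generator, path) -> None:
    """Generator parameters in NPZ with a JSON config sidecar."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    params, bufs = generator.clone_state()
    arrays = {f"p{i}": a for i, a in enumerate(params)}
    for i, (rm, rv) in enumerate(bufs):
        arrays[f"bm{i}"] = rm
        arrays[f"bv{i}"] = rv
    np.savez(path, **arrays)
    cfg = asdict(generator.config)
    cfg["blocks"] = [list(b) for b in generator.config.blocks]
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_generator(path) -> Generator:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["blocks"] = tuple(tuple(b) for b in cfg["blocks"])
    gen = Generator(GeneratorConfig(**cfg))
    with np.load(path) as z:
        n = len([k for k in z.files if k.startswith("p")])
        params = [z[f"p{i}"] for i in range(n)]
        n_bn = len([k for k in z.files if k.startswith("bm")])
        bufs = [(z[f"bm{i}"], z[f"bv{i}"]) for i in range(n_bn)]
    gen.load_clone((params, bufs))
    return gen


@dataclass
class GanTrainConfig:
    lr: float = 1e-4
    beta1: float = 0.5
    batch_size: int = 16
    steps: int = 200
    seed: int = 0


def train_gan(generator: Generator, discriminator: Discriminator,
              features: np.ndarray, images: np.ndarray,
              labels: np.ndarray,
              config: GanTrainConfig = GanTrainConfig()) -> pd.DataFrame:
    """Alternating adversarial + classification training on paired data.

    ``features``/``images``/``labels`` must be index-aligned (one EEG
    feature vector and one target image per trial).  Returns the per-step
    loss history.
    """
    n = len(features)
    if not (len(images) == n == len(labels)):
        raise ValueError(f"unpaired data: {n} features, {len(images)} "
                         f"images, {len(labels)} labels")
    rng = np.random.default_rng([config.seed % (2**31), 389])
    opt_d = nn.Adam(discriminator.parameters(), lr=config.lr,
                    beta1=config.beta1)
    opt_g = nn.Adam(generator.parameters(), lr=config.lr, beta1=config.beta1)
    dim = generator.config.feature_dim
    history = []
    for step in range(config.steps):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        f_batch = features[idx]
        y_batch = labels[idx]
        x_real = images[idx]

        # discriminator update (generator output detached)
        generator.train()
        discriminator.train()
        eps = rng.standard_normal((len(idx), dim))
        with no_grad():
            fake = generator(f_batch, eps).data
        rp_real, cl_real = discriminator(x_real)
        rp_fake, _cl_fake = discriminator(fake)
        d_loss, _ = gan_losses(rp_real, rp_fake, cl_real, _cl_fake, y_batch)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        # generator update (through the discriminator)
        eps = rng.standard_normal((len(idx), dim))
        fake = generator(f_batch, eps)
        rp_fake2, cl_fake2 = discriminator(fake)
        g_loss = (nn.binary_cross_entropy(rp_fake2, 1.0)
                  + nn.cross_entropy(cl_fake2, y_batch))
        opt_g.zero_grad()
        opt_d.zero_grad()
        g_loss.backward()
        opt_g.step()

        history.append({"step": step, "d_loss": d_loss.item(),
                        "g_loss": g_loss.item()})
    return pd.DataFrame(history)


def class_separability(generator: Generator, features_by_class: np.ndarray,
                       n_resamples: int = 4, seed: int = 0) -> float:
    """Between-class vs within-class pixel variance of generated images.

    For each class feature vector, sample ``n_resamples`` images with
    fresh noise; return the ratio of the variance of class-mean images to
    the mean within-class variance.  Values above 1 indicate the
    conditioning pathway dominates the noise.
    """
    n_classes, dim = features_by_class.shape
    rng = np.random.default_rng([seed % (2**31), 401])
    generator.eval()
    samples = []
    with no_grad():
        for _ in range(n_resamples):
            eps = rng.standard_normal((n_classes, dim))
            samples.append(generator(features_by_class, eps).data)
    stack = np.stack(samples)          # (R, n_classes, C, H, W)
    class_means = stack.mean(axis=0)
    between = class_means.var(axis=0).mean()
    within = stack.var(axis=0).mean()
    if within == 0:
        return np.inf
    return float(between / within)
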