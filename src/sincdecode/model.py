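"""The sinc filter-bank EEG classifier with channel attention.

Architecture (for the default 128-channel, 125-sample input):

====================  =========================================
Layer                 Parameters
====================  =========================================
Sinc convolution      16 band-pass filters, 65 taps, f1 ≥ 1 Hz,
                      bandwidth ≥ 4 Hz (two scalars per filter)
Batch norm            per filter
Depthwise spatial     kernel (128, 1), depth multiplier 2 → 32 maps
Batch norm + SE gate  squeeze-and-excitation, reduction r=8
ELU / avg-pool 4      125 → 31 samples
Dropout 0.5
Separable conv        depthwise (1, 8) + pointwise → 32 maps
Batch norm / ELU
Avg-pool 3            31 → 10 samples
Dropout 0.5
Flatten               32 × 10 = 320
Dense 512 (relu)      dropout 0.5
Dense 2048 (relu)     dropout 0.5; this is the EEG feature layer
Dense 40 (softmax)
====================  =========================================

The sinc layer learns only each filter's low cutoff and bandwidth; the
kernel is the difference of two Hamming-windowed sinc low-passes,
unit-energy normalized, so its passband is readable directly from the two
scalars.  The squeeze-and-excitation gate produces one weight per feature
map from pooled summaries through a shared bottleneck MLP; the gate values
are the attention map the interpretation module consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad

__all__ = ["ModelConfig", "SincFilterBank", "SEAttention", "SincEEGNet",
           "ModelOutputs", "extract_attention", "predict_proba",
           "save_checkpoint", "load_checkpoint", "summary"]


@dataclass
class ModelConfig:
    n_channels: int = 128
    n_samples: int = 125
    n_classes: int = 40
    rate_hz: float = 250.0
    n_filters: int = 16
    kernel_len: int = 65
    freq_min: float = 1.0
    band_min: float = 4.0
    multiplier: int = 2
    se_reduction: int = 8
    pool1: int = 4
    pool2: int = 3
    sep_kernel: int = 8
    sep_filters: int | None = None     # default: n_filters * multiplier
    dense1: int = 512
    dense2: int = 2048
    dropout: float = 0.5
    init_low_max_hz: float = 40.0
    seed: int = 0

    @property
    def n_maps(self) -> int:
        return self.n_filters * self.multiplier

    @property
    def n_sep(self) -> int:
        return self.sep_filters or self.n_maps

    @property
    def flat_width(self) -> int:
        t1 = self.n_samples // self.pool1
        t2 = t1 // self.pool2
        return self.n_sep * t2


@dataclass
class ModelOutputs:
    """Forward-pass results: class logits, EEG features, attention gates."""

    logits: Tensor
    features: Tensor
    attention: np.ndarray

    @property
    def probs(self) -> np.ndarray:
        z = self.logits.data - self.logits.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


class SincFilterBank(nn.Module):
    """Learnable band-pass filter bank parameterized by (low cutoff, width).

    Effective cutoffs: f1 = freq_min + |raw_low|, f2 = f1 + band_min +
    |raw_band|, with f2 softly clipped below the Nyquist frequency.  The
    absolute-value-plus-floor construction keeps the constraints satisfied
    for any raw parameter value while remaining differentiable.
    """

    def __init__(self, n_filters: int = 16, kernel_len: int = 65,
                 rate_hz: float = 250.0, freq_min: float = 1.0,
                 band_min: float = 4.0, init_low_max_hz: float = 40.0):
        super().__init__()
        if kernel_len % 2 == 0:
            raise ValueError("kernel_len must be odd")
        self.n_filters = n_filters
        self.kernel_len = kernel_len
        self.rate_hz = rate_hz
        self.freq_min = freq_min
        self.band_min = band_min
        init_f1 = np.linspace(freq_min, min(init_low_max_hz,
                                            0.8 * rate_hz / 2), n_filters)
        self.raw_low = nn.Parameter(init_f1 - freq_min)
        self.raw_band = nn.Parameter(np.linspace(0.0, 2.0, n_filters))

    def _cutoff_tensors(self) -> tuple[Tensor, Tensor]:
        nyq = 0.99 * self.rate_hz / 2.0
        f1 = self.raw_low.abs() + self.freq_min
        band = self.raw_band.abs() + self.band_min
        hi = f1 + band
        # soft clip below Nyquist: min(hi, nyq) = hi - relu(hi - nyq)
        f2 = hi - (hi - nyq).relu()
        if np.any(f1.data >= nyq):
            raise ValueError("low cutoff reached the Nyquist frequency")
        return f1, f2

    def cutoffs(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective (f1, f2) in Hz as plain arrays."""
        f1, f2 = self._cutoff_tensors()
        return f1.data.copy(), f2.data.copy()

    def kernels(self) -> Tensor:
        """Differentiable (n_filters × kernel_len) band-pass kernels.

        g[n] = (2·f2·sinc(2·f2·t_n) − 2·f1·sinc(2·f1·t_n)) · hamming(n),
        t_n centered on the window, unit-energy normalized per filter.
        """
        K = self.kernel_len
        t = (np.arange(K) - (K - 1) / 2.0) / self.rate_hz
        center = t == 0.0
        t_safe = np.where(center, 1.0, t)
        f1, f2 = self._cutoff_tensors()
        f1c = f1.reshape(-1, 1)
        f2c = f2.reshape(-1, 1)

        def lowpass(f: Tensor) -> Tensor:
            # 2f·sinc(2ft) = sin(2πft)/(πt); the center tap equals 2f
            wave = (f * (2.0 * np.pi * t)).sin() * (1.0 / (np.pi * t_safe))
            return wave * (~center) + (2.0 * f) * center

        g = lowpass(f2c) - lowpass(f1c)
        g = g * np.hamming(K)
        energy = (g * g).sum(axis=1, keepdims=True)
        return g * (energy ** -0.5)


class SEAttention(nn.Module):
    """Squeeze-and-excitation gate over feature maps with avg+max squeeze.

    a = sigmoid(MLP(avgpool(x)) + MLP(maxpool(x))) with one shared hidden
    layer of width n_maps / reduction; output = x + x ⊙ a.
    """

    def __init__(self, n_maps: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        if n_maps % reduction != 0:
            raise ValueError(f"reduction {reduction} does not divide "
                             f"{n_maps} maps")
        hidden = n_maps // reduction
        self.fc1 = nn.Dense(n_maps, hidden, rng)
        self.fc2 = nn.Dense(hidden, n_maps, rng)

    def _shared(self, s: Tensor) -> Tensor:
        return self.fc2(self.fc1(s).relu())

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        s_avg = x.mean(axis=2)
        s_max = x.max(axis=2)
        a = (self._shared(s_avg) + self._shared(s_max)).sigmoid()
        out = x + x * a.reshape(a.shape[0], a.shape[1], 1)
        return out, a


class SincEEGNet(nn.Module):
    """The full classifier; see the module docstring for the layer table."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng([config.seed % (2**31), 101])
        self.sinc = SincFilterBank(config.n_filters, config.kernel_len,
                                   config.rate_hz, config.freq_min,
                                   config.band_min, config.init_low_max_hz)
        self.bn1 = nn.BatchNorm(config.n_filters, axes=(0, 2, 3))
        self.spatial = nn.Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(config.n_channels),
                       size=(config.n_filters, config.multiplier,
                             config.n_channels)))
        self.bn2 = nn.BatchNorm(config.n_maps, axes=(0, 2))
        self.attention = SEAttention(config.n_maps, config.se_reduction, rng)
        self.drop1 = nn.Dropout(config.dropout, rng)
        self.sep_depth = nn.Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(config.sep_kernel),
                       size=(config.n_maps, config.sep_kernel)))
        self.sep_point = nn.Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(config.n_maps),
                       size=(config.n_maps, config.n_sep)))
        self.bn3 = nn.BatchNorm(config.n_sep, axes=(0, 2))
        self.drop2 = nn.Dropout(config.dropout, rng)
        self.fc1 = nn.Dense(config.flat_width, config.dense1, rng)
        self.drop3 = nn.Dropout(config.dropout, rng)
        self.fc2 = nn.Dense(config.dense1, config.dense2, rng)
        self.drop4 = nn.Dropout(config.dropout, rng)
        self.head = nn.Dense(config.dense2, config.n_classes, rng)

    def __call__(self, x) -> ModelOutputs:
        cfg = self.config
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.shape[1:] != (cfg.n_channels, cfg.n_samples):
            raise ValueError(
                f"expected input (batch, {cfg.n_channels}, {cfg.n_samples}),"
                f" got {x.shape}")
        h = nn.conv1d_bank(x, self.sinc.kernels())
        h = self.bn1(h)
        h = nn.spatial_collapse(h, self.spatial)
        h = self.bn2(h)
        h, attn = self.attention(h)
        h = h.elu()
        h = nn.avg_pool_time(h, cfg.pool1)
        h = self.drop1(h)
        h = nn.depthwise_time_conv(h, self.sep_depth)
        h = h.transpose(0, 2, 1) @ self.sep_point
        h = h.transpose(0, 2, 1)
        h = self.bn3(h)
        h = h.elu()
        h = nn.avg_pool_time(h, cfg.pool2)
        h = self.drop2(h)
        B = h.shape[0]
        h = h.reshape(B, cfg.flat_width)
        h = self.drop3(self.fc1(h).relu())
        features = self.fc2(h).relu()
        logits = self.head(self.drop4(features))
        return ModelOutputs(logits=logits, features=features,
                            attention=attn.data.copy())


def _batched(model: SincEEGNet, epochs: np.ndarray, batch_size: int):
    model.eval()
    with no_grad():
        for i in range(0, len(epochs), batch_size):
            yield model(epochs[i:i + batch_size])


def extract_attention(model: SincEEGNet, epochs: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
    """Per-trial attention gate values (n_trials × n_maps), eval mode."""
    return np.concatenate([o.attention
                           for o in _batched(model, epochs, batch_size)])


def predict_proba(model: SincEEGNet, epochs: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    return np.concatenate([o.probs
                           for o in _batched(model, epochs, batch_size)])


def save_checkpoint(model: SincEEGNet, path: str | Path) -> None:
    """Parameters + batch-norm statistics in NPZ, config in a JSON sidecar."""
    path = Path(path)
    params, bufs = model.clone_state()
    arrays = {f"p{i}": a for i, a in enumerate(params)}
    for i, (rm, rv) in enumerate(bufs):
        arrays[f"bm{i}"] = rm
        arrays[f"bv{i}"] = rv
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_checkpoint(path: str | Path) -> SincEEGNet:
    path = Path(path)
    cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = SincEEGNet(cfg)
    with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
        n_params = len([k for k in z.files if k.startswith("p")])
        params = [z[f"p{i}"] for i in range(n_params)]
        n_bn = len([k for k in z.files if k.startswith("bm")])
        bufs = [(z[f"bm{i}"], z[f"bv{i}"]) for i in range(n_bn)]
    model.load_clone((params, bufs))
    return model


def summary(config: ModelConfig = ModelConfig()) -> str:
    """Human-readable layer table with shapes and parameter counts."""
    cfg = config
    t1 = cfg.n_samples // cfg.pool1
    t2 = t1 // cfg.pool2
    rows = [
        ("Input", f"({cfg.n_channels}, {cfg.n_samples})", 0),
        ("Sinc convolution",
         f"filters={cfg.n_filters}, kernel={cfg.kernel_len}, "
         f"f_min={cfg.freq_min}, b_min={cfg.band_min}", 2 * cfg.n_filters),
        ("BatchNorm", f"({cfg.n_filters} maps)", 2 * cfg.n_filters),
        ("Depthwise spatial conv",
         f"kernel=({cfg.n_channels}, 1), multiplier={cfg.multiplier}",
         cfg.n_filters * cfg.multiplier * cfg.n_channels),
        ("BatchNorm + SE attention",
         f"r={cfg.se_reduction}, hidden={cfg.n_maps // cfg.se_reduction}",
         2 * cfg.n_maps + 2 * (cfg.n_maps * (cfg.n_maps // cfg.se_reduction))
         + cfg.n_maps // cfg.se_reduction + cfg.n_maps),
        ("ELU + AvgPool", f"{cfg.pool1} → (…, {t1})", 0),
        (f"Dropout {cfg.dropout}", "", 0),
        ("Separable conv",
         f"depthwise kernel={cfg.sep_kernel}, filters={cfg.n_sep}",
         cfg.n_maps * cfg.sep_kernel + cfg.n_maps * cfg.n_sep),
        ("BatchNorm + ELU + AvgPool", f"{cfg.pool2} → (…, {t2})",
         2 * cfg.n_sep),
        ("Flatten", f"{cfg.flat_width}", 0),
        (f"Dense {cfg.dense1} (relu)", "",
         cfg.flat_width * cfg.dense1 + cfg.dense1),
        (f"Dense {cfg.dense2} (relu)", "EEG feature layer",
         cfg.dense1 * cfg.dense2 + cfg.dense2),
        (f"Dense {cfg.n_classes} (softmax)", "",
         cfg.dense2 * cfg.n_classes + cfg.n_classes),
    ]
    width = max(len(r[0]) for r in rows)
    lines = [f"{'Layer':<{width}}  {'Params':>10}  Detail",
             "-" * (width + 40)]
    for name, detail, n in rows:
        lines.append(f"{name:<{width}}  {n:>10}  {detail}")
    total = sum(r[2] for r in rows)
    lines.append(f"{'Total':<{width}}  {total:>10}")
    return "\n".join(lines)
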