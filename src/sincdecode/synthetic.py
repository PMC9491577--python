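"""Synthetic EEG sessions with class-specific spatio-spectral structure.

The generator emulates the layout of a two-task visual-imagery experiment:
a *visual* session shows blocks of rapid 500 ms stimuli (one class per
block), an *imagination* session gives one cue per class followed by a
10 s imagination period.  Each class carries a band-limited oscillation
(amplitude-modulated sinusoid, random phase and carrier per trial)
projected onto a class-specific scalp topography, on top of pink (1/f)
background noise and sporadic frontal EOG-like transients.

A configurable fraction of each class signature is *shared* between the
two tasks; the remainder is task-specific.  This single knob controls
whether a classifier trained on the visual task can transfer to the
imagination task, which is the phenomenon the training module's mixed-task
regime exploits.

All randomness derives from ``SyntheticConfig.seed`` plus the subject and
task, so identical calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (IMAGINATION, IMAGINE_ONSET, VISUAL, VISUAL_ONSET, Event,
                   RawRecording, default_channel_labels)

__all__ = ["SyntheticConfig", "generate_session", "FeatureProvider",
           "make_feature_provider", "make_image_dataset", "image_manifest"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the full study layout: 4 subjects, 40 classes, 50
    visual stimuli per class at 500 ms each, one 10 s imagination block
    per class, 128 channels at 2 kHz.  ``shared_fraction`` is the fraction
    of each class signature's *power* that is common to both tasks.
    ``imagine_snr_db`` defaults 8 dB below the visual SNR: imagining an
    image evokes a far weaker, more variable signature than seeing it,
    which is what makes the imagination task the hard one.
    """

    n_subjects: int = 4
    n_classes: int = 40
    visual_trials_per_class: int = 50
    visual_trial_ms: float = 500.0
    imagine_block_s: float = 10.0
    native_rate_hz: float = 2000.0
    n_channels: int = 128
    class_bands: list[tuple[float, float]] | None = None
    class_topographies: np.ndarray | None = None
    shared_fraction: float = 1.0
    snr_db: float = -6.0
    imagine_snr_db: float | None = None
    eog_rate: float = 4.0          # artifacts per minute
    eog_amplitude_uv: float = 120.0
    signal_amplitude_uv: float = 8.0
    topo_jitter: float = 0.1       # per-subject topography perturbation
    inter_block_gap_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "visual_trials_per_class",
                     "n_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.eog_rate < 0:
            raise ValueError("eog_rate must be nonnegative")
        nyq = self.native_rate_hz / 2.0
        if self.class_bands is not None:
            if len(self.class_bands) != self.n_classes:
                raise ValueError("need one band per class")
            for lo, hi in self.class_bands:
                if not 0.0 < lo < hi < nyq:
                    raise ValueError(f"band ({lo}, {hi}) outside (0, {nyq})")
        if self.class_topographies is not None:
            topo = np.asarray(self.class_topographies, dtype=np.float64)
            if topo.shape != (self.n_classes, self.n_channels):
                raise ValueError("class_topographies must be "
                                 "(n_classes, n_channels)")
            if np.any(np.linalg.norm(topo, axis=1) == 0):
                raise ValueError("degenerate all-zero topography")
            self.class_topographies = topo

    @property
    def imagine_snr(self) -> float:
        return (self.snr_db - 8.0 if self.imagine_snr_db is None
                else self.imagine_snr_db)

    def bands(self) -> list[tuple[float, float]]:
        """Per-class passbands; default centers spread over 5–41 Hz."""
        if self.class_bands is not None:
            return list(self.class_bands)
        centers = np.linspace(6.0, 41.0, self.n_classes)
        return [(float(c - 2.0), float(c + 2.0)) for c in centers]

    def _topo(self, rng: np.random.Generator) -> np.ndarray:
        """One focal topography: Gaussian bump over channel index + texture."""
        n = self.n_channels
        focus = rng.integers(0, n)
        width = max(2.0, n / 12.0)
        idx = np.arange(n)
        w = np.exp(-0.5 * ((idx - focus) / width) ** 2)
        w += 0.25 * rng.normal(size=n)
        norm = np.linalg.norm(w)
        return w / norm

    def topographies(self, subject_id: int, stream: str) -> np.ndarray:
        """Per-class topographies for a subject.

        ``stream`` selects the shared generator (identical across tasks)
        or a task-specific one.  Explicit ``class_topographies`` override
        the shared stream; per-subject jitter is applied on top.
        """
        topos = np.empty((self.n_classes, self.n_channels))
        for c in range(self.n_classes):
            if stream == "shared" and self.class_topographies is not None:
                w = np.array(self.class_topographies[c], dtype=np.float64)
                w = w / np.linalg.norm(w)
            else:
                rng = np.random.default_rng(
                    [self.seed % (2**31), c, _stream_code(stream)])
                w = self._topo(rng)
            if self.topo_jitter > 0:
                jrng = np.random.default_rng(
                    [self.seed % (2**31), subject_id, c, 977])
                w = w + self.topo_jitter * jrng.normal(size=self.n_channels)
                w = w / np.linalg.norm(w)
            topos[c] = w
        return topos

    def stream_bands(self, stream: str) -> list[tuple[float, float]]:
        if stream == "shared":
            return self.bands()
        # task-specific signatures live in shuffled bands so that with
        # shared_fraction = 0 the two tasks carry unrelated class codes
        rng = np.random.default_rng([self.seed % (2**31),
                                     _stream_code(stream), 31])
        bands = self.bands()
        perm = rng.permutation(len(bands))
        return [bands[i] for i in perm]


def _stream_code(stream: str) -> int:
    return {"shared": 1, VISUAL: 2, IMAGINATION: 3}[stream]


def _pink_noise(rng: np.random.Generator, n_channels: int,
                n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise, shaped in the frequency domain."""
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for ch in range(n_channels):
        shaped = (rng.normal(size=freqs.size)
                  + 1j * rng.normal(size=freqs.size)) * scale
        x = np.fft.irfft(shaped, n=n_samples)
        out[ch] = (x / x.std()).astype(np.float32)
    return out


def _oscillation(rng: np.random.Generator, band: tuple[float, float],
                 n: int, rate: float) -> np.ndarray:
    """Hann-enveloped sinusoid with random carrier inside ``band``."""
    f = rng.uniform(*band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / rate
    env = np.hanning(n)
    return env * np.sin(2.0 * np.pi * f * t + phase)


def _eog_weights(n_channels: int) -> np.ndarray:
    """Frontal loading: 1 on Fp1/Fp2, exponential decay toward the back."""
    w = np.exp(-np.arange(n_channels) / 8.0)
    w[0] = w[1] = 1.0
    return w


def generate_session(config: SyntheticConfig, subject_id: int,
                     task: str) -> RawRecording:
    """Simulate one subject's recording for one task.

    Visual sessions contain ``n_classes`` blocks of
    ``visual_trials_per_class`` 500 ms stimulus events; imagination
    sessions contain one ``imagine_onset`` event per class followed by
    ``imagine_block_s`` seconds of signal.
    """
    if task not in (VISUAL, IMAGINATION):
        raise ValueError(f"unknown task {task!r}")
    rate = config.native_rate_hz
    gap = int(round(config.inter_block_gap_s * rate))
    rng = np.random.default_rng(
        [config.seed % (2**31), subject_id, _stream_code(task), 7919])

    sf = config.shared_fraction
    a_shared = np.sqrt(sf)
    a_task = np.sqrt(1.0 - sf)
    topo_shared = config.topographies(subject_id, "shared")
    topo_task = config.topographies(subject_id, task)
    bands_shared = config.stream_bands("shared")
    bands_task = config.stream_bands(task)

    if task == VISUAL:
        trial_len = int(round(config.visual_trial_ms / 1000.0 * rate))
        trials_per_block = config.visual_trials_per_class
        event_kind = VISUAL_ONSET
    else:
        trial_len = int(round(config.imagine_block_s * rate))
        trials_per_block = 1
        event_kind = IMAGINE_ONSET

    block_len = gap + trials_per_block * trial_len
    n_samples = config.n_classes * block_len + gap
    signal = np.zeros((config.n_channels, n_samples), dtype=np.float32)
    events: list[Event] = []

    block_classes = rng.permutation(config.n_classes)
    amp = config.signal_amplitude_uv
    for b, cls in enumerate(block_classes):
        block_start = b * block_len + gap
        for tix in range(trials_per_block):
            start = block_start + tix * trial_len
            osc_s = _oscillation(rng, bands_shared[cls], trial_len, rate)
            comp = a_shared * np.outer(topo_shared[cls], osc_s)
            if a_task > 0:
                osc_t = _oscillation(rng, bands_task[cls], trial_len, rate)
                comp = comp + a_task * np.outer(topo_task[cls], osc_t)
            signal[:, start:start + trial_len] += (amp * comp).astype(
                np.float32)
            events.append(Event(start, int(cls), event_kind))

    # background noise scaled to the requested SNR over signal spans
    snr_db = config.snr_db if task == VISUAL else config.imagine_snr
    active = np.zeros(n_samples, dtype=bool)
    for e in events:
        active[e.sample:e.sample + trial_len] = True
    p_sig = float(np.mean(signal[:, active].astype(np.float64) ** 2))
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)) if p_sig > 0 else 1.0
    noise = _pink_noise(rng, config.n_channels, n_samples)
    data = signal + (sigma * noise).astype(np.float32)

    # ocular transients: half-cosine pulses loaded on the frontal channels
    if config.eog_rate > 0:
        n_pulses = rng.poisson(config.eog_rate * n_samples / rate / 60.0)
        pulse_len = int(round(0.3 * rate))
        pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi *
                                    np.arange(pulse_len) / pulse_len))
        w = _eog_weights(config.n_channels)
        for _ in range(n_pulses):
            start = rng.integers(0, max(1, n_samples - pulse_len))
            a = config.eog_amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, start:start + pulse_len] += (
                a * np.outer(w, pulse)).astype(np.float32)

    events.sort(key=lambda e: e.sample)
    return RawRecording(
        data=data, rate_hz=rate,
        channel_labels=default_channel_labels(config.n_channels),
        events=events, subject_id=subject_id, task=task)


# ---------------------------------------------------------------------------
# class feature vectors (image-embedding stand-in) and synthetic images
# ---------------------------------------------------------------------------


@dataclass
class FeatureProvider:
    """Deterministic map class label → unit-norm target feature vector.

    Stands in for an image-embedding network's penultimate layer: the
    training module's feature-matching loss pulls EEG features toward
    these targets, and the generator conditions on them.
    """

    vectors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)

    @property
    def n_classes(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __getitem__(self, label: int) -> np.ndarray:
        return self.vectors[label]

    def __call__(self, labels: np.ndarray) -> np.ndarray:
        return self.vectors[np.asarray(labels)]


def make_feature_provider(n_classes: int, dim: int = 2048,
                          seed: int = 0) -> FeatureProvider:
    if dim <= 0:
        raise ValueError("dim must be positive")
    rng = np.random.default_rng([seed % (2**31), 40427])
    v = rng.normal(size=(n_classes, dim))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return FeatureProvider(v)


def image_manifest(config: SyntheticConfig) -> pd.DataFrame:
    """The stimulus manifest: one row per (class, exemplar) image."""
    rows = [(c * config.visual_trials_per_class + i, c, i)
            for c in range(config.n_classes)
            for i in range(config.visual_trials_per_class)]
    return pd.DataFrame(rows, columns=["image_id", "class", "exemplar"])


def make_image_dataset(n_classes: int, images_per_class: int,
                       size: int = 64, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic class-coded images in [-1, 1], shape (N, 3, size, size).

    Each class is a colored Gabor-like texture (class-specific orientation,
    spatial frequency and color); exemplars vary by phase jitter and noise.
    Returns (images, labels).
    """
    rng = np.random.default_rng([seed % (2**31), 515])
    yy, xx = np.mgrid[0:size, 0:size] / size - 0.5
    images = np.empty((n_classes * images_per_class, 3, size, size),
                      dtype=np.float32)
    labels = np.repeat(np.arange(n_classes), images_per_class)
    for c in range(n_classes):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(3.0, 9.0)
        color = rng.uniform(-1.0, 1.0, size=3)
        base_phase = rng.uniform(0, 2 * np.pi)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        for i in range(images_per_class):
            phase = base_phase + rng.uniform(-0.3, 0.3)
            pattern = np.sin(2 * np.pi * freq * u + phase)
            pattern *= np.exp(-((xx ** 2 + yy ** 2) / 0.18))
            img = color[:, None, None] * pattern[None]
            img = img + 0.15 * rng.normal(size=img.shape)
            images[c * images_per_class + i] = np.tanh(img)
    return images, labels
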