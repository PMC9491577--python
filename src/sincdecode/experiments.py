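"""Reduced-scale reference experiments.

These functions bundle the package's standard desk-scale studies: the
mixed-task transfer experiment (does pooling perception trials with
imagination trials improve imagination decoding?), the spatio-spectral
parameter-recovery experiment (does the attention-based interpretation
recover a planted band and channel set?), and the conditioned-generator
smoke study.  Problem sizes — 8 classes, 16 channels, 500 Hz native rate,
one or two subjects — are chosen so each study trains in minutes on one
CPU core while preserving the structure of the full 40-class, 128-channel
layout.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import IMAGINATION, VISUAL, TrialSet
from .gan import (GanTrainConfig, Discriminator, Generator,
                  class_separability, smoke_discriminator_config,
                  smoke_generator_config, train_gan)
from .interpretation import (average_attention, sort_filters,
                             spatial_filter_matrix, weighted_spatial_map)
from .model import ModelConfig, SincEEGNet, extract_attention
from .preprocessing import PreprocessConfig, preprocess_session
from .synthetic import (SyntheticConfig, generate_session,
                        make_feature_provider, make_image_dataset)
from .training import SplitSpec, TrainConfig, evaluate, split_dataset, train

__all__ = ["small_model_config", "transfer_experiment", "transfer_suite",
           "recovery_experiment", "recovery_suite", "gan_smoke"]


def small_model_config(n_classes: int = 8, n_channels: int = 16,
                       seed: int = 0) -> ModelConfig:
    """The desk-scale classifier: same stack, narrower layers."""
    return ModelConfig(n_channels=n_channels, n_samples=125,
                       n_classes=n_classes, n_filters=8, se_reduction=4,
                       dense1=64, dense2=128, dropout=0.25, seed=seed)


def _sessions(cfg: SyntheticConfig, task: str) -> TrialSet:
    pcfg = PreprocessConfig(ica_enabled=False)
    return TrialSet.concatenate(
        [preprocess_session(generate_session(cfg, s, task), pcfg)[0]
         for s in range(cfg.n_subjects)])


def transfer_experiment(seed: int, shared_fraction: float = 0.9,
                        max_epochs: int = 50, patience: int = 10) -> dict:
    """Train the three regimes on one synthetic cohort; report test accuracy.

    Two subjects, 8 classes, 16 channels.  The visual task carries the
    class signatures at +2 dB SNR, the imagination task at −14 dB with the
    same shared component — the conditions under which imagination-only
    training starves while mixed training can import the signatures
    learned from the easy task.
    """
    cfg = SyntheticConfig(
        n_subjects=2, n_classes=8, visual_trials_per_class=20,
        n_channels=16, native_rate_hz=500.0,
        shared_fraction=shared_fraction, snr_db=2.0, imagine_snr_db=-14.0,
        eog_rate=0.0, seed=seed)
    visual = _sessions(cfg, VISUAL)
    imagine = _sessions(cfg, IMAGINATION)
    trv, vav, tev = split_dataset(visual, SplitSpec(seed=seed))
    tri, vai, tei = split_dataset(imagine, SplitSpec(seed=seed))
    provider = make_feature_provider(cfg.n_classes, dim=128, seed=0)

    def fresh() -> SincEEGNet:
        return SincEEGNet(small_model_config(cfg.n_classes, cfg.n_channels,
                                             seed=seed))

    out: dict = {"seed": seed, "shared_fraction": shared_fraction}
    m, hist = train(fresh(), trv, vav,
                    TrainConfig(regime="visual", batch_size=64,
                                max_epochs=max_epochs, patience=patience,
                                seed=seed), provider)
    out["visual_on_visual"] = evaluate(m, tev).accuracy
    out["visual_on_imagine"] = evaluate(m, tei).accuracy

    # the two task datasets are equal-sized here, so one batch size keeps
    # steps-per-epoch matched across regimes
    m, _ = train(fresh(), tri, vai,
                 TrainConfig(regime="imagine", batch_size=64,
                             max_epochs=max_epochs, patience=patience,
                             seed=seed))
    out["imagine_on_imagine"] = evaluate(m, tei).accuracy

    trm = TrialSet.concatenate([trv, tri])
    vam = TrialSet.concatenate([vav, vai])
    m, _ = train(fresh(), trm, vam,
                 TrainConfig(regime="mix", batch_size=64,
                             max_epochs=max_epochs, patience=patience,
                             seed=seed), provider)
    out["mix_on_imagine"] = evaluate(m, tei).accuracy
    out["mix_on_visual"] = evaluate(m, tev).accuracy
    out["n_imagine_test"] = len(tei)
    return out


def transfer_suite(seeds: tuple[int, ...],
                   shared_fraction: float = 0.9) -> pd.DataFrame:
    return pd.DataFrame([transfer_experiment(s, shared_fraction)
                         for s in seeds])


def recovery_experiment(seed: int, band: tuple[float, float] = (8.0, 16.0),
                        channels: tuple[int, ...] = (4, 5, 6, 7),
                        max_epochs: int = 50, patience: int = 10) -> dict:
    """Plant class signals in one band over one channel set; train;
    check that interpretation recovers both.

    The classes tile sub-bands of the planted band and carry sign-flipped
    random patterns on the planted channels, so class identity is encoded
    jointly in carrier frequency and spatial phase — exactly the structure
    the sinc + depthwise layers factorize.  The patterns are zero-mean
    over channels so the average reference cannot leak them onto the rest
    of the montage.  Success means (i) a top-3 attention-ranked filter's
    passband overlaps the planted band and (ii) the top decile of the
    weighted spatial map intersects the planted channel set.

    Training runs at lr 2e-3: the spatial read-out reflects learned
    kernel structure only once the depthwise weights have moved well
    beyond their random initialization, which at this problem size needs
    the larger step.
    """
    n_classes, n_channels = 8, 16
    lo, hi = band
    width = (hi - lo) / n_classes
    class_bands = [(lo + i * width, lo + (i + 1) * width)
                   for i in range(n_classes)]
    rng = np.random.default_rng([seed % (2**31), 59])
    topo = np.zeros((n_classes, n_channels))
    for c in range(n_classes):
        p = (rng.uniform(0.5, 1.0, len(channels))
             * rng.choice([-1.0, 1.0], len(channels)))
        topo[c, list(channels)] = p - p.mean()
    cfg = SyntheticConfig(
        n_subjects=1, n_classes=n_classes, visual_trials_per_class=40,
        n_channels=n_channels, native_rate_hz=500.0,
        class_bands=class_bands, class_topographies=topo,
        shared_fraction=1.0, snr_db=10.0, eog_rate=0.0, topo_jitter=0.0,
        seed=seed)
    trials = _sessions(cfg, VISUAL)
    tr, va, te = split_dataset(trials, SplitSpec(seed=seed))
    model = SincEEGNet(small_model_config(n_classes, n_channels, seed=seed))
    model, _ = train(model, tr, va,
                     TrainConfig(regime="visual", batch_size=64, lr=2e-3,
                                 max_epochs=max_epochs, patience=patience,
                                 seed=seed))
    attn = extract_attention(model, te.epochs)
    a_ave = average_attention(attn)
    ranked = sort_filters(a_ave, model.sinc, model.config.multiplier)
    top3 = ranked.head(3)
    band_overlap = bool(((top3.f1_hz < hi) & (top3.f2_hz > lo)).any())
    spatial = spatial_filter_matrix(model)
    tmap = weighted_spatial_map(spatial, a_ave, te.channel_labels)
    n_top = max(1, int(np.ceil(n_channels / 10)))
    top_channels = np.argsort(tmap.weights)[::-1][:n_top]
    channel_hit = bool(set(top_channels.tolist()) & set(channels))
    return {
        "seed": seed,
        "band_overlap": band_overlap,
        "channel_hit": channel_hit,
        "success": band_overlap and channel_hit,
        "top3_bands": top3[["f1_hz", "f2_hz"]].to_numpy().tolist(),
        "top_channels": top_channels.tolist(),
        "test_accuracy": evaluate(model, te).accuracy,
    }


def recovery_suite(seeds: tuple[int, ...]) -> pd.DataFrame:
    return pd.DataFrame([recovery_experiment(s) for s in seeds])


def gan_smoke(seed: int, n_classes: int = 8, steps: int = 200,
              images_per_class: int = 8) -> dict:
    """Short conditioned-GAN training on synthetic 16×16 images.

    Class feature vectors stand in for EEG features; returns final losses
    and the between/within class separability of generated images.
    """
    gen_cfg = smoke_generator_config(feature_dim=64, seed=seed)
    disc_cfg = smoke_discriminator_config(n_classes=n_classes,
                                          image_size=gen_cfg.image_size,
                                          seed=seed)
    provider = make_feature_provider(n_classes, dim=gen_cfg.feature_dim,
                                     seed=seed)
    images, labels = make_image_dataset(n_classes, images_per_class,
                                        size=gen_cfg.image_size, seed=seed)
    rng = np.random.default_rng([seed % (2**31), 653])
    features = provider(labels)
    features = features + 0.05 * rng.normal(size=features.shape)  # trial noise
    generator = Generator(gen_cfg)
    discriminator = Discriminator(disc_cfg)
    history = train_gan(generator, discriminator, features, images, labels,
                        GanTrainConfig(steps=steps, seed=seed))
    sep = class_separability(generator, provider.vectors, seed=seed)
    return {
        "seed": seed,
        "steps": int(len(history)),
        "final_d_loss": float(history.d_loss.iloc[-1]),
        "final_g_loss": float(history.g_loss.iloc[-1]),
        "losses_finite": bool(np.isfinite(history[["d_loss",
                                                   "g_loss"]]).all().all()),
        "class_separability": sep,
        "history": history,
        "generator": generator,
    }
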